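seed: 11
output_dir: demo_run
groups:
  - name: control
    n_cases: 4
    stacks_per_case: 2
    simulation:
      shape: [12, 320, 320]
      plaque: {kind: none}
      accumulations:
        - {channel: cspalpha, count: 2, volume_mixture: [1.0, 0.0, 0.0]}
      synapses: []
      nuclei_count: 4
      max_shift_px: 3
  - name: alzheimers
    n_cases: 4
    stacks_per_case: 2
    simulation:
      shape: [12, 320, 320]
      plaque: {kind: neuritic-cored, core_radius_um: 2.5}
      accumulations:
        - {channel: cspalpha, count: 4, mode_distance_um: 8.0, spread_um: 2.5,
           volume_mixture: [1.0, 0.0, 0.0]}
      synapses: []
      nuclei_count: 4
      max_shift_px: 3
analysis:
  analysis_channels: [cspalpha]
  coloc_pairs: [[cspalpha, abeta]]
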