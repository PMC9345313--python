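# atpuncta

Quantification of synaptic puncta and plaque-associated protein
deposits in array-tomography (AT) serial-section volumes, with a
synthetic ribbon simulator that provides full ground truth for
validating every stage of the analysis.

## The problem

Array tomography images ribbons of ultrathin (70 nm) resin sections,
immunolabelled and acquired section by section, then computationally
reassembled into 3D volumes whose axial resolution equals the section
thickness. In neurodegeneration research this is used to quantify how
pre-synaptic proteins — synaptophysin, and the co-chaperone CSPα —
redistribute around beta-amyloid (Aβ) plaques: small synaptic puncta
are lost while larger extracellular accumulations (focal spots,
10–50 μm³, and amorphous deposits, ≥50 μm³) appear within tens of
micrometres of the plaque core. The analysis chain this package
implements:

- **registration** — serial sections are aligned by translation
  (chained pairwise masked cross-correlation on a reference channel);
- **segmentation** — channels are binarized by a union of automatic
  global thresholds (Otsu + Triangle by default) so that both high-
  and low-intensity synapses are detected; the dense plaque core is
  segmented with a fixed threshold;
- **persistence filtering** — objects present in fewer than two
  consecutive sections are removed as single-section artifacts;
- **3D volumetrics** — objects are 26-connected components with
  volume *V* (voxel count × pitch² × thickness) and equatorial
  diameter *d* = (6V/π)^(1/3), gated at 8 μm³ and classed into
  focal spots and amorphous deposits;
- **object-based co-localization** — an object co-localizes with
  another channel when ≥10% of its voxels overlap that channel's
  mask; the summary is the percentage of objects flagged;
- **plaque-distance analysis** — densities (objects/mm³) in 10 μm
  shells (0–10, 10–20, 20–30, 30–40 μm) around the core, normalized
  by each shell's analysable volume and contrasted against the
  30–40 μm reference bin;
- **statistics** — Tukey / Box–Cox power transforms, Shapiro–Wilk
  normality checks, and linear mixed-effects models
  `response ~ group + (1 | case)` with Satterthwaite degrees of
  freedom for nested case/stack designs.

Since no public AT dataset accompanies this kind of study, the
`simulate` module renders seeded synthetic ribbons — plaque core and
halo, radially decaying oligomer field, dense synapse fields, two
accumulation populations with designed volumes, placements and
co-localization fractions, per-section misalignment, photon-like noise
and single-section speckles — together with a ground-truth object
table, so recovery can be scored exactly.

## Worked example

A small simulated cohort — 4 control cases (no plaque) and 4 cases
with a neuritic-cored plaque and peri-plaque CSPα deposits, 2 stacks
per case:

```sh
atpuncta run examples/demo.yaml
atpuncta report demo_run
```

prints, at the end of the report:

```
atpuncta 0.1.0 run (seed 11, 16 stacks)
 channel              term     estimate            se         t        df            p  singular
cspalpha group[alzheimers] 2.201665e+06 147414.815265 14.935169 13.943103 5.697809e-10     False
```

Reading: CSPα object density is higher in the plaque-bearing group by
≈2.2 × 10⁶ objects/mm³; the mixed model (random intercept per case,
so the two stacks per brain are not treated as independent) gives
t = 14.9 on 13.9 Satterthwaite degrees of freedom, p ≈ 6 × 10⁻¹⁰.
Per-stack tables are written alongside (`densities.csv`,
`objects.csv`, `colocalization.csv`, `binned_densities.csv`) plus a
`manifest.json` recording every threshold, seed and parameter used;
rerunning from the same config reproduces the CSVs byte for byte.

The same machinery is available as a library:

```python
from atpuncta import simulate_ribbon, SimulationConfig, register_stack
from atpuncta import binarize, persistence_filter, label_objects

stack, truth = simulate_ribbon(SimulationConfig(seed=1))
aligned = register_stack(stack)
mask = persistence_filter(binarize(aligned.channels["cspalpha"], aligned))
objects = [o for o in label_objects(mask) if o.klass != "sub_gate"]
```

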