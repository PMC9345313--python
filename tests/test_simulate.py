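import numpy as np
import pytest
from scipy import stats as sps

from atpuncta.simulate import (
    AccumulationSpec,
    NoiseSpec,
    PlaqueSpec,
    SimulationConfig,
    SynapseFieldSpec,
    render_distance_field,
    simulate_ribbon,
)


def test_empty_field_contains_only_noise():
    cfg = SimulationConfig(
        shape=(6, 64, 64),
        plaque=PlaqueSpec(kind="none"),
        synapses=(SynapseFieldSpec(density_per_um3=0.0),),
        accumulations=(),
        nuclei_count=0,
        noise=NoiseSpec(background=100.0, background_sd=10.0, shot_scale=0.0),
        seed=1,
    )
    stack, gt = simulate_ribbon(cfg)
    assert len(gt.objects) == 0
    for vol in stack.channels.values():
        assert abs(vol.mean() - 100.0) < 2.0
        assert vol.max() < 100.0 + 8 * 10.0


def test_same_seed_is_bit_identical():
    cfg = SimulationConfig(
        shape=(12, 192, 192),
        accumulations=(AccumulationSpec(count=2, mode_distance_um=5.0,
                                        spread_um=1.5,
                                        volume_mixture=(1.0, 0.0, 0.0)),),
        plaque=PlaqueSpec(kind="neuritic-cored", core_radius_um=1.5),
        synapses=(SynapseFieldSpec(count=10),),
        n_speckles=2,
        max_shift_px=3,
        seed=42,
    )
    s1, g1 = simulate_ribbon(cfg)
    s2, g2 = simulate_ribbon(cfg)
    for ch in s1.channels:
        assert np.array_equal(s1.channels[ch], s2.channels[ch])
    assert g1.objects.equals(g2.objects)
    assert np.array_equal(g1.section_shifts_px, g2.section_shifts_px)


def test_fixed_synapse_count_and_rendered_volume():
    # 200 puncta in a 20x20x3.5 um stack; rendered mask volume should sit
    # close to the configured sphere volume
    diam = 0.5
    cfg = SimulationConfig(
        shape=(50, 200, 200),
        plaque=PlaqueSpec(kind="none"),
        synapses=(SynapseFieldSpec(count=200, punctum_diameter_um=diam),),
        accumulations=(),
        nuclei_count=0,
        seed=7,
    )
    _, gt = simulate_ribbon(cfg)
    syn = gt.of_class("synapse")
    assert len(syn) == 200
    expected = np.pi / 6.0 * diam**3
    assert abs(syn["volume_um3"].mean() - expected) / expected < 0.15


def test_ground_truth_section_span_invariants(small_plaque_sim):
    _, (_, gt) = small_plaque_sim
    obj = gt.objects
    non_speckle = obj[obj["klass"] != "speckle"]
    assert (non_speckle["sections"] >= 2).all()
    speckle = obj[obj["klass"] == "speckle"]
    assert (speckle["sections"] == 1).all()


def test_radial_placement_law_matches_configuration():
    """Pooled accumulation distances follow the configured truncated
    normal law (two-sided KS)."""
    mode, spread = 15.0, 5.0
    dists = []
    for seed in range(2):
        # exclusion disabled: the law is about where objects are drawn,
        # not about crowding corrections
        cfg = SimulationConfig(
            shape=(20, 768, 768),
            accumulations=(AccumulationSpec(count=250, mode_distance_um=mode,
                                            spread_um=spread,
                                            volume_mixture=(1.0, 0.0, 0.0),
                                            min_separation_um=None),),
            synapses=(),
            nuclei_count=0,
            noise=NoiseSpec(background=0.0, background_sd=0.0, shot_scale=0.0),
            seed=900 + seed,
        )
        _, gt = simulate_ribbon(cfg)
        acc = gt.objects[gt.objects["klass"].isin(
            ["focal_spot", "amorphous_deposit"])]
        dists.append(acc["distance_um"].to_numpy())
    pooled = np.concatenate(dists)
    assert pooled.size == 500
    law = sps.truncnorm(-mode / spread, np.inf, loc=mode, scale=spread)
    res = sps.kstest(pooled, law.cdf)
    assert res.pvalue > 0.01


def test_conservation_of_requested_counts(small_plaque_sim):
    cfg, (_, gt) = small_plaque_sim
    n_acc = len(gt.objects[gt.objects["klass"].isin(
        ["focal_spot", "amorphous_deposit"])])
    assert n_acc == cfg.accumulations[0].count


def test_invalid_configs_are_rejected():
    with pytest.raises(ValueError, match="core radius"):
        SimulationConfig(
            shape=(6, 32, 32),
            plaque=PlaqueSpec(kind="neuritic-cored", core_radius_um=10.0),
        ).validate()
    with pytest.raises(ValueError, match="mixture"):
        SimulationConfig(
            accumulations=(AccumulationSpec(count=1,
                                            volume_mixture=(0.5, 0.2, 0.2)),),
        ).validate()
    with pytest.raises(ValueError, match="thickness|pitch"):
        SimulationConfig(section_thickness_um=0.0).validate()


class TestDistanceField:
    cfg = SimulationConfig(shape=(10, 200, 200))

    def test_zero_at_centroid(self):
        f = render_distance_field(self.cfg, (0.35, 10.0, 10.0))
        assert f[5, 100, 100] == pytest.approx(0.0, abs=1e-9)

    def test_lateral_distance_is_pitch_scaled(self):
        f = render_distance_field(self.cfg, (0.35, 10.0, 10.0))
        assert f[5, 100, 200 - 1] == pytest.approx(
            (200 - 1 - 100) * 0.1, rel=1e-12
        )

    def test_axial_distance_is_section_thickness(self):
        f = render_distance_field(self.cfg, (0.35, 10.0, 10.0))
        assert f[6, 100, 100] == pytest.approx(0.07, rel=1e-12)

    def test_outside_centroid_rejected(self):
        with pytest.raises(ValueError):
            render_distance_field(self.cfg, (50.0, 10.0, 10.0))
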