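import numpy as np
import pytest

from atpuncta.segment import (
    BinaryStack,
    binarize,
    persistence_filter,
    segment_plaque_core,
)
from atpuncta.simulate import simulate_ribbon
from atpuncta.stack import SectionStack
from tests.conftest import make_speckle_config


def _geom(shape):
    return SectionStack(
        channels={"x": np.zeros(shape, np.float32)},
        pixel_pitch_um=0.1,
        section_thickness_um=0.07,
    )


class TestBinarize:
    def test_union_catches_both_intensity_tiers(self, rng):
        """A high-bias method alone misses dim objects; the union of a
        high- and a low-bias method catches both tiers."""
        vol = rng.normal(100.0, 5.0, (6, 80, 80)).astype(np.float32)
        # bright tier and dim tier, both well above background
        vol[1:4, 10:20, 10:20] = 3000.0
        vol[1:4, 50:60, 50:60] = 250.0
        geom = _geom(vol.shape)
        high = binarize(vol, geom, methods=("otsu",))
        both = binarize(vol, geom, methods=("otsu", "triangle"))
        bright = np.zeros(vol.shape, bool); bright[1:4, 10:20, 10:20] = True
        dim = np.zeros(vol.shape, bool); dim[1:4, 50:60, 50:60] = True
        assert high.mask[bright].all() and not high.mask[dim].any()
        assert both.mask[bright].all() and both.mask[dim].all()
        # per-voxel agreement with direct comparison against the thresholds
        expected = (vol > high.thresholds["otsu"]) | (
            vol > both.thresholds["triangle"]
        )
        assert np.array_equal(both.mask, expected)

    def test_constant_volume_yields_empty_mask_with_warning(self):
        vol = np.full((4, 16, 16), 7.0, np.float32)
        with pytest.warns(UserWarning, match="constant"):
            b = binarize(vol, _geom(vol.shape))
        assert not b.mask.any()

    def test_intersection_of_nested_masks_is_smaller_mask(self, rng):
        vol = rng.normal(100.0, 5.0, (4, 40, 40)).astype(np.float32)
        vol[1:3, 5:15, 5:15] = 500.0
        geom = _geom(vol.shape)
        inter = binarize(vol, geom, methods=("otsu", "triangle"),
                         combine="intersection")
        # thresholds are nested, so intersection equals the higher one
        hi = max(inter.thresholds.values())
        assert np.array_equal(inter.mask, vol > hi)

    def test_union_monotone_in_methods(self, rng):
        vol = rng.normal(100.0, 30.0, (4, 40, 40)).astype(np.float32)
        vol[1:3, 5:15, 5:15] = 900.0
        geom = _geom(vol.shape)
        m1 = binarize(vol, geom, methods=("otsu",)).mask
        m2 = binarize(vol, geom, methods=("otsu", "triangle")).mask
        m3 = binarize(vol, geom, methods=("otsu", "triangle", "li")).mask
        assert (m1 <= m2).all() and (m2 <= m3).all()

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            binarize(np.zeros((2, 4, 4)), _geom((2, 4, 4)), methods=("magic",))


class TestPersistenceFilter:
    def _wrap(self, mask):
        return BinaryStack(mask=mask, pixel_pitch_um=0.1,
                           section_thickness_um=0.07)

    def test_single_section_component_removed(self):
        mask = np.zeros((4, 8, 8), bool)
        mask[1, 2:4, 2:4] = True
        out = persistence_filter(self._wrap(mask))
        assert not out.mask.any()

    def test_two_consecutive_section_component_retained(self):
        mask = np.zeros((4, 8, 8), bool)
        mask[1:3, 2:4, 2:4] = True
        out = persistence_filter(self._wrap(mask))
        assert np.array_equal(out.mask, mask)

    def test_idempotent_and_never_creates_voxels(self, rng):
        mask = rng.random((5, 20, 20)) > 0.8
        once = persistence_filter(mask)
        twice = persistence_filter(once)
        assert np.array_equal(once, twice)
        assert not (once & ~mask).any()

    def test_single_section_stack_rejected(self):
        with pytest.raises(ValueError):
            persistence_filter(np.ones((1, 4, 4), bool))

    def test_simulated_speckles_removed_objects_kept(self):
        """On a simulated ribbon the filter removes exactly the injected
        single-section speckles and keeps every multi-section punctum."""
        from scipy import ndimage

        from atpuncta.segment import STRUCT_26

        cfg = make_speckle_config(seed=77)
        stack, gt = simulate_ribbon(cfg)
        mask = stack.channels["cspalpha"] > 450.0  # structure >> noise
        n_before = ndimage.label(mask, structure=STRUCT_26)[1]
        out = persistence_filter(mask)
        n_after = ndimage.label(out, structure=STRUCT_26)[1]
        k = len(gt.of_class("speckle"))
        m = len(gt.of_class("synapse"))
        assert n_before == k + m
        assert n_before - n_after == k
        # every surviving component is one of the multi-section puncta
        assert n_after == m


class TestPlaqueCore:
    def test_simulated_core_centroid_recovered(self, small_plaque_sim):
        cfg, (stack, gt) = small_plaque_sim
        core = segment_plaque_core(stack.channels["abeta"], stack)
        assert core.has_core
        err = np.linalg.norm(
            np.array(core.centroid_um) - np.array(gt.plaque_centroid_um)
        )
        assert err < 1.0

    def test_subthreshold_volume_gives_no_core(self, rng):
        vol = rng.normal(100.0, 5.0, (4, 32, 32)).astype(np.float32)
        core = segment_plaque_core(vol, _geom(vol.shape), threshold=1e6)
        assert not core.has_core
        assert core.distance_um is None

    def test_zero_threshold_keeps_whole_volume(self):
        vol = np.ones((3, 8, 8), np.float32)
        core = segment_plaque_core(vol, _geom(vol.shape), threshold=0.0)
        assert core.mask.all()
        # centroid of the full volume in um
        assert core.centroid_um == pytest.approx((0.07, 0.35, 0.35))

    def test_distance_fields_are_anisotropy_corrected(self):
        vol = np.zeros((5, 21, 21), np.float32)
        vol[2, 10, 10] = 10.0
        core = segment_plaque_core(vol, _geom(vol.shape), threshold=5.0)
        assert core.distance_um[2, 10, 10] == pytest.approx(0.0)
        assert core.distance_um[3, 10, 10] == pytest.approx(0.07)
        assert core.distance_um[2, 10, 15] == pytest.approx(0.5)
        assert core.edge_distance_um[2, 10, 11] == pytest.approx(0.1)
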