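import numpy as np
import pytest

from atpuncta.quantify import (
    CLASS_AMORPHOUS_50_100,
    CLASS_AMORPHOUS_GT100,
    CLASS_FOCAL,
    CLASS_SUB_GATE,
    classify_accumulation,
    colocalize,
    density_per_mm3,
    equatorial_diameter,
    label_objects,
)
from atpuncta.segment import BinaryStack, persistence_filter


def _bin(mask):
    return BinaryStack(mask=mask, pixel_pitch_um=0.1,
                       section_thickness_um=0.07, channel="cspalpha")


class TestEquatorialDiameter:
    def test_unit_sphere(self):
        assert equatorial_diameter(np.pi / 6.0) == pytest.approx(1.0, rel=1e-12)

    def test_value_at_gate_volume(self):
        # frozen from a 45-digit decimal evaluation of (48/pi)^(1/3)
        assert equatorial_diameter(8.0) == pytest.approx(
            2.4814019635976, rel=1e-12
        )

    def test_cube_root_homogeneity(self):
        for v in (0.3, 1.0, 57.2):
            assert equatorial_diameter(8 * v) == pytest.approx(
                2 * equatorial_diameter(v), rel=1e-12
            )

    def test_strictly_increasing(self, rng):
        v = np.sort(rng.uniform(0.1, 300.0, 100))
        d = equatorial_diameter(v)
        assert np.all(np.diff(d) > 0)

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            equatorial_diameter(0.0)


@pytest.mark.parametrize(
    "volume, expected",
    [
        (7.0, CLASS_SUB_GATE),       # below the 8 um^3 gate
        (8.0, CLASS_FOCAL),          # gate boundary is inclusive
        (9.0, CLASS_FOCAL),          # gate governs inclusion below the 10 bin
        (25.0, CLASS_FOCAL),
        (49.999, CLASS_FOCAL),
        (50.0, CLASS_AMORPHOUS_50_100),  # ties go to the upper class
        (99.999, CLASS_AMORPHOUS_50_100),
        (100.0, CLASS_AMORPHOUS_GT100),
        (150.0, CLASS_AMORPHOUS_GT100),
    ],
)
def test_volume_classification(volume, expected):
    assert classify_accumulation(volume) == expected


class TestLabelObjects:
    def test_single_voxel_volume(self):
        mask = np.zeros((3, 4, 4), bool)
        mask[1, 1, 1] = True
        objs = label_objects(_bin(mask))
        assert len(objs) == 1
        assert objs[0].volume_um3 == pytest.approx(7e-4, rel=1e-9)
        assert objs[0].section_span == 1

    def test_diagonal_voxels_are_one_object(self):
        mask = np.zeros((3, 4, 4), bool)
        mask[0, 0, 0] = True
        mask[1, 1, 1] = True
        objs = label_objects(_bin(mask))
        assert len(objs) == 1
        assert objs[0].section_span == 2

    def test_mass_conservation_after_persistence(self, rng):
        mask = rng.random((6, 30, 30)) > 0.85
        kept = persistence_filter(_bin(mask))
        objs = label_objects(kept)
        assert sum(o.n_voxels for o in objs) == int(kept.mask.sum())

    def test_deterministic_scan_order_ids(self):
        mask = np.zeros((4, 6, 6), bool)
        mask[2:4, 4:6, 4:6] = True   # later in scan order
        mask[0:2, 0:2, 0:2] = True   # earlier
        objs = label_objects(_bin(mask))
        assert objs[0].centroid_um[0] < objs[1].centroid_um[0]


class TestColocalize:
    def _objects(self):
        mask = np.zeros((4, 10, 10), bool)
        mask[0:2, 0:2, 0:2] = True   # 8 voxels
        mask[2:4, 5:9, 5:9] = True   # 32 voxels
        return label_objects(_bin(mask)), mask

    def test_full_overlap_flags_object(self):
        objs, mask = self._objects()
        summary = colocalize(objs, mask, target_channel="abeta")
        assert summary.n_colocalized == 2
        assert summary.percentage == pytest.approx(100.0)

    def test_subcriterion_overlap_not_flagged(self):
        objs, _ = self._objects()
        target = np.zeros((4, 10, 10), bool)
        target[0, 0, 0] = True  # 1/8 = 12.5% of first object
        target[2, 5, 5] = True  # 1/32 ~ 3% of second object
        summary = colocalize(objs, target, target_channel="abeta")
        assert summary.n_colocalized == 1
        frac = [o.overlap_fractions["abeta"] for o in objs]
        assert frac == pytest.approx([0.125, 1 / 32])

    def test_threshold_monotonicity(self, rng):
        mask = rng.random((5, 20, 20)) > 0.8
        objs = label_objects(_bin(mask))
        target = rng.random((5, 20, 20)) > 0.5
        flagged = [
            colocalize(objs, target, overlap_threshold=f).n_colocalized
            for f in (0.05, 0.1, 0.2, 0.35, 0.5)
        ]
        assert all(a >= b for a, b in zip(flagged, flagged[1:]))

    def test_geometry_mismatch_rejected(self):
        objs, _ = self._objects()
        with pytest.raises(ValueError, match="geometry"):
            colocalize(objs, np.zeros((2, 3, 3), bool))

    def test_empty_object_list_has_undefined_percentage(self):
        summary = colocalize([], np.zeros((2, 3, 3), bool))
        assert summary.percentage is None


class TestDensity:
    def test_known_ratio(self):
        assert density_per_mm3(100, 1e-3) == pytest.approx(1e5)

    def test_zero_objects(self):
        assert density_per_mm3(0, 1e-3) == 0.0

    def test_zero_volume_rejected(self):
        with pytest.raises(ValueError):
            density_per_mm3(5, 0.0)
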