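"""Binarization, plaque-core segmentation and the persistence filter.

Channels are binarized with one or more automatic global thresholds
whose masks are combined voxelwise (union by default, so that both
high- and low-intensity synapses are caught); dense plaque cores are
segmented with a fixed threshold; and connected components that do not
persist across two or more consecutive serial sections are removed as
single-section artifacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import filters

from .stack import SectionStack

#: automatic threshold menu; Otsu biases high (bright objects), Triangle
#: biases low (dim objects), so their union catches both tiers.
THRESHOLD_METHODS = {
    "otsu": filters.threshold_otsu,
    "triangle": filters.threshold_triangle,
    "li": filters.threshold_li,
    "yen": filters.threshold_yen,
    "mean": filters.threshold_mean,
    "isodata": filters.threshold_isodata,
}

#: 26-neighbourhood structuring element for 3D connected components
STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class BinaryStack:
    """A boolean volume with segmentation provenance."""

    mask: np.ndarray
    pixel_pitch_um: float
    section_thickness_um: float
    channel: str = ""
    methods: tuple[str, ...] = ()
    thresholds: dict[str, float] = field(default_factory=dict)
    combine: str = "union"

    @property
    def voxel_volume_um3(self) -> float:
        return self.section_thickness_um * self.pixel_pitch_um**2


@dataclass
class PlaqueCore:
    """The segmented dense Aβ core and its distance fields."""

    mask: np.ndarray | None
    centroid_um: tuple[float, float, float] | None
    threshold: float
    distance_um: np.ndarray | None  # from centroid, anisotropy-corrected
    edge_distance_um: np.ndarray | None  # from the core boundary

    @property
    def has_core(self) -> bool:
        return self.mask is not None


def binarize(
    volume: np.ndarray,
    geometry: SectionStack | BinaryStack,
    methods: tuple[str, ...] = ("otsu", "triangle"),
    combine: str = "union",
    channel: str = "",
) -> BinaryStack:
    """Binarize a channel with one or more global automatic thresholds.

    Each named method computes one threshold over the whole stack
    (global per stack, so the downstream persistence filter sees a
    consistent segmentation across sections); the per-method masks are
    combined voxelwise by ``union`` or ``intersection``.  A constant
    intensity volume yields an empty mask and a warning, as no
    threshold is definable.
    """
    if not methods:
        raise ValueError("at least one threshold method is required")
    if combine not in ("union", "intersection"):
        raise ValueError(f"unknown combination rule {combine!r}")
    unknown = [m for m in methods if m not in THRESHOLD_METHODS]
    if unknown:
        raise ValueError(f"unknown threshold method(s) {unknown}; "
                         f"available: {sorted(THRESHOLD_METHODS)}")
    volume = np.asarray(volume)
    thresholds: dict[str, float] = {}
    if np.ptp(volume) == 0:
        warnings.warn(
            "constant-intensity volume: no threshold definable, mask is empty",
            stacklevel=2,
        )
        mask = np.zeros(volume.shape, dtype=bool)
    else:
        mask = None
        for m in methods:
            thr = float(THRESHOLD_METHODS[m](volume))
            thresholds[m] = thr
            part = volume > thr
            if mask is None:
                mask = part
            elif combine == "union":
                mask |= part
            else:
                mask &= part
    return BinaryStack(
        mask=mask,
        pixel_pitch_um=geometry.pixel_pitch_um,
        section_thickness_um=geometry.section_thickness_um,
        channel=channel,
        methods=tuple(methods),
        thresholds=thresholds,
        combine=combine,
    )


def section_span(component_mask: np.ndarray) -> int:
    """Number of distinct sections occupied by a component's voxels.

    Under 26-connectivity a connected component can only occupy a
    contiguous run of sections, so this equals its consecutive span.
    """
    return int(np.unique(np.nonzero(component_mask)[0]).size)


def persistence_filter(binary: BinaryStack | np.ndarray) -> BinaryStack | np.ndarray:
    """Remove components present in fewer than two serial sections.

    Only objects present in two or more consecutive sections are
    retained; single-section components are deleted as non-specific
    signal (speckle artifacts).  The output mask is always a subset of
    the input and the operation is idempotent.
    """
    mask = binary.mask if isinstance(binary, BinaryStack) else np.asarray(binary)
    if mask.ndim != 3 or mask.shape[0] < 2:
        raise ValueError(
            "persistence filtering requires a 3D stack with >= 2 sections"
        )
    labels, n = ndimage.label(mask, structure=STRUCT_26)
    if n:
        # per-label count of occupied sections: a label occupies section z
        # if any voxel in that plane carries it
        occupied = np.zeros((mask.shape[0], n + 1), dtype=bool)
        for z in range(mask.shape[0]):
            occupied[z, np.unique(labels[z])] = True
        spans = occupied[:, 1:].sum(axis=0)
        keep = np.zeros(n + 1, dtype=bool)
        keep[1:] = spans >= 2
        out = keep[labels]
    else:
        out = mask.copy()
    if isinstance(binary, BinaryStack):
        return BinaryStack(
            mask=out,
            pixel_pitch_um=binary.pixel_pitch_um,
            section_thickness_um=binary.section_thickness_um,
            channel=binary.channel,
            methods=binary.methods,
            thresholds=dict(binary.thresholds),
            combine=binary.combine,
        )
    return out


def segment_plaque_core(
    abeta: np.ndarray,
    geometry: SectionStack,
    threshold: float | None = None,
    threshold_fraction: float = 0.5,
) -> PlaqueCore:
    """Segment the dense plaque core with a fixed intensity threshold.

    If no absolute ``threshold`` is given it is set to
    ``threshold_fraction`` of the Aβ channel's 99.9th intensity
    percentile, which is robust across exposure levels.  The largest
    suprathreshold connected component is kept; an empty suprathreshold
    set (e.g. a diffuse-only plaque) yields a "no core" result, and
    downstream distance binning must then be skipped.
    """
    abeta = np.asarray(abeta)
    if threshold is None:
        threshold = threshold_fraction * float(np.percentile(abeta, 99.9))
    mask = abeta >= threshold
    if not mask.any():
        return PlaqueCore(None, None, threshold, None, None)
    labels, n = ndimage.label(mask, structure=STRUCT_26)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
        mask = labels == (int(np.argmax(sizes)) + 1)
    dz = geometry.section_thickness_um
    dxy = geometry.pixel_pitch_um
    centroid_vox = np.array(ndimage.center_of_mass(mask))
    centroid_um = tuple(centroid_vox * np.array([dz, dxy, dxy]))
    S, R, C = mask.shape
    z = (np.arange(S) * dz - centroid_um[0]) ** 2
    y = (np.arange(R) * dxy - centroid_um[1]) ** 2
    x = (np.arange(C) * dxy - centroid_um[2]) ** 2
    dist = np.sqrt(z[:, None, None] + y[None, :, None] + x[None, None, :])
    edge = ndimage.distance_transform_edt(~mask, sampling=(dz, dxy, dxy))
    return PlaqueCore(
        mask=mask,
        centroid_um=tuple(float(v) for v in centroid_um),
        threshold=float(threshold),
        distance_um=dist,
        edge_distance_um=edge,
    )
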