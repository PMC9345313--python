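"""3D object labelling, volumetrics, classification and co-localization.

Objects are 26-connected components of a binarized channel.  Each
object carries its voxel-count volume V (μm³), the equatorial diameter
d = (6V/π)^(1/3) — the diameter of the sphere with the same volume —
its centroid, and the number of serial sections it spans.  Objects
below the 8 μm³ minimum volume gate are excluded from accumulation
statistics; gated objects are classified by volume into focal spots
(up to 50 μm³) and amorphous deposits (50–100 and >100 μm³).

Object-based co-localization flags an object when at least a fixed
fraction (10% by default) of its voxels fall inside the other
channel's mask, and reports the percentage of flagged objects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .segment import STRUCT_26, BinaryStack

#: minimum object volume (μm³) for inclusion in accumulation statistics
VOLUME_GATE_UM3 = 8.0
#: volume-class boundaries (μm³); half-open [lo, hi) intervals
CLASS_FOCAL_MAX = 50.0
CLASS_AMORPHOUS_MAX = 100.0
#: minimum fractional voxel overlap for object-based co-localization
OVERLAP_FRACTION = 0.10

CLASS_SUB_GATE = "sub_gate"
CLASS_FOCAL = "focal_spot"
CLASS_AMORPHOUS_50_100 = "amorphous_deposit_50_100"
CLASS_AMORPHOUS_GT100 = "amorphous_deposit_gt100"


@dataclass
class DetectedObject:
    """One 26-connected component with its measurements."""

    id: int
    channel: str
    voxels: tuple[np.ndarray, np.ndarray, np.ndarray]  # (z, y, x) index arrays
    volume_um3: float
    equatorial_diameter_um: float
    centroid_um: tuple[float, float, float]
    section_span: int
    klass: str
    overlap_fractions: dict[str, float] = field(default_factory=dict)
    colocalized_with: dict[str, bool] = field(default_factory=dict)

    @property
    def n_voxels(self) -> int:
        return self.voxels[0].size


@dataclass
class ColocalizationSummary:
    """Per channel pair: how many objects meet the overlap criterion."""

    source_channel: str
    target_channel: str
    overlap_threshold: float
    n_objects: int
    n_colocalized: int

    @property
    def percentage(self) -> float | None:
        """100 × co-localized / total; ``None`` when there are no objects."""
        if self.n_objects == 0:
            return None
        return 100.0 * self.n_colocalized / self.n_objects


def equatorial_diameter(volume_um3: float | np.ndarray) -> float | np.ndarray:
    """Diameter of the sphere with the same volume: (6V/π)^(1/3)."""
    v = np.asarray(volume_um3, dtype=float)
    if np.any(v <= 0):
        raise ValueError("equatorial diameter requires volume > 0")
    d = np.cbrt(6.0 * v / math.pi)
    return float(d) if np.isscalar(volume_um3) or d.ndim == 0 else d


def classify_accumulation(
    volume_um3: float, gate_um3: float = VOLUME_GATE_UM3
) -> str:
    """Volume class of an accumulation; intervals are half-open [lo, hi).

    Objects below the gate are excluded from accumulation statistics.
    Objects between the gate and 50 μm³ count as focal spots (the gate
    governs inclusion; 10–50 μm³ is a descriptive bin), larger ones as
    amorphous deposits, split at 100 μm³.
    """
    if volume_um3 < gate_um3:
        return CLASS_SUB_GATE
    if volume_um3 < CLASS_FOCAL_MAX:
        return CLASS_FOCAL
    if volume_um3 < CLASS_AMORPHOUS_MAX:
        return CLASS_AMORPHOUS_50_100
    return CLASS_AMORPHOUS_GT100


def label_objects(
    binary: BinaryStack,
    channel: str | None = None,
    gate_um3: float = VOLUME_GATE_UM3,
) -> list[DetectedObject]:
    """Label 26-connected components and measure each one.

    Objects are ordered deterministically by the scan-order position of
    their minimum voxel index.  No volume gating is applied here beyond
    classification: sub-gate objects are returned with class
    ``sub_gate`` so callers can include or exclude them explicitly.
    """
    mask = binary.mask
    voxvol = binary.voxel_volume_um3
    dz = binary.section_thickness_um
    dxy = binary.pixel_pitch_um
    labels, n = ndimage.label(mask, structure=STRUCT_26)
    objects: list[DetectedObject] = []
    if n == 0:
        return objects
    slices = ndimage.find_objects(labels)
    shape = mask.shape
    entries = []
    for lab, sl in enumerate(slices, start=1):
        sub = labels[sl] == lab
        zz, yy, xx = np.nonzero(sub)
        zz = zz + sl[0].start
        yy = yy + sl[1].start
        xx = xx + sl[2].start
        flat_min = int(
            np.min((zz * shape[1] + yy) * shape[2] + xx)
        )
        entries.append((flat_min, zz, yy, xx))
    entries.sort(key=lambda e: e[0])
    for i, (_, zz, yy, xx) in enumerate(entries):
        v = zz.size * voxvol
        objects.append(
            DetectedObject(
                id=i,
                channel=channel or binary.channel,
                voxels=(zz, yy, xx),
                volume_um3=v,
                equatorial_diameter_um=equatorial_diameter(v),
                centroid_um=(
                    float(zz.mean() * dz),
                    float(yy.mean() * dxy),
                    float(xx.mean() * dxy),
                ),
                section_span=int(np.unique(zz).size),
                klass=classify_accumulation(v, gate_um3),
            )
        )
    return objects


def colocalize(
    objects: list[DetectedObject],
    target_mask: BinaryStack | np.ndarray,
    overlap_threshold: float = OVERLAP_FRACTION,
    target_channel: str | None = None,
) -> ColocalizationSummary:
    """Flag objects whose fractional voxel overlap with ``target_mask``
    meets the minimum-overlap criterion and summarize the percentage.

    An object is co-localized iff |voxels(object) ∩ mask| / |voxels(object)|
    ≥ ``overlap_threshold`` (10% by default).  Flags and fractions are
    stored on the objects in place.
    """
    mask = target_mask.mask if isinstance(target_mask, BinaryStack) else target_mask
    ch = target_channel or (
        target_mask.channel if isinstance(target_mask, BinaryStack) else "target"
    )
    if objects and mask.shape != _object_domain_shape(objects, mask):
        raise ValueError("object geometry does not match the target mask")
    n_coloc = 0
    for obj in objects:
        zz, yy, xx = obj.voxels
        frac = float(mask[zz, yy, xx].mean()) if zz.size else 0.0
        obj.overlap_fractions[ch] = frac
        flag = frac >= overlap_threshold
        obj.colocalized_with[ch] = flag
        n_coloc += int(flag)
    src = objects[0].channel if objects else ""
    return ColocalizationSummary(
        source_channel=src,
        target_channel=ch,
        overlap_threshold=overlap_threshold,
        n_objects=len(objects),
        n_colocalized=n_coloc,
    )


def _object_domain_shape(objects, mask):
    # voxel indices must address the mask legally; treat out-of-range
    # indices as a geometry mismatch
    for obj in objects:
        zz, yy, xx = obj.voxels
        if zz.size and (
            zz.max() >= mask.shape[0]
            or yy.max() >= mask.shape[1]
            or xx.max() >= mask.shape[2]
        ):
            return None
    return mask.shape


def density_per_mm3(n_objects: int, analysed_volume_mm3: float) -> float:
    """Object density in objects/mm³ over the analysable (valid) volume."""
    if analysed_volume_mm3 <= 0:
        raise ValueError("analysed volume must be > 0")
    return n_objects / analysed_volume_mm3


def objects_to_frame(objects: list[DetectedObject]) -> pd.DataFrame:
    """Tidy one-row-per-object table (for CSV export)."""
    rows = []
    for o in objects:
        row = dict(
            id=o.id,
            channel=o.channel,
            volume_um3=o.volume_um3,
            equatorial_diameter_um=o.equatorial_diameter_um,
            z_um=o.centroid_um[0],
            y_um=o.centroid_um[1],
            x_um=o.centroid_um[2],
            section_span=o.section_span,
            klass=o.klass,
        )
        for ch, f in o.overlap_fractions.items():
            row[f"overlap_{ch}"] = f
            row[f"coloc_{ch}"] = o.colocalized_with[ch]
        rows.append(row)
    return pd.DataFrame(rows)
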