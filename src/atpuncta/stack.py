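"""Multi-channel serial-section image stacks.

A :class:`SectionStack` holds one 3D intensity volume per fluorescence
channel on a shared anisotropic voxel grid: the axial pitch is the
physical section thickness of the ribbon (70 nm by default) while the
lateral pitch is the camera pixel size.  Axes are ordered ``(section,
row, col)`` i.e. ``(z, y, x)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: canonical channel names used throughout the package
CHANNEL_ABETA = "abeta"
CHANNEL_CSP = "cspalpha"
CHANNEL_SYP = "synaptophysin"
CHANNEL_NUCLEI = "nuclei"
DEFAULT_CHANNELS = (CHANNEL_ABETA, CHANNEL_CSP, CHANNEL_SYP, CHANNEL_NUCLEI)


@dataclass
class SectionStack:
    """A registered or raw multi-channel serial-section volume.

    Parameters
    ----------
    channels
        Mapping of channel name to a float array of shape
        ``(sections, rows, cols)``.  All channels share one geometry.
    pixel_pitch_um
        Lateral pixel size in micrometres per pixel.
    section_thickness_um
        Physical thickness of one section in micrometres; this is the
        axial voxel pitch.
    aligned
        Whether the sections have been registered.
    section_shifts_px
        Per-section ``(dy, dx)`` translations (pixels) applied by the
        registration step; ``None`` for raw stacks.
    validity
        Boolean volume marking voxels that carry genuine image data
        (False where zero-filling was introduced by resampling).
    """

    channels: dict[str, np.ndarray]
    pixel_pitch_um: float
    section_thickness_um: float
    aligned: bool = False
    section_shifts_px: np.ndarray | None = None
    validity: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("SectionStack requires at least one channel")
        if self.pixel_pitch_um <= 0 or self.section_thickness_um <= 0:
            raise ValueError("pixel pitch and section thickness must be > 0")
        shapes = {ch: arr.shape for ch, arr in self.channels.items()}
        first = next(iter(shapes.values()))
        if any(s != first for s in shapes.values()):
            raise ValueError(f"channels disagree on geometry: {shapes}")
        if len(first) != 3:
            raise ValueError("channel volumes must be 3D (sections, rows, cols)")
        if self.validity is None:
            self.validity = np.ones(first, dtype=bool)

    # -- geometry ------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def n_sections(self) -> int:
        return self.shape[0]

    @property
    def voxel_size_um(self) -> tuple[float, float, float]:
        """Anisotropic voxel edge lengths ``(dz, dy, dx)`` in μm."""
        return (self.section_thickness_um, self.pixel_pitch_um, self.pixel_pitch_um)

    @property
    def voxel_volume_um3(self) -> float:
        return self.section_thickness_um * self.pixel_pitch_um**2

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(self.channels)

    def valid_volume_mm3(self) -> float:
        """Analysable volume (validity-masked voxels only) in mm³."""
        return float(self.validity.sum()) * self.voxel_volume_um3 * 1e-9

    def voxel_to_um(self, zyx: np.ndarray) -> np.ndarray:
        """Convert voxel coordinates (possibly fractional) to μm."""
        zyx = np.asarray(zyx, dtype=float)
        return zyx * np.array(self.voxel_size_um)
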