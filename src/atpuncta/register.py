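"""Translation registration of serial sections.

Serial ultrathin sections predominantly misalign by rigid in-plane
translation during ribbon pickup and imaging, so sections are aligned
by chained pairwise phase cross-correlation on a reference channel
(nuclei by default, whose large blobs are stable landmarks), and the
recovered shifts are applied identically to all channels.
"""

from __future__ import annotations

import warnings

import numpy as np
from skimage.registration import phase_cross_correlation

from .simulate import _apply_section_shifts
from .stack import CHANNEL_NUCLEI, SectionStack


class RegistrationWarning(UserWarning):
    """Raised (as a warning) when an estimated shift is implausibly large."""


def estimate_shifts(
    stack: SectionStack,
    reference_channel: str = CHANNEL_NUCLEI,
    sanity_fraction: float = 0.10,
    subpixel: bool = False,
    upsample_factor: int = 20,
) -> np.ndarray:
    """Estimate per-section alignment shifts on the reference channel.

    Each section is cross-correlated against its predecessor (chained
    pairwise alignment, mirroring acquisition drift along the ribbon);
    the returned array holds, per section, the absolute ``(dy, dx)``
    translation that aligns it to section 0.  Integer estimation uses
    masked (overlap-normalized) cross-correlation, which is unbiased by
    content lost at the frame edges under translation; sub-pixel mode
    refines the plain correlation peak by Fourier upsampling instead.
    Shifts whose magnitude exceeds ``sanity_fraction`` of the frame are
    clamped to that bound and a :class:`RegistrationWarning` is emitted.
    """
    if reference_channel not in stack.channels:
        raise KeyError(f"reference channel {reference_channel!r} not in stack")
    ref = stack.channels[reference_channel]
    S, R, C = ref.shape
    if S < 2:
        raise ValueError("registration requires at least 2 sections")
    bound = np.array([sanity_fraction * R, sanity_fraction * C])
    full = np.ones((R, C), dtype=bool)
    shifts = np.zeros((S, 2), dtype=float)
    for s in range(1, S):
        if subpixel:
            rel = phase_cross_correlation(
                ref[s - 1], ref[s],
                upsample_factor=upsample_factor,
                normalization=None,
            )[0]
        else:
            rel = phase_cross_correlation(
                ref[s - 1], ref[s],
                reference_mask=full, moving_mask=full,
                overlap_ratio=max(1.0 - 2.0 * sanity_fraction, 0.3),
            )[0]
        shifts[s] = shifts[s - 1] + rel
    over = np.abs(shifts) > bound
    if over.any():
        warnings.warn(
            "estimated section shifts exceed the sanity bound "
            f"({sanity_fraction:.0%} of frame) in {int(over.any(axis=1).sum())} "
            "section(s); clamping",
            RegistrationWarning,
            stacklevel=2,
        )
        shifts = np.clip(shifts, -bound, bound)
    if not subpixel:
        shifts = np.round(shifts).astype(int)
    return shifts


def apply_shifts(stack: SectionStack, shifts: np.ndarray) -> SectionStack:
    """Apply per-section ``(dy, dx)`` translations to every channel.

    Integer shifts are applied losslessly with zero fill; the returned
    stack's validity mask flags the zero-filled out-of-frame voxels.
    """
    shifts = np.asarray(shifts)
    int_shifts = np.round(shifts).astype(int)
    channels = {
        ch: _apply_section_shifts(vol, int_shifts)
        for ch, vol in stack.channels.items()
    }
    validity = _apply_section_shifts(
        stack.validity.astype(np.float32), int_shifts
    ) > 0.5
    return SectionStack(
        channels=channels,
        pixel_pitch_um=stack.pixel_pitch_um,
        section_thickness_um=stack.section_thickness_um,
        aligned=True,
        section_shifts_px=int_shifts,
        validity=validity,
        metadata=dict(stack.metadata),
    )


def register_stack(
    stack: SectionStack,
    reference_channel: str = CHANNEL_NUCLEI,
    sanity_fraction: float = 0.10,
    subpixel: bool = False,
) -> SectionStack:
    """Align a raw ribbon stack; see :func:`estimate_shifts`."""
    shifts = estimate_shifts(
        stack, reference_channel, sanity_fraction, subpixel=subpixel
    )
    return apply_shifts(stack, shifts)
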