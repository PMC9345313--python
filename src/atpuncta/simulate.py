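"""Synthetic serial-section ribbon simulator with full ground truth.

Generates multi-channel array-tomography-like volumes: a dense amyloid
plaque core with a diffuse halo and a radially decaying oligomer field
in the Aβ channel, a dense field of small synaptic puncta, two
populations of plaque-associated accumulations (focal spots 10–50 μm³
and larger amorphous deposits) placed at configurable distances from
the plaque core, per-section rigid misalignment, photon-like noise and
single-section speckle artifacts.  Every rendered object is recorded in
a ground-truth table so that detection, registration, co-localization
and distance-binning can be scored against a known answer.

Objects are rendered as soft-edged ellipsoids: a hard ellipsoidal
support (whose voxel count defines the true volume) with a narrow
linear intensity roll-off at the rim, approximating diffraction-limited
puncta without modelling optics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .stack import (
    CHANNEL_ABETA,
    CHANNEL_CSP,
    CHANNEL_NUCLEI,
    CHANNEL_SYP,
    SectionStack,
)

# volume classes (μm³) for plaque-associated accumulations: focal spots
# 10–50, amorphous deposits 50–100 and >100.  The default mixture
# mirrors the observed partition 56.4 / 22.6 / 14.8 % (rescaled to sum
# to one); it is a generator default, not a biological ground truth.
ACCUMULATION_CLASS_EDGES = (10.0, 50.0, 100.0, 330.0)
_RAW_MIX = np.array([0.564, 0.226, 0.148])
DEFAULT_VOLUME_MIXTURE = tuple(_RAW_MIX / _RAW_MIX.sum())


@dataclass(frozen=True)
class PlaqueSpec:
    """Amyloid plaque model for the Aβ channel."""

    kind: str = "neuritic-cored"  # neuritic-cored | diffuse | none
    core_radius_um: float = 5.0
    core_peak: float = 4000.0
    halo_radius_um: float = 12.0
    halo_peak: float = 400.0


@dataclass(frozen=True)
class OligomerFieldSpec:
    """Radially decaying soluble-oligomer intensity added to Aβ.

    The field decays exponentially with distance from the core edge and
    is clipped back to baseline beyond ``baseline_radius_um`` (default
    20 μm, the distance at which the oligomer halo returns to baseline).
    """

    baseline: float = 0.0
    peak: float = 300.0
    decay_length_um: float = 5.0
    baseline_radius_um: float = 20.0


@dataclass(frozen=True)
class SynapseFieldSpec:
    """Dense small pre-synaptic puncta in a given channel.

    Either ``count`` (fixed number) or ``density_per_um3`` (Poisson
    mean = density × stack volume) drives how many puncta are placed.
    The default density of 0.8 objects/μm³ is the order of magnitude of
    synapse density in human cortical neuropil.
    """

    channel: str = CHANNEL_SYP
    density_per_um3: float = 0.8
    count: int | None = None
    punctum_diameter_um: float = 0.5
    mean_intensity: float = 800.0
    intensity_sd: float = 200.0
    #: optional surface-to-surface separation (μm); None lets puncta
    #: overlap freely, as they do in dense neuropil
    min_separation_um: float | None = None


@dataclass(frozen=True)
class AccumulationSpec:
    """A population of plaque-associated accumulations in one channel.

    Volumes are drawn from a mixture over the three classes 10–50,
    50–100 and >100 μm³ (log-uniform within class); radial placement
    from the plaque-core centre follows a truncated normal with mode
    ``mode_distance_um`` and spread ``spread_um``.
    """

    channel: str = CHANNEL_CSP
    count: int = 20
    volume_mixture: tuple[float, float, float] = DEFAULT_VOLUME_MIXTURE
    mode_distance_um: float = 15.0
    spread_um: float = 5.0
    mean_intensity: float = 1200.0
    intensity_sd: float = 250.0
    #: minimum surface-to-surface separation (μm) between same-channel
    #: accumulations; None disables the exclusion entirely (objects may
    #: then merge).  Exclusion thins crowded regions, so it biases the
    #: radial placement law at high density.
    min_separation_um: float | None = 1.0


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian background plus signal-scaled Gaussian noise
    (approximating Poisson photon noise at moderate counts)."""

    background: float = 100.0
    background_sd: float = 50.0
    shot_scale: float = 1.0


@dataclass(frozen=True)
class ColocDesign:
    """Fraction of source-channel accumulations that are paired with a
    co-centred target-channel object (guaranteeing ≥10% voxel overlap)."""

    source: str = CHANNEL_CSP
    target: str = CHANNEL_SYP
    fraction: float = 0.0


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic ribbon."""

    shape: tuple[int, int, int] = (30, 512, 512)  # sections, rows, cols
    pixel_pitch_um: float = 0.1
    section_thickness_um: float = 0.07
    plaque: PlaqueSpec = field(default_factory=PlaqueSpec)
    oligomer: OligomerFieldSpec = field(default_factory=OligomerFieldSpec)
    synapses: tuple[SynapseFieldSpec, ...] = field(
        default_factory=lambda: (SynapseFieldSpec(),)
    )
    accumulations: tuple[AccumulationSpec, ...] = field(
        default_factory=lambda: (AccumulationSpec(),)
    )
    coloc: ColocDesign = field(default_factory=ColocDesign)
    max_shift_px: int = 0
    n_speckles: int = 0
    speckle_channel: str = CHANNEL_CSP
    nuclei_count: int | None = None
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        s, r, c = self.shape
        if min(s, r, c) < 1:
            raise ValueError("stack shape must be positive")
        if self.pixel_pitch_um <= 0 or self.section_thickness_um <= 0:
            raise ValueError("pixel pitch and section thickness must be > 0")
        for syn in self.synapses:
            if syn.density_per_um3 < 0:
                raise ValueError("synapse density must be >= 0")
            if syn.punctum_diameter_um <= 0:
                raise ValueError("punctum diameter must be > 0")
        for acc in self.accumulations:
            w = np.asarray(acc.volume_mixture, dtype=float)
            if acc.count < 0:
                raise ValueError("accumulation count must be >= 0")
            if acc.count > 0 and abs(w.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"volume mixture weights must sum to 1, got {w.sum()!r}"
                )
        if not 0.0 <= self.coloc.fraction <= 1.0:
            raise ValueError("co-localization fraction must lie in [0, 1]")
        if self.plaque.kind not in ("neuritic-cored", "diffuse", "none"):
            raise ValueError(f"unknown plaque kind {self.plaque.kind!r}")
        if self.plaque.kind != "none":
            half_lat = 0.5 * min(r, c) * self.pixel_pitch_um
            if self.plaque.core_radius_um >= half_lat:
                raise ValueError(
                    "plaque core radius "
                    f"{self.plaque.core_radius_um} μm does not fit in a stack "
                    f"of half lateral extent {half_lat} μm"
                )
        if self.max_shift_px < 0 or self.n_speckles < 0:
            raise ValueError("max shift and speckle count must be >= 0")

    @property
    def extent_um(self) -> tuple[float, float, float]:
        s, r, c = self.shape
        return (
            s * self.section_thickness_um,
            r * self.pixel_pitch_um,
            c * self.pixel_pitch_um,
        )

    @property
    def volume_um3(self) -> float:
        ez, ey, ex = self.extent_um
        return ez * ey * ex


@dataclass
class GroundTruth:
    """Simulator-emitted object table plus per-section shift metadata."""

    objects: pd.DataFrame
    section_shifts_px: np.ndarray  # (sections, 2) int, applied (dy, dx)
    plaque_centroid_um: tuple[float, float, float] | None
    seed: int

    COLUMNS = (
        "id",
        "channel",
        "klass",
        "z_um",
        "y_um",
        "x_um",
        "volume_um3",
        "distance_um",
        "sections",
        "coloc_with",
    )

    def of_class(self, klass: str) -> pd.DataFrame:
        return self.objects[self.objects["klass"] == klass]

    def of_channel(self, channel: str) -> pd.DataFrame:
        return self.objects[self.objects["channel"] == channel]


# ---------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------

def render_distance_field(
    config: SimulationConfig, centroid_um: tuple[float, float, float]
) -> np.ndarray:
    """Per-voxel anisotropy-corrected Euclidean distance (μm) from a point.

    Distances are measured from voxel centres; the supplied centroid
    must lie inside the stack.
    """
    ez, ey, ex = config.extent_um
    cz, cy, cx = centroid_um
    if not (0 <= cz <= ez and 0 <= cy <= ey and 0 <= cx <= ex):
        raise ValueError(f"centroid {centroid_um} lies outside the stack")
    return _distance_field(config.shape, config.section_thickness_um,
                           config.pixel_pitch_um, centroid_um)


def _distance_field(shape, dz, dxy, centroid_um, dtype=np.float64):
    s, r, c = shape
    z = ((np.arange(s) * dz - centroid_um[0]) ** 2).astype(dtype)
    y = ((np.arange(r) * dxy - centroid_um[1]) ** 2).astype(dtype)
    x = ((np.arange(c) * dxy - centroid_um[2]) ** 2).astype(dtype)
    return np.sqrt(z[:, None, None] + y[None, :, None] + x[None, None, :])


def _render_ellipsoid(vol, center_vox, semi_axes_vox, amplitude, edge=0.15):
    """Draw a soft-edged ellipsoid; returns (voxel count, centroid_vox, span).

    The hard support (normalised radius ρ ≤ 1) defines the true object
    mask; intensity rolls off linearly over ``edge`` in ρ outside it.
    Intensities combine with the existing volume by maximum.
    """
    cz, cy, cx = center_vox
    az, ay, ax = semi_axes_vox
    S, R, C = vol.shape
    z0, z1 = max(0, int(math.floor(cz - az * (1 + edge)))), min(
        S, int(math.ceil(cz + az * (1 + edge))) + 1
    )
    y0, y1 = max(0, int(math.floor(cy - ay * (1 + edge)))), min(
        R, int(math.ceil(cy + ay * (1 + edge))) + 1
    )
    x0, x1 = max(0, int(math.floor(cx - ax * (1 + edge)))), min(
        C, int(math.ceil(cx + ax * (1 + edge))) + 1
    )
    if z0 >= z1 or y0 >= y1 or x0 >= x1:
        return 0, None, 0
    zz = (np.arange(z0, z1) - cz) / az
    yy = (np.arange(y0, y1) - cy) / ay
    xx = (np.arange(x0, x1) - cx) / ax
    rho = np.sqrt(
        zz[:, None, None] ** 2 + yy[None, :, None] ** 2 + xx[None, None, :] ** 2
    )
    soft = np.clip((1.0 + edge - rho) / edge, 0.0, 1.0)
    sub = vol[z0:z1, y0:y1, x0:x1]
    np.maximum(sub, amplitude * soft, out=sub)
    mask = rho <= 1.0
    n = int(mask.sum())
    if n == 0:
        return 0, None, 0
    idx = np.nonzero(mask)
    centroid = (
        idx[0].mean() + z0,
        idx[1].mean() + y0,
        idx[2].mean() + x0,
    )
    span = int(np.unique(idx[0]).size)
    return n, centroid, span


def _sphere_radius(volume_um3: float) -> float:
    return (3.0 * volume_um3 / (4.0 * math.pi)) ** (1.0 / 3.0)


# ---------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------

class _Placer:
    """Rejection-sampling placement that keeps same-channel objects apart."""

    def __init__(self, config: SimulationConfig, rng: np.random.Generator):
        self.cfg = config
        self.rng = rng
        self.placed: dict[str, list[tuple[np.ndarray, float]]] = {}

    def _ok(self, channel, pos_um, radius_um, clearance):
        if clearance is None:
            return True
        for other, r in self.placed.get(channel, []):
            if np.linalg.norm(other - pos_um) < radius_um + r + clearance:
                return False
        return True

    def _ok_multi(self, channels, pos_um, radius_um, clearance):
        return all(self._ok(ch, pos_um, radius_um, clearance) for ch in channels)

    def record(self, channel, pos_um, radius_um):
        self.placed.setdefault(channel, []).append((np.asarray(pos_um), radius_um))

    def uniform(self, channel, radius_lat_um, radius_ax_um, clearance=1.0,
                tries=2000, avoid_channels=(), cross_clearance=0.2):
        """Uniform lateral placement with margins; z keeps the object inside."""
        ez, ey, ex = self.cfg.extent_um
        for _ in range(tries):
            z = self.rng.uniform(min(radius_ax_um, ez / 2), max(ez - radius_ax_um, ez / 2))
            y = self.rng.uniform(radius_lat_um, max(ey - radius_lat_um, radius_lat_um))
            x = self.rng.uniform(radius_lat_um, max(ex - radius_lat_um, radius_lat_um))
            pos = np.array([z, y, x])
            if not self._ok(channel, pos, radius_lat_um, clearance):
                continue
            if not self._ok_multi(avoid_channels, pos, radius_lat_um, cross_clearance):
                continue
            return pos
        raise RuntimeError(
            f"could not place an object of radius {radius_lat_um:.2f} μm in the "
            f"{channel} channel; the stack is too crowded or too small"
        )

    def radial(self, channel, origin_um, mode_um, spread_um, radius_lat_um,
               radius_ax_um, clearance=1.0, tries=2000,
               avoid_channels=(), cross_clearance=0.2):
        """Place at a truncated-normal distance from ``origin_um``.

        The sampled distance is realised exactly in 3D: a small axial
        offset is drawn first (bounded by the stack depth), the lateral
        offset makes up the remainder, at a uniform lateral angle.
        """
        ez, ey, ex = self.cfg.extent_um
        oz, oy, ox = origin_um
        for _ in range(tries):
            d = self.rng.normal(mode_um, spread_um)
            if d <= 0:
                continue
            dz_max = min(d, oz - radius_ax_um, ez - radius_ax_um - oz)
            dz = self.rng.uniform(-dz_max, dz_max) if dz_max > 0 else 0.0
            lat = math.sqrt(max(d * d - dz * dz, 0.0))
            theta = self.rng.uniform(0, 2 * math.pi)
            pos = np.array([oz + dz, oy + lat * math.sin(theta), ox + lat * math.cos(theta)])
            if not (radius_lat_um <= pos[1] <= ey - radius_lat_um
                    and radius_lat_um <= pos[2] <= ex - radius_lat_um):
                continue
            if not (0 <= pos[0] <= ez):
                continue
            if self._ok(channel, pos, radius_lat_um, clearance) and self._ok_multi(
                avoid_channels, pos, radius_lat_um, cross_clearance
            ):
                return pos, d
        raise RuntimeError(
            f"could not place a radial object (mode {mode_um} μm) in the "
            f"{channel} channel; enlarge the stack or reduce the count"
        )


def _accumulation_semi_axes(volume_um3, config):
    """Semi-axes (μm) of an ellipsoid of the target volume that fits the
    shallow stack: the axial semi-axis is capped at 40% of the stack
    depth (deposits extend beyond the imaged ribbon in practice) and the
    lateral semi-axes absorb the remainder."""
    ez = config.extent_um[0]
    r_iso = _sphere_radius(volume_um3)
    c = min(r_iso, 0.40 * ez)
    a = math.sqrt(3.0 * volume_um3 / (4.0 * math.pi * c))
    return a, c


def simulate_ribbon(config: SimulationConfig) -> tuple[SectionStack, GroundTruth]:
    """Render one synthetic ribbon and its ground-truth table.

    Returns the (misaligned, noisy) :class:`SectionStack` together with
    a :class:`GroundTruth` whose coordinates refer to the aligned
    geometry (i.e. before per-section shifts are applied).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    S, R, C = config.shape
    dz, dxy = config.section_thickness_um, config.pixel_pitch_um
    vox = np.array([dz, dxy, dxy])
    voxvol = dz * dxy * dxy

    volumes = {ch: np.zeros((S, R, C), dtype=np.float32) for ch in
               (CHANNEL_ABETA, CHANNEL_CSP, CHANNEL_SYP, CHANNEL_NUCLEI)}
    rows: list[dict] = []
    next_id = 0
    placer = _Placer(config, rng)

    # -- plaque --------------------------------------------------------
    plaque_centroid_um = None
    if config.plaque.kind != "none":
        ez, ey, ex = config.extent_um
        centre = np.array([ez / 2, ey / 2, ex / 2])
        plaque_centroid_um = tuple(float(v) for v in centre)
        dfield = _distance_field(config.shape, dz, dxy, centre, dtype=np.float32)
        if config.plaque.kind == "neuritic-cored":
            c_ax, c_lat = 0.45 * ez, config.plaque.core_radius_um
            n, cen, span = _render_ellipsoid(
                volumes[CHANNEL_ABETA], centre / vox,
                (c_ax / dz, c_lat / dxy, c_lat / dxy), config.plaque.core_peak,
            )
            rows.append(dict(
                id=next_id, channel=CHANNEL_ABETA, klass="plaque_core",
                z_um=cen[0] * dz, y_um=cen[1] * dxy, x_um=cen[2] * dxy,
                volume_um3=n * voxvol, distance_um=0.0, sections=span,
                coloc_with="",
            ))
            next_id += 1
        # diffuse halo: smooth radial profile, present for both kinds
        halo = np.float32(config.plaque.halo_peak) * np.exp(
            -np.maximum(dfield - np.float32(config.plaque.core_radius_um), 0.0)
            / np.float32(max(config.plaque.halo_radius_um / 3.0, 1e-6))
        )
        if config.plaque.kind == "diffuse":
            rows.append(dict(
                id=next_id, channel=CHANNEL_ABETA, klass="diffuse_plaque",
                z_um=plaque_centroid_um[0], y_um=plaque_centroid_um[1],
                x_um=plaque_centroid_um[2],
                volume_um3=float((halo > 0.5 * config.plaque.halo_peak).sum()) * voxvol,
                distance_um=0.0, sections=S, coloc_with="",
            ))
            next_id += 1
        np.maximum(volumes[CHANNEL_ABETA], halo, out=volumes[CHANNEL_ABETA])
        # oligomer field: exponential decay from the core edge, back to
        # baseline beyond baseline_radius_um
        og = config.oligomer
        fld = np.float32(og.baseline) + np.float32(og.peak - og.baseline) * np.exp(
            -np.maximum(dfield - np.float32(config.plaque.core_radius_um), 0.0)
            / np.float32(max(og.decay_length_um, 1e-6))
        )
        fld[dfield >= og.baseline_radius_um] = og.baseline
        np.maximum(volumes[CHANNEL_ABETA], fld, out=volumes[CHANNEL_ABETA])
        placer.record(CHANNEL_ABETA, centre, config.plaque.core_radius_um)

    # -- nuclei (registration landmarks) -------------------------------
    ez, ey, ex = config.extent_um
    n_nuclei = config.nuclei_count
    if n_nuclei is None:
        n_nuclei = max(3, int(round(ey * ex / 400.0)))
    for _ in range(n_nuclei):
        r_lat = rng.uniform(2.5, 4.0)
        try:
            pos = placer.uniform(CHANNEL_NUCLEI, r_lat, ez / 2, clearance=0.0)
        except RuntimeError:
            break
        _render_ellipsoid(volumes[CHANNEL_NUCLEI], pos / vox,
                          (max(S, 2.0), r_lat / dxy, r_lat / dxy),
                          rng.uniform(800.0, 1500.0))
        placer.record(CHANNEL_NUCLEI, pos, r_lat)

    # -- accumulations --------------------------------------------------
    acc_positions: list[tuple[np.ndarray, float]] = []
    coloc_src_rows: list[int] = []
    acc_channels = {s.channel for s in config.accumulations}
    if config.coloc.fraction > 0:
        acc_channels |= {config.coloc.source, config.coloc.target}
    for spec in config.accumulations:
        # keep unpaired accumulations clear of the other channels'
        # accumulations so only the designed pairs share voxels
        avoid = tuple(acc_channels - {spec.channel})
        edges = ACCUMULATION_CLASS_EDGES
        w = np.asarray(spec.volume_mixture, dtype=float)
        for _ in range(spec.count):
            # if a drawn volume cannot be placed (a large deposit in a
            # crowded or small field), redraw the volume: the requested
            # count is always honoured, at the price of a slightly
            # lighter upper tail of the volume mixture in small stacks
            for attempt in range(30):
                k = rng.choice(3, p=w)
                lo, hi = edges[k], edges[k + 1]
                v_target = math.exp(rng.uniform(math.log(lo), math.log(hi)))
                a, c = _accumulation_semi_axes(v_target, config)
                try:
                    if plaque_centroid_um is not None:
                        pos, _ = placer.radial(
                            spec.channel, np.asarray(plaque_centroid_um),
                            spec.mode_distance_um, spec.spread_um, a, c,
                            clearance=spec.min_separation_um,
                            avoid_channels=avoid,
                        )
                    else:
                        pos = placer.uniform(
                            spec.channel, a, c,
                            clearance=spec.min_separation_um,
                            avoid_channels=avoid,
                        )
                    break
                except RuntimeError:
                    if attempt == 29:
                        raise
            amp = max(rng.normal(spec.mean_intensity, spec.intensity_sd), 50.0)
            n, cen, span = _render_ellipsoid(
                volumes[spec.channel], pos / vox, (c / dz, a / dxy, a / dxy), amp
            )
            if n == 0:
                continue
            cen_um = np.array(cen) * vox
            dist = (
                float(np.linalg.norm(cen_um - np.asarray(plaque_centroid_um)))
                if plaque_centroid_um is not None
                else np.nan
            )
            rows.append(dict(
                id=next_id, channel=spec.channel,
                klass="focal_spot" if v_target < 50.0 else "amorphous_deposit",
                z_um=cen_um[0], y_um=cen_um[1], x_um=cen_um[2],
                volume_um3=n * voxvol, distance_um=dist, sections=span,
                coloc_with="",
            ))
            placer.record(spec.channel, pos, a)
            if spec.channel == config.coloc.source:
                acc_positions.append((pos, a))
                coloc_src_rows.append(len(rows) - 1)
            next_id += 1

    # -- designed co-localization ---------------------------------------
    # a chosen fraction of source-channel accumulations receive a
    # co-centred target-channel partner of equal shape, making the
    # fractional voxel overlap ≈ 1 (comfortably above the 10% criterion);
    # remaining source objects are kept clear of target objects.
    if config.coloc.fraction > 0 and acc_positions:
        n_pair = int(round(config.coloc.fraction * len(acc_positions)))
        chosen = rng.choice(len(acc_positions), size=n_pair, replace=False)
        for i in chosen:
            pos, a = acc_positions[i]
            src_row = rows[coloc_src_rows[i]]
            c = min(_sphere_radius(src_row["volume_um3"]), 0.40 * ez)
            amp = max(rng.normal(1000.0, 200.0), 50.0)
            n, cen, span = _render_ellipsoid(
                volumes[config.coloc.target], pos / vox,
                (c / dz, a / dxy, a / dxy), amp,
            )
            if n == 0:
                continue
            cen_um = np.array(cen) * vox
            dist = (
                float(np.linalg.norm(cen_um - np.asarray(plaque_centroid_um)))
                if plaque_centroid_um is not None
                else np.nan
            )
            rows.append(dict(
                id=next_id, channel=config.coloc.target,
                klass="focal_spot" if n * voxvol < 50.0 else "amorphous_deposit",
                z_um=cen_um[0], y_um=cen_um[1], x_um=cen_um[2],
                volume_um3=n * voxvol, distance_um=dist, sections=span,
                coloc_with=config.coloc.source,
            ))
            src_row["coloc_with"] = config.coloc.target
            placer.record(config.coloc.target, pos, a)
            next_id += 1

    # -- synaptic puncta -------------------------------------------------
    for syn in config.synapses:
        if syn.count is not None:
            n_syn = syn.count
        else:
            n_syn = int(rng.poisson(syn.density_per_um3 * config.volume_um3))
        r = syn.punctum_diameter_um / 2.0
        for _ in range(n_syn):
            if syn.min_separation_um is not None:
                z, y, x = placer.uniform(syn.channel, r, r,
                                         clearance=syn.min_separation_um)
            else:
                # dense fields are allowed to overlap: uniform placement
                # with margins only, no clearance rejection
                z = rng.uniform(min(r, ez / 2), max(ez - r, ez / 2))
                y = rng.uniform(r, max(ey - r, r))
                x = rng.uniform(r, max(ex - r, r))
            amp = max(rng.normal(syn.mean_intensity, syn.intensity_sd), 50.0)
            n, cen, span = _render_ellipsoid(
                volumes[syn.channel], np.array([z, y, x]) / vox,
                (r / dz, r / dxy, r / dxy), amp,
            )
            if n == 0:
                continue
            cen_um = np.array(cen) * vox
            dist = (
                float(np.linalg.norm(cen_um - np.asarray(plaque_centroid_um)))
                if plaque_centroid_um is not None
                else np.nan
            )
            rows.append(dict(
                id=next_id, channel=syn.channel, klass="synapse",
                z_um=cen_um[0], y_um=cen_um[1], x_um=cen_um[2],
                volume_um3=n * voxvol, distance_um=dist, sections=span,
                coloc_with="",
            ))
            placer.record(syn.channel, np.array([z, y, x]), r)
            next_id += 1

    # -- single-section speckle artifacts --------------------------------
    for _ in range(config.n_speckles):
        s_idx = int(rng.integers(0, S))
        r_px = rng.uniform(2.0, 4.0)
        # keep speckles clear of same-channel multi-section objects so
        # that a speckle never fuses with a persistent component
        for _try in range(200):
            y = rng.uniform(r_px, R - 1 - r_px)
            x = rng.uniform(r_px, C - 1 - r_px)
            pos_um = np.array([s_idx * dz, y * dxy, x * dxy])
            if placer._ok(config.speckle_channel, pos_um, r_px * dxy, 0.5):
                break
        yy = (np.arange(R) - y) / r_px
        xx = (np.arange(C) - x) / r_px
        rho = np.sqrt(yy[:, None] ** 2 + xx[None, :] ** 2)
        disk = rho <= 1.0
        amp = rng.uniform(1500.0, 3000.0)
        plane = volumes[config.speckle_channel][s_idx]
        np.maximum(plane, np.float32(amp) * disk.astype(np.float32), out=plane)
        rows.append(dict(
            id=next_id, channel=config.speckle_channel, klass="speckle",
            z_um=s_idx * dz, y_um=y * dxy, x_um=x * dxy,
            volume_um3=float(disk.sum()) * voxvol, distance_um=np.nan,
            sections=1, coloc_with="",
        ))
        placer.record(config.speckle_channel, pos_um, r_px * dxy)
        next_id += 1

    # -- per-section misalignment ---------------------------------------
    shifts = np.zeros((S, 2), dtype=int)
    if config.max_shift_px > 0:
        shifts[1:] = rng.integers(
            -config.max_shift_px, config.max_shift_px + 1, size=(S - 1, 2)
        )
        for ch, vol in volumes.items():
            volumes[ch] = _apply_section_shifts(vol, shifts)

    # -- noise -----------------------------------------------------------
    nz = config.noise
    for ch, vol in volumes.items():
        noisy = vol + np.float32(nz.background)
        if nz.background_sd > 0:
            noisy += rng.standard_normal(vol.shape, dtype=np.float32) * np.float32(
                nz.background_sd
            )
        if nz.shot_scale > 0:
            noisy += rng.standard_normal(vol.shape, dtype=np.float32) * (
                np.float32(nz.shot_scale) * np.sqrt(vol)
            )
        np.maximum(noisy, np.float32(0.0), out=noisy)
        volumes[ch] = noisy

    objects = pd.DataFrame(rows, columns=list(GroundTruth.COLUMNS))
    gt = GroundTruth(
        objects=objects,
        section_shifts_px=shifts,
        plaque_centroid_um=plaque_centroid_um,
        seed=config.seed,
    )
    stack = SectionStack(
        channels=volumes,
        pixel_pitch_um=dxy,
        section_thickness_um=dz,
        aligned=config.max_shift_px == 0,
        metadata={"seed": config.seed},
    )
    return stack, gt


def _apply_section_shifts(vol: np.ndarray, shifts: np.ndarray) -> np.ndarray:
    """Translate each section by its (dy, dx) shift with zero fill."""
    out = np.zeros_like(vol)
    R, C = vol.shape[1:]
    for s, (dy, dx) in enumerate(shifts):
        ys0, ys1 = max(0, dy), min(R, R + dy)
        xs0, xs1 = max(0, dx), min(C, C + dx)
        yo0, yo1 = max(0, -dy), min(R, R - dy)
        xo0, xo1 = max(0, -dx), min(C, C - dx)
        out[s, ys0:ys1, xs0:xs1] = vol[s, yo0:yo1, xo0:xo1]
    return out
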