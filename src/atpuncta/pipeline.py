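"""End-to-end orchestration: simulate → register → segment → quantify →
spatial → stats, with a run manifest for reproducibility.

A run is described by one YAML/JSON document with per-stage blocks; all
numeric parameters used by any stage are logged to the manifest, and a
rerun from the same config and seed reproduces deterministic stage
outputs bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .quantify import (
    OVERLAP_FRACTION,
    VOLUME_GATE_UM3,
    colocalize,
    density_per_mm3,
    label_objects,
    objects_to_frame,
)
from .register import register_stack
from .segment import binarize, persistence_filter, segment_plaque_core
from .simulate import (
    AccumulationSpec,
    ColocDesign,
    NoiseSpec,
    OligomerFieldSpec,
    PlaqueSpec,
    SimulationConfig,
    SynapseFieldSpec,
    simulate_ribbon,
)
from .spatial import DEFAULT_BIN_EDGES, bin_by_distance
from .stack import CHANNEL_ABETA, CHANNEL_CSP, CHANNEL_NUCLEI, CHANNEL_SYP
from .stats import fit_group_model, transform

log = logging.getLogger("atpuncta")


@dataclass
class AnalysisParams:
    """Per-stage tunables, all logged to the manifest."""

    reference_channel: str = CHANNEL_NUCLEI
    threshold_methods: tuple[str, ...] = ("otsu", "triangle")
    combine: str = "union"
    plaque_threshold_fraction: float = 0.5
    overlap_threshold: float = OVERLAP_FRACTION
    volume_gate_um3: float = VOLUME_GATE_UM3
    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES
    distance_mode: str = "centroid"
    analysis_channels: tuple[str, ...] = (CHANNEL_CSP, CHANNEL_SYP)
    coloc_pairs: tuple[tuple[str, str], ...] = (
        (CHANNEL_CSP, CHANNEL_SYP),
        (CHANNEL_CSP, CHANNEL_ABETA),
    )


@dataclass
class StackResult:
    """All per-stack stage outputs."""

    stack_id: str
    case_id: str
    group: str
    objects: dict[str, list]
    densities: dict[str, float]
    coloc: dict[str, object]
    binned: dict[str, object]
    has_core: bool
    warnings: list[str] = field(default_factory=list)


def simulation_config_from_dict(d: dict | None, seed: int = 0) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a nested plain-dict block."""
    d = dict(d or {})
    kwargs: dict = {}
    if "shape" in d:
        kwargs["shape"] = tuple(int(v) for v in d.pop("shape"))
    sub = {
        "plaque": PlaqueSpec,
        "oligomer": OligomerFieldSpec,
        "noise": NoiseSpec,
        "coloc": ColocDesign,
    }
    for key, cls in sub.items():
        if key in d:
            kwargs[key] = cls(**d.pop(key))
    if "synapses" in d:
        kwargs["synapses"] = tuple(
            SynapseFieldSpec(**s) for s in d.pop("synapses")
        )
    if "accumulations" in d:
        kwargs["accumulations"] = tuple(
            AccumulationSpec(**a) for a in d.pop("accumulations")
        )
    kwargs.update(d)
    kwargs.setdefault("seed", seed)
    return SimulationConfig(**kwargs)


def analyse_stack(
    stack,
    params: AnalysisParams,
    stack_id: str = "stack",
    case_id: str = "case",
    group: str = "",
) -> StackResult:
    """Run register → segment → quantify → spatial on one stack."""
    captured: list[str] = []
    t0 = time.time()
    if not stack.aligned and stack.n_sections >= 2:
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            stack = register_stack(stack, params.reference_channel)
        captured += [str(w.message) for w in wlist]
    valid_mm3 = stack.valid_volume_mm3()

    core = segment_plaque_core(
        stack.channels[CHANNEL_ABETA],
        stack,
        threshold_fraction=params.plaque_threshold_fraction,
    )

    objects: dict[str, list] = {}
    masks = {}
    for ch in set(params.analysis_channels) | {c for p in params.coloc_pairs for c in p}:
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            b = binarize(
                stack.channels[ch], stack,
                methods=params.threshold_methods, combine=params.combine,
                channel=ch,
            )
        captured += [str(w.message) for w in wlist]
        b = persistence_filter(b)
        masks[ch] = b
        objects[ch] = [
            o for o in label_objects(b, gate_um3=params.volume_gate_um3)
            if o.klass != "sub_gate"
        ]

    densities = {
        ch: density_per_mm3(len(objects[ch]), valid_mm3)
        for ch in params.analysis_channels
    }
    coloc = {}
    for src, tgt in params.coloc_pairs:
        summary = colocalize(
            objects[src], masks[tgt],
            overlap_threshold=params.overlap_threshold, target_channel=tgt,
        )
        coloc[f"{src}__{tgt}"] = summary

    binned = {}
    if core.has_core:
        for ch in params.analysis_channels:
            binned[ch] = bin_by_distance(
                objects[ch], core, stack.validity, stack.voxel_volume_um3,
                bin_edges=params.bin_edges, mode=params.distance_mode,
            )
    log.info(
        "stack %s (case %s, group %s): %s objects, core=%s, %.1fs",
        stack_id, case_id, group,
        {ch: len(o) for ch, o in objects.items()}, core.has_core,
        time.time() - t0,
    )
    return StackResult(
        stack_id=stack_id,
        case_id=case_id,
        group=group,
        objects=objects,
        densities=densities,
        coloc=coloc,
        binned=binned,
        has_core=core.has_core,
        warnings=captured,
    )


def run_pipeline(config: dict | str | Path, output_dir: str | Path | None = None) -> dict:
    """Execute a full simulated-cohort run from a config document.

    Returns the manifest dict; writes object tables, binned densities,
    co-localization summaries, model contrasts and the manifest itself
    under the configured output directory.
    """
    if not isinstance(config, dict):
        config = io.load_yaml(config)
    out = Path(output_dir or config.get("output_dir", "atpuncta_run"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    params = AnalysisParams(**{
        k: tuple(v) if isinstance(v, list) else v
        for k, v in (config.get("analysis") or {}).items()
    })
    groups = config.get("groups")
    if not groups:
        raise ValueError("config must define at least one group of stacks")

    manifest: dict = {
        "software": {"name": "atpuncta", "version": __version__},
        "seed": seed,
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "analysis_params": dataclasses.asdict(params),
        "stacks": [],
        "outputs": {},
        "warnings": [],
    }

    results: list[StackResult] = []
    ss = np.random.SeedSequence(seed)
    for gi, grp in enumerate(groups):
        name = grp.get("name", f"group{gi}")
        n_cases = int(grp.get("n_cases", 1))
        per_case = int(grp.get("stacks_per_case", 1))
        for ci in range(n_cases):
            case_id = f"{name}_case{ci}"
            for si in range(per_case):
                stack_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
                sim_cfg = simulation_config_from_dict(
                    grp.get("simulation"), seed=stack_seed
                )
                stack_id = f"{case_id}_s{si}"
                try:
                    stack, gt = simulate_ribbon(sim_cfg)
                    res = analyse_stack(stack, params, stack_id, case_id, name)
                except Exception as exc:  # abort with stage context
                    (out / "FAILED").write_text(f"{stack_id}: {exc}\n")
                    raise RuntimeError(
                        f"pipeline failed on stack {stack_id!r}: {exc}"
                    ) from exc
                results.append(res)
                manifest["stacks"].append(
                    {"stack_id": stack_id, "case": case_id, "group": name,
                     "sim_seed": stack_seed}
                )
                manifest["warnings"] += [
                    f"{stack_id}: {w}" for w in res.warnings
                ]

    # -- tidy per-stack tables -----------------------------------------
    obs_rows, coloc_rows, bin_rows = [], [], []
    for res in results:
        for ch, dens in res.densities.items():
            obs_rows.append(dict(
                stack=res.stack_id, case=res.case_id, group=res.group,
                channel=ch, response=dens, measure="density_per_mm3",
            ))
        for pair, summ in res.coloc.items():
            coloc_rows.append(dict(
                stack=res.stack_id, case=res.case_id, group=res.group,
                pair=pair, n_objects=summ.n_objects,
                n_colocalized=summ.n_colocalized,
                percentage=summ.percentage,
            ))
        for ch, bd in res.binned.items():
            f = bd.to_frame()
            f.insert(0, "channel", ch)
            f.insert(0, "group", res.group)
            f.insert(0, "case", res.case_id)
            f.insert(0, "stack", res.stack_id)
            bin_rows.append(f)

    obs = pd.DataFrame(obs_rows)
    obs.to_csv(out / "densities.csv", index=False)
    pd.DataFrame(coloc_rows).to_csv(out / "colocalization.csv", index=False)
    if bin_rows:
        pd.concat(bin_rows, ignore_index=True).to_csv(
            out / "binned_densities.csv", index=False
        )
    all_objects = pd.concat(
        [
            objects_to_frame(sum(res.objects.values(), [])).assign(
                stack=res.stack_id
            )
            for res in results
        ],
        ignore_index=True,
    )
    all_objects.to_csv(out / "objects.csv", index=False)

    # -- group statistics ----------------------------------------------
    stats_cfg = config.get("stats") or {}
    contrast_frames = []
    if len({r.group for r in results}) >= 2:
        for ch in params.analysis_channels:
            sub = obs[obs["channel"] == ch].copy()
            method = stats_cfg.get("transform")
            if method:
                tr = transform(
                    sub["response"].to_numpy(),
                    method=method,
                    lambda_selection=stats_cfg.get(
                        "lambda_selection", "log-likelihood"
                    ),
                    shift=stats_cfg.get("shift"),
                )
                sub["response"] = tr.values
            fitres = fit_group_model(
                sub, response="response", fixed="group", case="case",
                aggregate=stats_cfg.get("aggregate"),
            )
            f = fitres.to_frame()
            f.insert(0, "channel", ch)
            f["singular"] = fitres.singular
            contrast_frames.append(f)
        pd.concat(contrast_frames, ignore_index=True).to_csv(
            out / "contrasts.csv", index=False
        )
        manifest["outputs"]["contrasts"] = str(out / "contrasts.csv")

    manifest["outputs"].update(
        {
            "densities": str(out / "densities.csv"),
            "colocalization": str(out / "colocalization.csv"),
            "objects": str(out / "objects.csv"),
        }
    )
    if bin_rows:
        manifest["outputs"]["binned_densities"] = str(out / "binned_densities.csv")
    io.save_json(manifest, out / "manifest.json")
    return manifest
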