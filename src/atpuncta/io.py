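"""Reading and writing stacks, ground truth and configs.

Stacks are stored as multi-page TIFF with axes ``CZYX`` and a JSON
metadata block (channel names, voxel geometry, seed) in the shaped-TIFF
description, via :mod:`tifffile`.  Ground-truth object tables travel as
CSV with the documented header, configs as YAML.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .simulate import GroundTruth, SimulationConfig
from .stack import SectionStack


def save_stack(stack: SectionStack, path: str | Path) -> Path:
    """Write a multi-channel stack to one multi-page TIFF (axes CZYX).

    Files named ``*.ome.tif(f)`` are written as OME-TIFF with channel
    names and physical voxel sizes in the OME header; other names get a
    shaped TIFF with an equivalent JSON metadata block.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    names = list(stack.channel_names)
    data = np.stack([stack.channels[ch] for ch in names])
    extra = {
        "aligned": bool(stack.aligned),
        "seed": stack.metadata.get("seed"),
    }
    if ".ome." in path.name.lower():
        tifffile.imwrite(
            path,
            data,
            ome=True,
            metadata={
                "axes": "CZYX",
                "Channel": {"Name": names},
                "PhysicalSizeX": stack.pixel_pitch_um,
                "PhysicalSizeXUnit": "µm",
                "PhysicalSizeY": stack.pixel_pitch_um,
                "PhysicalSizeYUnit": "µm",
                "PhysicalSizeZ": stack.section_thickness_um,
                "PhysicalSizeZUnit": "µm",
                "Description": json.dumps(extra),
            },
        )
    else:
        tifffile.imwrite(
            path,
            data,
            metadata={
                "axes": "CZYX",
                "channel_names": names,
                "pixel_pitch_um": stack.pixel_pitch_um,
                "section_thickness_um": stack.section_thickness_um,
                **extra,
            },
        )
    return path


def load_stack(path: str | Path) -> SectionStack:
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        if tif.ome_metadata:
            meta = _parse_ome(tif.ome_metadata)
        elif tif.shaped_metadata:
            meta = dict(tif.shaped_metadata[0])
        else:
            meta = {}
    if data.ndim == 3:
        data = data[None]
    names = meta.get("channel_names") or [f"ch{i}" for i in range(data.shape[0])]
    stack = SectionStack(
        channels={ch: np.asarray(data[i]) for i, ch in enumerate(names)},
        pixel_pitch_um=float(meta.get("pixel_pitch_um", 0.1)),
        section_thickness_um=float(meta.get("section_thickness_um", 0.07)),
        aligned=bool(meta.get("aligned", False)),
    )
    if meta.get("seed") is not None:
        stack.metadata["seed"] = meta["seed"]
    return stack


def _parse_ome(xml: str) -> dict:
    """Extract channel names, voxel sizes and the JSON description."""
    from xml.etree import ElementTree

    root = ElementTree.fromstring(xml)

    def findall(tag):
        return [e for e in root.iter() if e.tag.rsplit("}", 1)[-1] == tag]

    meta: dict = {}
    pixels = findall("Pixels")
    if pixels:
        attr = pixels[0].attrib
        if "PhysicalSizeX" in attr:
            meta["pixel_pitch_um"] = float(attr["PhysicalSizeX"])
        if "PhysicalSizeZ" in attr:
            meta["section_thickness_um"] = float(attr["PhysicalSizeZ"])
    channels = [c.attrib.get("Name") for c in findall("Channel")]
    if channels and all(channels):
        meta["channel_names"] = channels
    descr = findall("Description")
    if descr and descr[0].text:
        try:
            meta.update(json.loads(descr[0].text))
        except (ValueError, TypeError):
            pass
    return meta


def save_mask(mask: np.ndarray, path: str | Path) -> Path:
    """Write a boolean volume as an 8-bit (0/255) multi-page TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, (np.asarray(mask, bool) * np.uint8(255)),
                     photometric="minisblack")
    return path


def load_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)) > 0


def save_ground_truth(gt: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    gt.objects.to_csv(path, index=False)
    return path


def load_ground_truth_objects(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, keep_default_na=False, na_values=[""])


def save_shift_table(shifts: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"section": np.arange(len(shifts)),
         "dy_px": shifts[:, 0], "dx_px": shifts[:, 1]}
    ).to_csv(path, index=False)
    return path


def _as_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_as_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def save_config(config: SimulationConfig | dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(_as_plain(config), sort_keys=False))
    return path


def load_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def save_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_as_plain(obj), indent=2, default=str))
    return path
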