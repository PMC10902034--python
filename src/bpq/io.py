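"""File round-trips for grids, partitions, designs and curves.

Masks and label maps travel as TIFF (uint8) with a JSON sidecar carrying
pixel size and origin; designs and layouts as YAML/JSON; indentation
curves as CSV with a ``delta_m, force_N`` header.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .afm import IndentationCurve
from .geometry import StructureDesign, WellLayout, build_y_design
from .grid import ImageGrid, LabeledPartition


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_grid(path: str | Path, grid: ImageGrid) -> None:
    path = Path(path)
    pixels = np.asarray(grid.pixels)
    if pixels.dtype == bool:
        pixels = pixels.astype(np.uint8)
    tifffile.imwrite(path, pixels)
    _sidecar(path).write_text(json.dumps(
        {"pixel_size_um": grid.pixel_size, "origin_um": list(grid.origin)}))


def read_grid(path: str | Path, as_bool: bool = False) -> ImageGrid:
    path = Path(path)
    pixels = tifffile.imread(path)
    meta = json.loads(_sidecar(path).read_text())
    if as_bool:
        pixels = pixels.astype(bool)
    return ImageGrid(pixels, meta["pixel_size_um"], tuple(meta["origin_um"]))


def write_partition(path: str | Path, partition: LabeledPartition) -> None:
    path = Path(path)
    tifffile.imwrite(path, partition.labels.astype(np.uint8))
    _sidecar(path).write_text(json.dumps(
        {"pixel_size_um": partition.pixel_size,
         "origin_um": list(partition.origin)}))


def read_partition(path: str | Path) -> LabeledPartition:
    path = Path(path)
    labels = tifffile.imread(path).astype(np.uint8)
    meta = json.loads(_sidecar(path).read_text())
    return LabeledPartition(labels, meta["pixel_size_um"],
                            tuple(meta["origin_um"]))


def write_design(path: str | Path, design: StructureDesign) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(design), sort_keys=False))


def read_design(path: str | Path) -> StructureDesign:
    data = yaml.safe_load(Path(path).read_text())
    data["branch_point"] = tuple(data.get("branch_point", (0.0, 0.0)))
    return build_y_design(**data)


def write_curves(path: str | Path, curves: list[IndentationCurve]) -> None:
    """All curves in one CSV, indexed by a ``curve`` column."""
    frames = []
    for i, c in enumerate(curves):
        df = c.to_frame()
        df.insert(0, "curve", i)
        for k, v in c.metadata.items():
            df[k] = v
        df["bead_radius_m"] = c.bead_radius
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_curves(path: str | Path) -> list[IndentationCurve]:
    df = pd.read_csv(path)
    curves = []
    meta_cols = [c for c in df.columns
                 if c not in ("curve", "delta_m", "force_N", "bead_radius_m")]
    for _, sub in df.groupby("curve", sort=True):
        meta = {k: sub[k].iloc[0] for k in meta_cols}
        curves.append(IndentationCurve(
            sub["delta_m"].to_numpy(), sub["force_N"].to_numpy(),
            float(sub["bead_radius_m"].iloc[0]), meta))
    return curves
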