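"""File I/O: multi-page TIFF stacks with JSON sidecars, atlas directories,
landmark JSON, cell/quant CSV tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .atlas import Atlas
from .registration import LandmarkLine
from .types import ImageStack

__all__ = [
    "write_stack",
    "read_stack",
    "write_atlas",
    "read_atlas",
    "read_landmarks",
    "write_landmarks",
]


def write_stack(stack: ImageStack, path: str | Path, **sidecar) -> None:
    """Write a stack as multi-page TIFF plus a ``.json`` sidecar carrying the
    voxel spacing, channel tag and any extra metadata (e.g. spec, seed)."""
    path = Path(path)
    tifffile.imwrite(path, stack.data, photometric="minisblack")
    meta = {"spacing_um": list(stack.spacing_um), "channel": stack.channel, **sidecar}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_stack(path: str | Path) -> ImageStack:
    path = Path(path)
    data = tifffile.imread(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    spacing, channel = (3.5, 5.0, 5.0), ""
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        spacing = tuple(meta.get("spacing_um", spacing))
        channel = meta.get("channel", "")
    return ImageStack(data=data, spacing_um=spacing, channel=channel)


def write_atlas(atlas: Atlas, outdir: str | Path) -> None:
    """Atlas directory: ``labels.tif`` (integer multi-page TIFF) +
    ``regions.csv`` (id, name) + ``meta.json``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        outdir / "labels.tif", atlas.labels.astype(np.int32), photometric="minisblack"
    )
    atlas.regions.to_csv(outdir / "regions.csv", index=False)
    (outdir / "meta.json").write_text(json.dumps({"spacing_um": list(atlas.spacing_um)}))


def read_atlas(indir: str | Path) -> Atlas:
    indir = Path(indir)
    labels = tifffile.imread(indir / "labels.tif")
    regions = pd.read_csv(indir / "regions.csv")
    spacing = (3.5, 5.0, 5.0)
    meta = indir / "meta.json"
    if meta.exists():
        spacing = tuple(json.loads(meta.read_text())["spacing_um"])
    return Atlas(labels=np.asarray(labels), regions=regions, spacing_um=spacing)


def read_landmarks(path: str | Path) -> LandmarkLine:
    """Landmark JSON: ``{"p0": [z, y, x], "p1": [z, y, x]}``."""
    d = json.loads(Path(path).read_text())
    return LandmarkLine(p0=tuple(d["p0"]), p1=tuple(d["p1"]))


def write_landmarks(line: LandmarkLine, path: str | Path) -> None:
    Path(path).write_text(json.dumps({"p0": list(line.p0), "p1": list(line.p1)}))
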