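"""Reading and writing of tiles, volumes, spiral models and cell tables.

Tiles and volumes are multi-page grayscale TIFFs (16-bit) with a JSON
manifest carrying voxel size and stage offsets in micrometres; spiral
models are JSON; cell tables and ground truth are CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .linearize import SpiralModel
from .phantom import VoxelVolume

__all__ = [
    "write_tiles",
    "read_tiles",
    "write_volume",
    "read_volume",
    "write_spiral",
    "read_spiral",
]


def write_tiles(
    out_dir: str | Path, tiles: list[VoxelVolume], truth: pd.DataFrame | None = None
) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, t in enumerate(tiles):
        name = f"tile_{i:03d}.tif"
        tifffile.imwrite(out / name, t.data)
        entries.append({"file": name, "offset_um": list(map(float, t.origin))})
    manifest = {
        "voxel_size_um": list(map(float, tiles[0].voxel_size)),
        "tiles": entries,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    if truth is not None:
        truth.to_csv(out / "ground_truth.csv", index=False)
    return out / "manifest.json"


def read_tiles(manifest_path: str | Path) -> tuple[list[VoxelVolume], pd.DataFrame | None]:
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / "manifest.json"
    man = json.loads(manifest_path.read_text())
    base = manifest_path.parent
    vs = tuple(man["voxel_size_um"])
    tiles = [
        VoxelVolume(tifffile.imread(base / e["file"]), vs, tuple(e["offset_um"]))
        for e in man["tiles"]
    ]
    gt = base / "ground_truth.csv"
    truth = pd.read_csv(gt) if gt.exists() else None
    return tiles, truth


def write_volume(path: str | Path, volume: VoxelVolume) -> None:
    path = Path(path)
    data = volume.data
    if data.dtype not in (np.uint8, np.uint16):
        data = np.clip(data, 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data)
    meta = {
        "voxel_size_um": list(map(float, volume.voxel_size)),
        "origin_um": list(map(float, volume.origin)),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_volume(path: str | Path) -> VoxelVolume:
    path = Path(path)
    data = tifffile.imread(path)
    meta_path = path.with_suffix(".json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        return VoxelVolume(data, tuple(meta["voxel_size_um"]), tuple(meta["origin_um"]))
    return VoxelVolume(data)


def write_spiral(path: str | Path, spiral: SpiralModel) -> None:
    obj = {
        "s": spiral.s.tolist(),
        "curve": spiral.curve.tolist(),
        "tangent": spiral.tangent.tolist(),
        "radial": spiral.radial.tolist(),
        "vertical": spiral.vertical.tolist(),
        "end_extension": spiral.end_extension,
    }
    Path(path).write_text(json.dumps(obj))


def read_spiral(path: str | Path) -> SpiralModel:
    obj = json.loads(Path(path).read_text())
    return SpiralModel(
        curve=np.asarray(obj["curve"]),
        s=np.asarray(obj["s"]),
        tangent=np.asarray(obj["tangent"]),
        radial=np.asarray(obj["radial"]),
        vertical=np.asarray(obj["vertical"]),
        end_extension=int(obj.get("end_extension", 0)),
    )
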