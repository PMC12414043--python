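"""Disk formats: PLY meshes, npz+JSON field bundles, CSV tables, PNG images.

Meshes go out as binary PLY through trimesh; field series as a NumPy ``.npz``
sidecar next to a small JSON manifest recording units and cycle duration;
metric fields and sample tables as CSV; images and masks as PNG; cameras and
ground truth as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .fields import WSSFieldSeries
from .mesh import SurfaceMesh


def write_mesh_ply(mesh: SurfaceMesh, path: str | Path) -> None:
    import trimesh

    tm = trimesh.Trimesh(vertices=mesh.points, faces=mesh.triangles,
                         process=False)
    tm.export(str(path))


def read_mesh_ply(path: str | Path, node_region=None) -> SurfaceMesh:
    import trimesh

    tm = trimesh.load(str(path), process=False)
    region = (np.asarray(node_region, dtype=object) if node_region is not None
              else np.full(len(tm.vertices), "dome", dtype=object))
    return SurfaceMesh(np.asarray(tm.vertices, dtype=float),
                       np.asarray(tm.faces, dtype=int), region)


def write_field_series(series: WSSFieldSeries, path_prefix: str | Path) -> None:
    """``<prefix>.npz`` with the arrays + ``<prefix>.json`` manifest."""
    prefix = Path(path_prefix)
    np.savez(prefix.with_suffix(".npz"), times=series.times,
             wss=series.wss, pressure=series.pressure)
    manifest = {
        "cycle_duration_s": series.cycle_duration,
        "n_timesteps": len(series.times),
        "n_nodes": series.n_nodes,
        "units": {"wss": "Pa", "pressure": "Pa", "times": "s"},
        "arrays": prefix.with_suffix(".npz").name,
    }
    prefix.with_suffix(".json").write_text(json.dumps(manifest, indent=2))


def read_field_series(path_prefix: str | Path) -> WSSFieldSeries:
    prefix = Path(path_prefix)
    manifest = json.loads(prefix.with_suffix(".json").read_text())
    data = np.load(prefix.with_suffix(".npz"))
    return WSSFieldSeries(data["times"], manifest["cycle_duration_s"],
                          data["wss"], data["pressure"])


def write_metric_fields(fields: dict, mesh: SurfaceMesh, path: str | Path) -> None:
    """Per-node CSV: node id, coordinates, region tag, one column per metric."""
    df = pd.DataFrame({
        "node_id": np.arange(mesh.n_nodes),
        "x_mm": mesh.points[:, 0], "y_mm": mesh.points[:, 1],
        "z_mm": mesh.points[:, 2], "region": mesh.node_region,
    })
    for name, f in fields.items():
        df[name] = f.values
    df.to_csv(path, index=False)


def write_image_png(image: np.ndarray, path: str | Path) -> None:
    Image.fromarray(image).save(str(path))


def write_mask_png(mask: np.ndarray, path: str | Path) -> None:
    Image.fromarray((np.asarray(mask, bool) * 255).astype(np.uint8)).save(str(path))


def read_image_png(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(str(path)).convert("RGB"))


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable))


def _jsonable(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer, np.floating)):
        return o.item()
    raise TypeError(f"not JSON serialisable: {type(o)}")
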