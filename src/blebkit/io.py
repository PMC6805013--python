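"""Reading and writing of movies, tables and meshes.

Movies travel as one multi-page TIFF per channel plus a sidecar JSON with
calibration (and, for synthetic data, ground truth). Tabular outputs are
plain CSV. Meshes are written as ASCII PLY (with a per-vertex protein
scalar) or OFF.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .edges import EdgeMap
from .membrane.mesh import TriMesh
from .movie import CellTrack, Movie

__all__ = [
    "write_movie",
    "read_movie",
    "write_tracks_csv",
    "write_edgemap",
    "read_edgemap",
    "write_mesh_ply",
    "write_mesh_off",
]


def write_movie(prefix: str | Path, movie: Movie, extra_meta: dict | None = None) -> None:
    """Write ``<prefix>_<channel>.tif`` per channel and ``<prefix>.json``."""
    prefix = Path(prefix)
    meta = {
        "pixel_size_um": movie.pixel_size,
        "frame_interval_s": movie.frame_interval,
        "channels": list(movie.channels),
    }
    if extra_meta:
        meta.update(extra_meta)
    for name, data in movie.channels.items():
        tifffile.imwrite(f"{prefix}_{name}.tif", data.astype(np.float32), photometric="minisblack")
    if movie.dark_frame is not None:
        tifffile.imwrite(
            f"{prefix}_dark.tif", movie.dark_frame.astype(np.float32), photometric="minisblack"
        )
        meta["dark_frame"] = True
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_movie(prefix: str | Path) -> Movie:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    channels = {
        name: tifffile.imread(f"{prefix}_{name}.tif").astype(float)
        for name in meta["channels"]
    }
    dark = None
    if meta.get("dark_frame"):
        dark = tifffile.imread(f"{prefix}_dark.tif").astype(float)
    return Movie(
        channels=channels,
        pixel_size=meta["pixel_size_um"],
        frame_interval=meta["frame_interval_s"],
        dark_frame=dark,
    )


def write_tracks_csv(
    path: str | Path, tracks: list[CellTrack], pixel_size: float, frame_interval: float
) -> None:
    rows = []
    for tr in tracks:
        flags = ";".join(k for k, v in tr.flags.items() if v)
        for f, (r, c) in zip(tr.frames, tr.centroids):
            rows.append(
                {
                    "track_id": tr.track_id,
                    "frame": f,
                    "t_s": f * frame_interval,
                    "x_um": c * pixel_size,
                    "y_um": r * pixel_size,
                    "flags": flags,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_edgemap(prefix: str | Path, emap: EdgeMap, cell_id: int = 0) -> None:
    """TIFF image (P×T float) plus long-format CSV."""
    prefix = Path(prefix)
    tifffile.imwrite(f"{prefix}.tif", emap.values.astype(np.float32), photometric="minisblack")
    p_idx, t_idx = np.meshgrid(np.arange(emap.P), np.arange(emap.T), indexing="ij")
    pd.DataFrame(
        {
            "cell": cell_id,
            "position_index": p_idx.ravel(),
            "frame": t_idx.ravel(),
            "value": emap.values.ravel(),
        }
    ).to_csv(f"{prefix}.csv", index=False)
    Path(f"{prefix}.json").write_text(
        json.dumps(
            {
                "kind": emap.kind,
                "frame_interval_s": emap.frame_interval,
                "perimeter_um": None if np.isnan(emap.perimeter_um) else emap.perimeter_um,
            }
        )
    )


def read_edgemap(prefix: str | Path) -> EdgeMap:
    prefix = Path(prefix)
    meta = json.loads(Path(f"{prefix}.json").read_text())
    values = tifffile.imread(f"{prefix}.tif").astype(float)
    perim = meta.get("perimeter_um")
    return EdgeMap(
        values=values,
        kind=meta["kind"],
        frame_interval=meta["frame_interval_s"],
        perimeter_um=np.nan if perim is None else perim,
    )


def write_mesh_ply(path: str | Path, mesh: TriMesh, protein: np.ndarray | None = None) -> None:
    """ASCII PLY with an optional per-vertex ``protein`` scalar property."""
    v = mesh.n_vertices
    lines = [
        "ply",
        "format ascii 1.0",
        f"element vertex {v}",
        "property float x",
        "property float y",
        "property float z",
    ]
    if protein is not None:
        lines.append("property uchar protein")
    lines += [f"element face {mesh.n_faces}", "property list uchar int vertex_indices", "end_header"]
    for i in range(v):
        x, y, z = mesh.vertices[i]
        row = f"{x:.6f} {y:.6f} {z:.6f}"
        if protein is not None:
            row += f" {int(protein[i])}"
        lines.append(row)
    for f in mesh.faces:
        lines.append(f"3 {f[0]} {f[1]} {f[2]}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_mesh_off(path: str | Path, mesh: TriMesh) -> None:
    lines = ["OFF", f"{mesh.n_vertices} {mesh.n_faces} {mesh.n_edges}"]
    for x, y, z in mesh.vertices:
        lines.append(f"{x:.6f} {y:.6f} {z:.6f}")
    for f in mesh.faces:
        lines.append(f"3 {f[0]} {f[1]} {f[2]}")
    Path(path).write_text("\n".join(lines) + "\n")
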