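"""File formats: stress-strain CSV, labeled meshes (VTK/STL/OBJ), TOML
configuration and atomic JSON/CSV artifacts.

The CSV curve dialect has columns ``mode, direction, true_strain,
true_stress_MPa``.  Meshes are written as legacy ASCII VTK (with region
labels and fiber vectors as cell data) or STL/OBJ through trimesh; the VTK
reader understands the dialect written here.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from typing import Sequence

import numpy as np
import pandas as pd

from .constitutive import StressStrainCurve
from .geometry import ValveSurface

__all__ = [
    "read_curves_csv",
    "write_curves_csv",
    "write_mesh",
    "read_mesh",
    "write_closure_series",
    "write_contacts_csv",
    "load_toml",
    "atomic_write_json",
    "config_hash",
]


# -- curves -----------------------------------------------------------------


def read_curves_csv(path: str) -> list[StressStrainCurve]:
    df = pd.read_csv(path)
    required = {"mode", "direction", "true_strain", "true_stress_MPa"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"curve CSV missing columns: {sorted(missing)}")
    curves = []
    for (mode, direction), grp in df.groupby(["mode", "direction"], sort=True):
        grp = grp.sort_values("true_strain")
        curves.append(StressStrainCurve(
            mode=mode, direction=direction,
            strain=grp["true_strain"].to_numpy(dtype=float),
            stress=grp["true_stress_MPa"].to_numpy(dtype=float),
        ))
    return curves


def write_curves_csv(curves: Sequence[StressStrainCurve], path: str) -> None:
    rows = []
    for c in curves:
        for eps, sig in zip(c.strain, c.stress):
            rows.append({"mode": c.mode, "direction": c.direction,
                         "true_strain": eps, "true_stress_MPa": sig})
    pd.DataFrame(rows).to_csv(path, index=False)


# -- meshes -----------------------------------------------------------------


def write_mesh(surface: ValveSurface, path: str,
               vertices: np.ndarray | None = None) -> None:
    """Write STL/OBJ (geometry only, via trimesh) or legacy ASCII VTK with
    region labels and fiber vectors as cell data."""
    V = surface.vertices if vertices is None else vertices
    ext = os.path.splitext(path)[1].lower()
    if ext in (".stl", ".obj"):
        import trimesh

        trimesh.Trimesh(V, surface.faces, process=False).export(path)
        return
    if ext != ".vtk":
        raise ValueError(f"unsupported mesh format {ext!r}")
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("trivalve surface\nASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(V)} double\n")
        np.savetxt(fh, V, fmt="%.9g")
        F = surface.faces
        fh.write(f"CELLS {len(F)} {4 * len(F)}\n")
        np.savetxt(fh, np.column_stack([np.full(len(F), 3), F]), fmt="%d")
        fh.write(f"CELL_TYPES {len(F)}\n")
        np.savetxt(fh, np.full(len(F), 5), fmt="%d")  # VTK_TRIANGLE
        fh.write(f"CELL_DATA {len(F)}\n")
        fh.write("SCALARS region int 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, surface.region, fmt="%d")
        fh.write("VECTORS fiber_circ double\n")
        np.savetxt(fh, surface.fiber_circ, fmt="%.9g")
        fh.write("VECTORS fiber_axial double\n")
        np.savetxt(fh, surface.fiber_axial, fmt="%.9g")
        if surface.free_edges:
            # ordered free-edge vertex paths as named field arrays
            fh.write(f"FIELD free_edges {len(surface.free_edges)}\n")
            for k, path in enumerate(surface.free_edges, start=1):
                fh.write(f"free_edge_{k} 1 {len(path)} int\n")
                np.savetxt(fh, np.asarray(path, dtype=int)[None, :], fmt="%d")


def read_mesh(path: str, thickness: float = 0.6) -> ValveSurface:
    """Read a valve surface from VTK (this module's dialect) or STL/OBJ.

    STL/OBJ carry no labels: all faces are labeled root and fiber directions
    default to the ring tangent / +z, so only label-free metrics apply.
    """
    ext = os.path.splitext(path)[1].lower()
    if ext in (".stl", ".obj"):
        import trimesh

        m = trimesh.load(path, force="mesh", process=False)
        V, F = np.asarray(m.vertices, float), np.asarray(m.faces, int)
        nf = len(F)
        ez = np.tile([0.0, 0.0, 1.0], (nf, 1))
        ex = np.tile([1.0, 0.0, 0.0], (nf, 1))
        return ValveSurface(V, F, np.zeros(nf, dtype=int), ex, ez,
                            thickness=thickness)
    if ext != ".vtk":
        raise ValueError(f"unsupported mesh format {ext!r}")
    with open(path) as fh:
        tokens = fh.read().split()
    i = 0

    def seek(word):
        nonlocal i
        while tokens[i].upper() != word:
            i += 1

    seek("POINTS")
    n_pts = int(tokens[i + 1])
    i += 3
    V = np.array(tokens[i:i + 3 * n_pts], dtype=float).reshape(n_pts, 3)
    i += 3 * n_pts
    seek("CELLS")
    n_cells = int(tokens[i + 1])
    i += 3
    cells = np.array(tokens[i:i + 4 * n_cells], dtype=int).reshape(n_cells, 4)
    F = cells[:, 1:]
    region = np.zeros(n_cells, dtype=int)
    fib_c = np.tile([1.0, 0.0, 0.0], (n_cells, 1))
    fib_a = np.tile([0.0, 0.0, 1.0], (n_cells, 1))
    try:
        seek("SCALARS")
        i += 6  # SCALARS region int 1 LOOKUP_TABLE default
        region = np.array(tokens[i:i + n_cells], dtype=int)
        seek("VECTORS")
        i += 3
        fib_c = np.array(tokens[i:i + 3 * n_cells], dtype=float).reshape(n_cells, 3)
        i += 3 * n_cells
        seek("VECTORS")
        i += 3
        fib_a = np.array(tokens[i:i + 3 * n_cells], dtype=float).reshape(n_cells, 3)
        i += 3 * n_cells
    except IndexError:
        pass
    free_edges: list[np.ndarray] = []
    try:
        seek("FIELD")
        n_arrays = int(tokens[i + 2])
        i += 3
        for _ in range(n_arrays):
            # name n_components n_values type
            n_vals = int(tokens[i + 2])
            i += 4
            free_edges.append(np.array(tokens[i:i + n_vals], dtype=int))
            i += n_vals
    except IndexError:
        pass
    return ValveSurface(V, F, region, fib_c, fib_a, thickness=thickness,
                        free_edges=free_edges)


def write_closure_series(result, out_dir: str, stride: int = 1) -> list[str]:
    """VTK time series of a closure result; returns the file list."""
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for i in range(0, len(result.snapshots), stride):
        path = os.path.join(out_dir, f"closure_{i:04d}.vtk")
        write_mesh(result.surface, path, vertices=result.snapshots[i])
        paths.append(path)
    with open(os.path.join(out_dir, "series.json"), "w") as fh:
        json.dump({"times": result.times[::stride].tolist(),
                   "pressures_pa": result.pressures_pa[::stride].tolist(),
                   "files": [os.path.basename(p) for p in paths]}, fh, indent=2)
    return paths


def write_contacts_csv(result, path: str) -> None:
    rows = []
    for i, pairs in enumerate(result.contact_pairs):
        for row in pairs:
            rows.append({"snapshot": i, "t": result.times[i],
                         "vertex": int(row[0]), "face_a": int(row[1]),
                         "face_b": int(row[2]), "gap_mm": float(row[3])})
    pd.DataFrame(rows, columns=["snapshot", "t", "vertex", "face_a", "face_b",
                                "gap_mm"]).to_csv(path, index=False)


# -- config / artifacts -----------------------------------------------------


def load_toml(path: str) -> dict:
    import tomllib

    with open(path, "rb") as fh:
        return tomllib.load(fh)


def config_hash(obj) -> str:
    blob = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha1(blob.encode()).hexdigest()[:16]


def atomic_write_json(obj, path: str, embed_hash: bool = True) -> None:
    """Write JSON atomically (temp file + rename), embedding a config hash."""
    if embed_hash and isinstance(obj, dict):
        obj = {**obj, "config_hash": config_hash(
            {k: v for k, v in obj.items() if k != "config_hash"})}
    d = os.path.dirname(os.path.abspath(path))
    os.makedirs(d, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            json.dump(obj, fh, indent=2, sort_keys=True, default=float)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)
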