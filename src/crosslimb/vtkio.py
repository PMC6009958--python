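"""Plain-text writers/readers: legacy-ASCII VTK, STL, metrics CSV, manifests.

Output formats are limited to legacy VTK (ImageData / PolyData), ASCII
STL, CSV and JSON manifests so results stay tool-agnostic and diffable.
Floats are serialized with %.17g, so a write/read round trip is
bit-exact.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "write_vtk_imagedata",
    "read_vtk_imagedata",
    "write_vtk_polydata",
    "write_stl_ascii",
    "write_vtk_series",
    "append_metrics_csv",
    "write_trace_csv",
]

_FMT = "%.17g"


def write_vtk_imagedata(path, origin, spacing, point_data: dict) -> None:
    """Legacy VTK structured-points file with named point-data arrays.

    Arrays must share one (nx, ny, nz) shape; VTK expects x-fastest
    ordering, handled here.
    """
    arrays = {k: np.asarray(v, float) for k, v in point_data.items()}
    dims = next(iter(arrays.values())).shape
    for k, a in arrays.items():
        if a.shape != dims:
            raise ValueError(f"array {k!r} shape {a.shape} != {dims}")
    n = int(np.prod(dims))
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\ncrosslimb field\nASCII\n")
        f.write("DATASET STRUCTURED_POINTS\n")
        f.write(f"DIMENSIONS {dims[0]} {dims[1]} {dims[2]}\n")
        f.write(f"ORIGIN {_FMT % origin[0]} {_FMT % origin[1]} "
                f"{_FMT % origin[2]}\n")
        f.write(f"SPACING {_FMT % spacing} {_FMT % spacing} "
                f"{_FMT % spacing}\n")
        f.write(f"POINT_DATA {n}\n")
        for name, a in arrays.items():
            f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            flat = a.transpose(2, 1, 0).ravel()
            np.savetxt(f, flat, fmt=_FMT)


def read_vtk_imagedata(path):
    """Read a file written by write_vtk_imagedata.

    Returns (origin, spacing, {name: array}) with (nx, ny, nz) arrays.
    """
    with open(path) as f:
        lines = f.read().splitlines()
    dims = spacing = origin = None
    arrays = {}
    i = 0
    while i < len(lines):
        tok = lines[i].split()
        if not tok:
            i += 1
            continue
        if tok[0] == "DIMENSIONS":
            dims = tuple(int(x) for x in tok[1:4])
        elif tok[0] == "ORIGIN":
            origin = np.array([float(x) for x in tok[1:4]])
        elif tok[0] == "SPACING":
            spacing = float(tok[1])
        elif tok[0] == "SCALARS":
            name = tok[1]
            n = dims[0] * dims[1] * dims[2]
            vals = []
            j = i + 2
            while len(vals) < n:
                vals.extend(float(x) for x in lines[j].split())
                j += 1
            arr = np.array(vals).reshape(dims[2], dims[1], dims[0])
            arrays[name] = arr.transpose(2, 1, 0)
            i = j - 1
        i += 1
    return origin, spacing, arrays


def write_vtk_polydata(path, vertices, triangles, point_data=None,
                       cell_data=None) -> None:
    """Legacy VTK triangle-mesh PolyData with optional data arrays."""
    verts = np.asarray(vertices, float)
    tris = np.asarray(triangles, int)
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\ncrosslimb surface\nASCII\n")
        f.write("DATASET POLYDATA\n")
        f.write(f"POINTS {len(verts)} double\n")
        np.savetxt(f, verts, fmt=_FMT)
        f.write(f"POLYGONS {len(tris)} {4 * len(tris)}\n")
        np.savetxt(f, np.column_stack([np.full(len(tris), 3), tris]),
                   fmt="%d")
        for header, data, n in (("POINT_DATA", point_data, len(verts)),
                                ("CELL_DATA", cell_data, len(tris))):
            if not data:
                continue
            f.write(f"{header} {n}\n")
            for name, a in data.items():
                a = np.asarray(a)
                if a.dtype.kind in "US":
                    codes, uniq = pd.factorize(a)
                    f.write(f"SCALARS {name} int 1\nLOOKUP_TABLE default\n")
                    np.savetxt(f, codes, fmt="%d")
                elif a.ndim == 2 and a.shape[1] == 3:
                    f.write(f"VECTORS {name} double\n")
                    np.savetxt(f, a, fmt=_FMT)
                else:
                    f.write(f"SCALARS {name} double 1\n"
                            "LOOKUP_TABLE default\n")
                    np.savetxt(f, a.astype(float), fmt=_FMT)


def write_stl_ascii(path, vertices, triangles, name="crosslimb") -> None:
    verts = np.asarray(vertices, float)
    tris = np.asarray(triangles, int)
    tri = verts[tris]
    nrm = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    ln = np.linalg.norm(nrm, axis=1, keepdims=True)
    ln[ln == 0] = 1.0
    nrm = nrm / ln
    with open(path, "w") as f:
        f.write(f"solid {name}\n")
        for t, n in zip(tri, nrm):
            f.write(f"facet normal {n[0]:.9g} {n[1]:.9g} {n[2]:.9g}\n"
                    " outer loop\n")
            for v in t:
                f.write(f"  vertex {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
            f.write(" endloop\nendfacet\n")
        f.write(f"endsolid {name}\n")


def write_vtk_series(states, grid, out_dir, rheology=None,
                     sdf_cc=None) -> dict:
    """One ImageData file per snapshot plus a JSON time-series manifest.

    Fields: cell-centered velocity components, pressure, strain rate and
    viscosity (when rheology is given), and the fluid mask when the
    signed distance at cell centers is given.
    """
    from .solver import strain_rate_modulus
    from .rheology import carreau_viscosity

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, st in enumerate(states):
        uc, vc, wc = st.cell_velocity()
        fields = {"u": uc, "v": vc, "w": wc, "p": st.p}
        if rheology is not None:
            gd = strain_rate_modulus(uc, vc, wc, grid.spacing)
            fields["gamma_dot"] = gd
            fields["eta"] = np.asarray(carreau_viscosity(gd, rheology))
        if sdf_cc is not None:
            fields["mask"] = (sdf_cc < 0).astype(float)
        fname = f"step_{i:04d}.vtk"
        write_vtk_imagedata(out / fname, grid.origin, grid.spacing, fields)
        entries.append({"file": fname, "time": float(st.t)})
    manifest = {"n_steps": len(entries), "spacing": grid.spacing,
                "origin": list(map(float, grid.origin)), "steps": entries}
    with open(out / "series.json", "w") as f:
        json.dump(manifest, f, indent=1)
    return manifest


def save_state(path, state) -> None:
    """Single-file solver restart (compressed container)."""
    np.savez_compressed(path, u=state.u, v=state.v, w=state.w, p=state.p,
                        t=np.array([state.t]))


def load_state(path):
    from .solver import FlowState

    d = np.load(path)
    return FlowState(d["u"], d["v"], d["w"], d["p"], float(d["t"][0]))


_METRICS_FLOAT_FMT = "%.9g"


def append_metrics_csv(row: dict, path) -> None:
    """Append one metrics row; header written once and enforced stable.

    Floats carry 9 significant digits; NaN serializes as an empty cell.
    """
    df = pd.DataFrame([row])
    path = Path(path)
    if path.exists():
        existing = pd.read_csv(path, nrows=0)
        if list(existing.columns) != list(df.columns):
            raise ValueError(
                f"CSV header mismatch: file has {list(existing.columns)}, "
                f"row has {list(df.columns)}")
        df.to_csv(path, mode="a", header=False, index=False,
                  float_format=_METRICS_FLOAT_FMT, na_rep="")
    else:
        df.to_csv(path, index=False, float_format=_METRICS_FLOAT_FMT,
                  na_rep="")


def write_trace_csv(path, times, values, name="value") -> None:
    """Two-column (or vector) time-trace CSV."""
    vals = np.asarray(values)
    if vals.ndim == 1:
        arr = np.column_stack([times, vals])
        header = f"t,{name}"
    else:
        arr = np.column_stack([times, vals])
        header = "t," + ",".join(f"{name}_{c}" for c in "xyz"[: vals.shape[1]])
    np.savetxt(path, arr, delimiter=",", header=header, comments="",
               fmt=_FMT)
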