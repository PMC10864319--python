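"""Plain-text file I/O: legacy ASCII VTK, ASCII STL and probe tables.

Field files use the legacy ASCII VTK unstructured-grid format with cell
data, which every common visualiser reads.  Coordinates are written in
millimetres (flask-fixed frame); the ``volume`` cell array is in m^3 and
all physical fields in SI.  The reader accepts any legacy ASCII
unstructured grid carrying the expected ``CELL_DATA`` scalars, so
solver exports converted to this format round-trip through the same
code paths as the synthetic fields.
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np

from .dissipation import FieldSet
from .extraction import NearestPointField
from .geometry import FlaskGeometry
from .kinematics import FluidProperties

__all__ = [
    "write_vtk_fields",
    "read_vtk_cells",
    "field_from_vtk",
    "fieldset_from_vtk",
    "write_stl_surface",
    "field_from_probe_table",
]

_HEX_TETS = ((0, 1, 2, 6), (0, 2, 3, 6), (0, 3, 7, 6),
             (0, 7, 4, 6), (0, 4, 5, 6), (0, 5, 1, 6))


def _mesh_hexes(mesh) -> Tuple[np.ndarray, np.ndarray]:
    """Points (mm) and hex connectivity for a :class:`SyntheticMesh`."""
    n_z, n_r, n_th = mesh.shape
    z_edges = mesh.z_edges
    th = mesh.theta_edges  # seam duplicated
    redges = mesh.radial_edges_at(z_edges)  # (n_z+1, n_r+1)
    # point index (iz, ir, ith)
    R = redges[:, :, None]
    TH = th[None, None, :]
    X = R * np.cos(TH)
    Y = R * np.sin(TH)
    Z = np.broadcast_to(z_edges[:, None, None], X.shape)
    pts = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
    nr1, nt1 = n_r + 1, n_th + 1

    def pid(iz, ir, it):
        return (iz * nr1 + ir) * nt1 + it

    iz, ir, it = np.meshgrid(np.arange(n_z), np.arange(n_r), np.arange(n_th),
                             indexing="ij")
    conn = np.stack([
        pid(iz, ir, it), pid(iz, ir + 1, it), pid(iz, ir + 1, it + 1),
        pid(iz, ir, it + 1),
        pid(iz + 1, ir, it), pid(iz + 1, ir + 1, it),
        pid(iz + 1, ir + 1, it + 1), pid(iz + 1, ir, it + 1),
    ], axis=-1).reshape(-1, 8)
    return pts, conn


def write_vtk_fields(path, mesh, cell_data: Dict[str, np.ndarray],
                     title: str = "shakeflask fields (points mm, volume m3, SI)") -> None:
    """Write a synthetic mesh plus cell-data scalars as legacy ASCII VTK."""
    pts, conn = _mesh_hexes(mesh)
    n_cells = conn.shape[0]
    for name, arr in cell_data.items():
        if len(arr) != n_cells:
            raise ValueError(f"cell array {name!r} has wrong length")
    buf = io.StringIO()
    buf.write("# vtk DataFile Version 3.0\n")
    buf.write(title + "\n")
    buf.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
    buf.write(f"POINTS {len(pts)} float\n")
    np.savetxt(buf, pts, fmt="%.6g")
    buf.write(f"CELLS {n_cells} {n_cells * 9}\n")
    np.savetxt(buf, np.column_stack([np.full(n_cells, 8), conn]), fmt="%d")
    buf.write(f"CELL_TYPES {n_cells}\n")
    buf.write("\n".join(["12"] * n_cells) + "\n")
    buf.write(f"CELL_DATA {n_cells}\n")
    for name, arr in cell_data.items():
        buf.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
        np.savetxt(buf, np.asarray(arr, dtype=float), fmt="%.9g")
    Path(path).write_text(buf.getvalue())


def _tokens(text: str):
    for line in text.splitlines():
        line = line.strip()
        if line:
            yield from line.split()


def read_vtk_cells(path) -> Tuple[np.ndarray, np.ndarray, Dict[str, np.ndarray]]:
    """Parse a legacy ASCII VTK unstructured grid.

    Returns cell centres (mm), approximate cell volumes (mm^3, from a
    six-tetrahedron decomposition of each hexahedron) and the cell-data
    scalar arrays.
    """
    text = Path(path).read_text()
    tok = list(_tokens(text))
    i = 0

    def find(word):
        nonlocal i
        while i < len(tok) and tok[i].upper() != word:
            i += 1
        if i == len(tok):
            raise ValueError(f"VTK file missing {word} section")

    find("POINTS")
    n_pts = int(tok[i + 1])
    pts = np.array(tok[i + 3:i + 3 + 3 * n_pts], dtype=float).reshape(n_pts, 3)
    i += 3 + 3 * n_pts
    find("CELLS")
    n_cells, size = int(tok[i + 1]), int(tok[i + 2])
    raw = np.array(tok[i + 3:i + 3 + size], dtype=int)
    i += 3 + size
    cells = []
    j = 0
    for _ in range(n_cells):
        npts = raw[j]
        cells.append(raw[j + 1:j + 1 + npts])
        j += 1 + npts
    # cell data scalars
    data: Dict[str, np.ndarray] = {}
    k = i
    while k < len(tok):
        if tok[k].upper() == "CELL_DATA":
            k += 2
            continue
        if tok[k].upper() == "SCALARS":
            name = tok[k + 1]
            # skip: SCALARS name type [ncomp] LOOKUP_TABLE default
            k += 3
            if tok[k].isdigit():
                k += 1
            if tok[k].upper() == "LOOKUP_TABLE":
                k += 2
            data[name] = np.array(tok[k:k + n_cells], dtype=float)
            k += n_cells
            continue
        k += 1

    centers = np.array([pts[c].mean(axis=0) for c in cells])
    vols = np.empty(n_cells)
    for idx, c in enumerate(cells):
        if len(c) == 8:
            p = pts[c]
            v = 0.0
            for a, b, cc, d in _HEX_TETS:
                v += abs(np.linalg.det(np.stack([p[b] - p[a], p[cc] - p[a],
                                                 p[d] - p[a]]))) / 6.0
            vols[idx] = v
        else:
            vols[idx] = np.nan
    return centers, vols, data


def field_from_vtk(path, geometry: FlaskGeometry,
                   array: str = "alpha") -> NearestPointField:
    """Volume-fraction field from a VTK file (nearest-cell sampling)."""
    centers, _, data = read_vtk_cells(path)
    if array not in data:
        raise KeyError(
            f"VTK file has no cell array {array!r}; found {sorted(data)}")
    return NearestPointField(centers, data[array], geometry)


def fieldset_from_vtk(path, fluid: FluidProperties) -> FieldSet:
    """Dissipation inputs from a VTK file.

    Expects cell arrays ``alpha``, ``k``, ``omega`` and ``S2`` (squared
    strain measure); cell volumes are taken from a ``volume`` array (m^3)
    when present, otherwise recomputed from the hexahedra (mm^3 -> m^3).
    """
    centers, vols_mm3, data = read_vtk_cells(path)
    missing = [a for a in ("alpha", "k", "omega", "S2") if a not in data]
    if missing:
        raise KeyError(f"VTK file missing cell arrays {missing}; found {sorted(data)}")
    if "volume" in data:
        volumes = data["volume"]
    else:
        volumes = vols_mm3 * 1e-9
    return FieldSet(cell_volumes=volumes, alpha=data["alpha"],
                    strain_sq=data["S2"], k=data["k"], omega=data["omega"],
                    fluid=fluid)


def write_stl_surface(path, geometry: FlaskGeometry, n_z: int = 120,
                      n_az: int = 90) -> None:
    """Triangulated inner flask surface as ASCII STL (mm)."""
    tris = geometry.surface_triangles(n_z=n_z, n_az=n_az)
    with open(path, "w") as fh:
        fh.write("solid flask\n")
        for tri in tris:
            a, b, c = (np.asarray(v) for v in tri)
            n = np.cross(b - a, c - a)
            norm = np.linalg.norm(n)
            n = n / norm if norm > 0 else n
            fh.write(f"facet normal {n[0]:.6g} {n[1]:.6g} {n[2]:.6g}\n outer loop\n")
            for v in (a, b, c):
                fh.write(f"  vertex {v[0]:.6g} {v[1]:.6g} {v[2]:.6g}\n")
            fh.write(" endloop\nendfacet\n")
        fh.write("endsolid flask\n")


def field_from_probe_table(path, geometry: FlaskGeometry,
                           alpha_column: str = "alpha") -> NearestPointField:
    """Volume-fraction field from a delimited probe table.

    The table must carry columns ``x_mm, y_mm, z_mm`` and an alpha
    column; delimiter is sniffed by pandas.
    """
    import pandas as pd

    df = pd.read_csv(path, sep=None, engine="python")
    needed = ["x_mm", "y_mm", "z_mm", alpha_column]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise KeyError(f"probe table missing columns {missing}")
    centers = df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
    return NearestPointField(centers, df[alpha_column].to_numpy(dtype=float),
                             geometry)
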