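"""Minimal legacy-VTK (ASCII unstructured grid) writer and point-data reader.

Covers exactly what the toolkit exports: polygon cells (2D bulk meshes and
cut-plane plot surfaces), polyhedron cells (3D bulk meshes, face-stream
format), lines and triangles (surface meshes), each with named nodal scalar
fields.  The reader is intentionally small: it round-trips points and point
data written by this module, enough to hand results to external tools and to
verify exports.
"""

from __future__ import annotations

import numpy as np

VTK_LINE = 3
VTK_TRIANGLE = 5
VTK_POLYGON = 7
VTK_POLYHEDRON = 42


def _write_header(fh, title):
    fh.write("# vtk DataFile Version 4.2\n")
    fh.write(f"{title}\n")
    fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")


def _write_points(fh, P):
    fh.write(f"POINTS {len(P)} double\n")
    for p in P:
        fh.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")


def _write_point_data(fh, n, point_data):
    if not point_data:
        return
    fh.write(f"POINT_DATA {n}\n")
    for name, vals in point_data.items():
        vals = np.asarray(vals, dtype=float).ravel()
        if len(vals) != n:
            raise ValueError(f"point data '{name}' has {len(vals)} values, "
                             f"expected {n}")
        fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
        for val in vals:
            fh.write(f"{val:.17g}\n")


def write_mesh_vtk(mesh, path, point_data=None, which="bulk") -> str:
    """Write a bulk-surface mesh (or one of its views) as legacy VTK."""
    path = str(path)
    if which == "bulk":
        if mesh.dim == 2:
            cells = [("polygon", el.Pind) for el in mesh.bulk_elements]
        else:
            cells = [("polyhedron", [el.Pind[fl] for fl in el.face_local])
                     for el in mesh.bulk_elements]
    elif which == "surface":
        kind = "line" if mesh.surf_elements.shape[1] == 2 else "triangle"
        cells = [(kind, row) for row in mesh.surf_elements]
    elif which == "plot":
        if not mesh.plot_elements:
            raise ValueError("mesh has no plot elements (xcut not requested)")
        cells = [("polygon", el.Pind) for el in mesh.plot_elements]
    else:
        raise ValueError("which must be 'bulk', 'surface' or 'plot'")
    with open(path, "w") as fh:
        _write_header(fh, f"polyvem {which} mesh")
        _write_points(fh, mesh.P)
        _write_cells(fh, cells)
        _write_point_data(fh, len(mesh.P), point_data or {})
    return path


def _write_cells(fh, cells):
    lines = []
    types = []
    total = 0
    for kind, data in cells:
        if kind == "polyhedron":
            faces = [np.asarray(f, dtype=int) for f in data]
            stream = [len(faces)]
            for f in faces:
                stream.append(len(f))
                stream.extend(int(i) for i in f)
            lines.append(" ".join(str(x) for x in [len(stream)] + stream))
            total += len(stream) + 1
            types.append(VTK_POLYHEDRON)
        else:
            idx = [int(i) for i in np.asarray(data, dtype=int)]
            lines.append(" ".join(str(x) for x in [len(idx)] + idx))
            total += len(idx) + 1
            types.append({"line": VTK_LINE, "triangle": VTK_TRIANGLE,
                          "polygon": VTK_POLYGON}[kind])
    fh.write(f"CELLS {len(cells)} {total}\n")
    fh.write("\n".join(lines) + ("\n" if lines else ""))
    fh.write(f"CELL_TYPES {len(cells)}\n")
    fh.write("\n".join(str(t) for t in types) + ("\n" if types else ""))


def read_vtk_points_and_data(path):
    """Read POINTS and SCALARS point data back from a legacy-VTK file."""
    points = None
    data = {}
    with open(path) as fh:
        tokens = fh.read().split("\n")
    i = 0
    npoints = 0
    while i < len(tokens):
        line = tokens[i].strip()
        if line.startswith("POINTS"):
            npoints = int(line.split()[1])
            vals = []
            i += 1
            while len(vals) < 3 * npoints:
                vals.extend(float(x) for x in tokens[i].split())
                i += 1
            points = np.asarray(vals).reshape(npoints, 3)
            continue
        if line.startswith("SCALARS"):
            name = line.split()[1]
            i += 2  # skip LOOKUP_TABLE
            vals = []
            while len(vals) < npoints:
                vals.extend(float(x) for x in tokens[i].split())
                i += 1
            data[name] = np.asarray(vals)
            continue
        i += 1
    if points is None:
        raise ValueError(f"no POINTS section found in {path}")
    return points, data
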