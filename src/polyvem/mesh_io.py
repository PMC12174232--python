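"""Plain-text mesh formats: the two-table surface format and a bulk format.

On disk all indices are 1-based (the convention of the common node/triangle
two-table surface format); in memory everything is 0-based.  Conversion
happens only here.

Surface format: a node file with N rows of 3 coordinates and an element file
with M rows of 3 (or 2) node indices, whitespace-separated.

Bulk-surface format (single file)::

    polyvem-mesh <dim>
    nodes <N>
    <x y z>            (N rows)
    elements <NE>
    2D:  <k i1 ... ik>            one polygon ring per row
    3D:  <nv NF> / <v1 ... vnv> / NF face rows "k i1 ... ik" (global indices)
         followed by "cube" or "poly" tag per element header
    surface <M>
    <i j [k]>          (M rows)

Matrix Market export of assembled operators is delegated to scipy.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import scipy.io

from .geometry import PolygonElement, PolyhedronElement
from .meshgen import BulkSurfaceMesh, import_surface

__all__ = [
    "read_surface_tables",
    "write_surface_tables",
    "write_mesh",
    "read_mesh",
    "export_matrices_mtx",
]


class MeshFormatError(ValueError):
    """Malformed mesh file; the message carries the offending line number."""


def read_surface_tables(node_path, elem_path, one_based: bool = True
                        ) -> BulkSurfaceMesh:
    """Read the two-table surface format into a surface-only mesh."""
    P = np.loadtxt(node_path, dtype=float, ndmin=2)
    T = np.loadtxt(elem_path, dtype=np.int64, ndmin=2)
    if one_based:
        T = T - 1
    return import_surface(P, T)


def write_surface_tables(mesh: BulkSurfaceMesh, node_path, elem_path,
                         one_based: bool = True) -> None:
    np.savetxt(node_path, mesh.P, fmt="%.17g")
    T = np.asarray(mesh.surf_elements)
    np.savetxt(elem_path, T + (1 if one_based else 0), fmt="%d")


def write_mesh(mesh: BulkSurfaceMesh, path) -> None:
    """Write a bulk-surface mesh in the documented plain-text format."""
    with open(path, "w") as fh:
        fh.write(f"polyvem-mesh {mesh.dim}\n")
        fh.write(f"nodes {mesh.num_nodes}\n")
        for p in mesh.P:
            fh.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
        fh.write(f"elements {len(mesh.bulk_elements)}\n")
        for el in mesh.bulk_elements:
            if mesh.dim == 2:
                idx = " ".join(str(int(i) + 1) for i in el.Pind)
                tag = "square" if el.is_square else "poly"
                fh.write(f"{tag} {len(el.Pind)} {idx}\n")
            else:
                tag = "cube" if el.is_cube else "poly"
                fh.write(f"{tag} {len(el.Pind)} {len(el.face_local)}\n")
                fh.write(" ".join(str(int(i) + 1) for i in el.Pind) + "\n")
                for fl in el.face_local:
                    glob = el.Pind[fl]
                    fh.write(f"{len(glob)} "
                             + " ".join(str(int(i) + 1) for i in glob) + "\n")
        surf = np.asarray(mesh.surf_elements)
        fh.write(f"surface {len(surf)}\n")
        for row in surf:
            fh.write(" ".join(str(int(i) + 1) for i in row) + "\n")


def read_mesh(path) -> BulkSurfaceMesh:
    """Read a mesh written by :func:`write_mesh` (lossless round trip)."""
    lines = Path(path).read_text().splitlines()
    ln = 0

    def take():
        nonlocal ln
        if ln >= len(lines):
            raise MeshFormatError(f"{path}: unexpected end of file at line {ln + 1}")
        ln += 1
        return lines[ln - 1].split()

    head = take()
    if len(head) != 2 or head[0] != "polyvem-mesh":
        raise MeshFormatError(f"{path}:1: not a polyvem mesh file")
    dim = int(head[1])
    tag = take()
    if tag[0] != "nodes":
        raise MeshFormatError(f"{path}:{ln}: expected 'nodes'")
    n = int(tag[1])
    P = np.empty((n, 3))
    for i in range(n):
        row = take()
        if len(row) != 3:
            raise MeshFormatError(f"{path}:{ln}: expected 3 coordinates")
        P[i] = [float(v) for v in row]
    tag = take()
    if tag[0] != "elements":
        raise MeshFormatError(f"{path}:{ln}: expected 'elements'")
    ne = int(tag[1])
    elements = []
    h = 0.0
    for _ in range(ne):
        head = take()
        if dim == 2:
            kind, k = head[0], int(head[1])
            idx = np.array([int(v) - 1 for v in head[2:2 + k]], dtype=np.int64)
            el = PolygonElement(P[idx], Pind=idx, is_square=(kind == "square"))
        else:
            kind, nv, nf = head[0], int(head[1]), int(head[2])
            idx = np.array([int(v) - 1 for v in take()], dtype=np.int64)
            if len(idx) != nv:
                raise MeshFormatError(f"{path}:{ln}: vertex count mismatch")
            lut = {int(g): i for i, g in enumerate(idx)}
            face_local = []
            for _ in range(nf):
                frow = take()
                k = int(frow[0])
                glob = [int(v) - 1 for v in frow[1:1 + k]]
                face_local.append(np.array([lut[g] for g in glob], dtype=np.int64))
            faces = [PolygonElement(P[idx[fl]], Pind=idx[fl]) for fl in face_local]
            el = PolyhedronElement(P[idx], faces, Pind=idx,
                                   is_cube=(kind == "cube"),
                                   face_local=face_local, orient=False)
        elements.append(el)
        h = max(h, el.diameter)
    tag = take()
    if tag[0] != "surface":
        raise MeshFormatError(f"{path}:{ln}: expected 'surface'")
    m = int(tag[1])
    surf = []
    for _ in range(m):
        surf.append([int(v) - 1 for v in take()])
    width = len(surf[0]) if surf else (2 if dim == 2 else 3)
    surf = np.asarray(surf, dtype=np.int64).reshape(-1, width)
    return BulkSurfaceMesh(P=P, h=float(h), bulk_elements=elements,
                           surf_elements=surf, dim=dim)


def export_matrices_mtx(mats, directory, names=("K", "C", "M", "KS", "MS", "CS", "R")
                        ) -> list[str]:
    """Write assembled sparse operators as Matrix Market files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name in names:
        A = getattr(mats, name, None)
        if A is None:
            continue
        path = directory / f"{name}.mtx"
        scipy.io.mmwrite(str(path), A.tocoo())
        written.append(str(path))
    return written
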