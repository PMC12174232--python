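"""Level-set-driven bulk-surface mesh generation.

A compact domain is described implicitly as ``Omega = {x in Q : f(x) <= 0}``
with ``Gamma = {f = 0}`` its boundary.  A Cartesian grid is laid over the
bounding box Q; cells entirely inside become square/cube elements, cells cut
by the zero level set become general polygons/polyhedra obtained by the
marching-squares (2D) / marching-cubes (3D) rule, and the cut chords /
isosurface patch triangles form the surface mesh.  By construction the
discrete surface is exactly the boundary of the discrete bulk,
``Gamma_h = boundary(Omega_h)``, so bulk and surface meshes are conforming.

Ambiguous (saddle) cell and face configurations are resolved by the sign of
the level-set function at the cell/face center.  Nodes closer than ``tol``
are merged: an edge-intersection node within ``tol`` of a grid node snaps to
that grid node, and clusters of intersection nodes within ``tol`` of each
other collapse to their mean; this removes the short edges that the raw
marching rule would otherwise produce.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.spatial import cKDTree

from .geometry import (
    PolygonElement,
    PolyhedronElement,
    polytope_diameter,
)

__all__ = [
    "LevelSetDomain",
    "BulkSurfaceMesh",
    "EmptyDomainError",
    "generate_mesh_2d",
    "generate_mesh_3d",
    "import_surface",
]


class EmptyDomainError(ValueError):
    """No grid cell intersects the domain: the mesh would be empty."""


@dataclass
class LevelSetDomain:
    """Implicit domain ``{f <= 0}`` inside a bounding box.

    Parameters
    ----------
    fun : callable
        Vectorized level-set function: maps an (n, dim) array of points to n
        values.  The domain is where ``fun <= 0``.
    Q : (dim, 2) array
        Bounding box rows ``(min, max)`` per coordinate.
    Nx : int
        Number of grid points along the shortest box side (>= 2); the grid
        spacing is ``dx = shortest_side / (Nx - 1)`` in every direction.
    tol : float, optional
        Minimum distance between distinct mesh nodes.  Defaults to
        ``1e-6 * dx`` when omitted, which merges only genuine duplicates
        (e.g. intersection nodes falling on grid nodes where the level set
        vanishes at a corner); larger values additionally remove the short
        edges the raw marching rule produces near grazing cuts, at the price
        of perturbing the surface polyline/triangulation.
    """

    fun: Callable[[np.ndarray], np.ndarray]
    Q: np.ndarray
    Nx: int
    tol: Optional[float] = None

    def __post_init__(self):
        self.Q = np.atleast_2d(np.asarray(self.Q, dtype=float))
        if self.Q.shape[1] != 2 or self.Q.shape[0] not in (2, 3):
            raise ValueError("Q must be a (dim, 2) array of per-axis bounds")
        if np.any(self.Q[:, 1] <= self.Q[:, 0]):
            raise ValueError("Q must have positive side lengths")
        if int(self.Nx) < 2:
            raise ValueError("Nx must be at least 2")
        if self.tol is not None and self.tol <= 0.0:
            raise ValueError("tol must be positive")

    @property
    def dim(self) -> int:
        return self.Q.shape[0]

    def grid(self):
        """Per-axis grid coordinates; non-shortest sides are covered by
        ``ceil(side/dx)`` congruent cells with the box enlarged symmetrically."""
        sides = self.Q[:, 1] - self.Q[:, 0]
        dx = sides.min() / (self.Nx - 1)
        axes = []
        for d in range(self.dim):
            ncell = int(np.ceil(sides[d] / dx - 1e-9))
            c = 0.5 * (self.Q[d, 0] + self.Q[d, 1])
            start = c - 0.5 * ncell * dx
            axes.append(start + dx * np.arange(ncell + 1))
        return axes, dx


@dataclass
class BulkSurfaceMesh:
    """A conforming bulk-surface mesh.

    ``P`` is the (N, 3) node table (2D meshes keep the third coordinate 0);
    ``surf_elements`` holds index pairs (2D segments) or triples (3D
    triangles) into ``P``, oriented so the implied normal points out of the
    bulk.  ``plot_elements`` (3D, optional) is the polygonal boundary mesh of
    ``Omega_h`` cut at a plane ``x <= xcut``, useful for visualizing interior
    values.
    """

    P: np.ndarray
    h: float
    bulk_elements: list = field(default_factory=list)
    surf_elements: np.ndarray = None
    plot_elements: Optional[list] = None
    dim: int = 3

    @property
    def num_nodes(self) -> int:
        return self.P.shape[0]

    def surface_node_indices(self) -> np.ndarray:
        """Distinct node indices on Gamma_h, in ascending order."""
        if self.surf_elements is None or len(self.surf_elements) == 0:
            return np.empty(0, dtype=np.int64)
        return np.unique(np.asarray(self.surf_elements))

    def boundary_facets(self) -> set:
        """Facets (sorted index tuples) of bulk elements used exactly once."""
        count: dict[tuple, int] = {}
        for el in self.bulk_elements:
            if self.dim == 2:
                idx = el.Pind
                facets = [
                    tuple(sorted((int(idx[i]), int(idx[(i + 1) % len(idx)]))))
                    for i in range(len(idx))
                ]
            else:
                facets = [
                    tuple(sorted(int(i) for i in el.Pind[fl]))
                    for fl in el.face_local
                ]
            for fkey in facets:
                count[fkey] = count.get(fkey, 0) + 1
        return {fkey for fkey, c in count.items() if c == 1}


# --------------------------------------------------------------------------- #
# shared cut-cell machinery
# --------------------------------------------------------------------------- #

def _cut_ring(ring, inside, crossing, center_inside):
    """Apply the marching-squares rule to one cell/face boundary ring.

    ``ring``: node keys of the corners (cyclic); ``inside``: corner flags;
    ``crossing``: crossing node key per ring edge i (corner i -> i+1) or
    None; ``center_inside``: saddle disambiguation flag.

    Returns (polygons, chords): polygons as key lists, chords as directed
    (exit, entry) key pairs tracing the zero level set with the bulk on the
    left of the ring orientation.
    """
    m = len(ring)
    tokens = []  # ('c', key) or ('x', key, 'exit'|'entry')
    for i in range(m):
        if inside[i]:
            tokens.append(("c", ring[i]))
        if crossing[i] is not None:
            kind = "exit" if inside[i] else "entry"
            tokens.append(("x", crossing[i], kind))
    xs = [t for t in tokens if t[0] == "x"]
    if not xs:
        if all(inside):
            return [list(ring)], []
        return [], []
    chords = []
    if center_inside:
        nx = len(xs)
        for k, t in enumerate(xs):
            if t[2] == "exit":
                chords.append((t[1], xs[(k + 1) % nx][1]))
        return [[t[1] for t in tokens]], chords
    # center outside: split into one polygon per entry..exit run
    polys = []
    n = len(tokens)
    for s, t in enumerate(tokens):
        if t[0] == "x" and t[2] == "entry":
            poly = [t[1]]
            k = (s + 1) % n
            while True:
                tk = tokens[k]
                poly.append(tk[1])
                if tk[0] == "x" and tk[2] == "exit":
                    chords.append((tk[1], t[1]))
                    break
                k = (k + 1) % n
            polys.append(poly)
    return polys, chords


def _dedup_ring(keys):
    out = []
    for k in keys:
        if not out or k != out[-1]:
            out.append(k)
    if len(out) > 1 and out[0] == out[-1]:
        out.pop()
    return out


class _NodeBook:
    """Bookkeeping of grid nodes, merged intersection nodes and final ids."""

    def __init__(self, grid_coords: np.ndarray):
        self.grid_coords = grid_coords  # (ngrid, dim)
        self.cross_coords: list[np.ndarray] = []
        self.parent: list[int] = []  # union-find over crossing nodes

    def new_cross(self, p: np.ndarray) -> tuple:
        self.cross_coords.append(np.asarray(p, dtype=float))
        self.parent.append(len(self.parent))
        return ("x", len(self.parent) - 1)

    def _root(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def merge_clusters(self, tol: float) -> None:
        """Collapse crossing nodes closer than tol to their cluster mean."""
        if not self.cross_coords:
            return
        X = np.asarray(self.cross_coords)
        pairs = cKDTree(X).query_pairs(r=tol, output_type="ndarray")
        for a, b in pairs:
            ra, rb = self._root(int(a)), self._root(int(b))
            if ra != rb:
                self.parent[max(ra, rb)] = min(ra, rb)
        clusters: dict[int, list[int]] = {}
        for i in range(len(self.parent)):
            clusters.setdefault(self._root(i), []).append(i)
        for r, members in clusters.items():
            if len(members) > 1:
                self.cross_coords[r] = X[members].mean(axis=0)

    def canon(self, key: tuple) -> tuple:
        if key[0] == "x":
            return ("x", self._root(key[1]))
        return key

    def coords(self, key: tuple) -> np.ndarray:
        if key[0] == "g":
            return self.grid_coords[key[1]]
        return self.cross_coords[key[1]]

    def finalize(self, used_keys) -> dict:
        """Assign final node numbers: grid nodes first, then crossings."""
        gk = sorted(k[1] for k in used_keys if k[0] == "g")
        xk = sorted(k[1] for k in used_keys if k[0] == "x")
        mapping = {("g", i): n for n, i in enumerate(gk)}
        mapping.update({("x", i): len(gk) + n for n, i in enumerate(xk)})
        return mapping


def _edge_crossings(book, fun, F, inside, gid, axes_pts, axis, dx, tol):
    """Crossing node keys for all grid edges along one axis.

    The crossing position on each sign-change edge is located by bisection of
    the level-set function restricted to the edge (exact root up to floating
    point), so boundary nodes lie on the zero level set itself rather than on
    its piecewise linear interpolant.  Returns a dict mapping the low-corner
    grid multi-index to a node key; crossings within ``tol`` of an endpoint
    snap to that grid node.
    """
    lo = inside
    hi = np.roll(inside, -1, axis=axis)
    sl = [slice(None)] * F.ndim
    sl[axis] = slice(0, -1)
    crossed = (lo != hi)[tuple(sl)]
    idxs = np.argwhere(crossed)
    if len(idxs) == 0:
        return {}
    pa = np.column_stack([axes_pts[d][idxs[:, d]] for d in range(F.ndim)])
    fa = F[tuple(idxs.T)]
    jdxs = idxs.copy()
    jdxs[:, axis] += 1
    fb = F[tuple(jdxs.T)]
    # bisection on t in [0, 1]; keep the sign convention f(ta) <= 0 < f(tb)
    swap = fa > 0.0
    ta = np.where(swap, 1.0, 0.0)
    tb = np.where(swap, 0.0, 1.0)
    for _ in range(52):
        tm = 0.5 * (ta + tb)
        pm = pa.copy()
        pm[:, axis] += tm * dx
        fm = np.asarray(fun(pm), dtype=float)
        neg = fm <= 0.0
        ta = np.where(neg, tm, ta)
        tb = np.where(neg, tb, tm)
    t = 0.5 * (ta + tb)
    out = {}
    for k, idx in enumerate(idxs):
        idx = tuple(int(v) for v in idx)
        if t[k] * dx < tol:
            out[idx] = ("g", int(gid[idx]))
            continue
        if (1.0 - t[k]) * dx < tol:
            out[idx] = ("g", int(gid[tuple(jdxs[k])]))
            continue
        p = pa[k].copy()
        p[axis] += t[k] * dx
        out[idx] = book.new_cross(p)
    return out


# --------------------------------------------------------------------------- #
# 2D generator
# --------------------------------------------------------------------------- #

def generate_mesh_2d(domain: LevelSetDomain) -> BulkSurfaceMesh:
    """Marching-squares bulk-surface mesh of a 2D level-set domain."""
    if domain.dim != 2:
        raise ValueError("generate_mesh_2d needs a 2D domain")
    axes, dx = domain.grid()
    tol = domain.tol if domain.tol is not None else 1e-6 * dx
    xs, ys = axes
    nx, ny = len(xs), len(ys)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel()])
    F = np.asarray(domain.fun(pts), dtype=float).reshape(nx, ny)
    if not np.all(np.isfinite(F)):
        raise ValueError("level-set function is not finite on the bounding box")
    inside = F <= 0.0
    gid = np.arange(nx * ny).reshape(nx, ny)
    grid_coords = pts
    book = _NodeBook(grid_coords)
    cross = {
        0: _edge_crossings(book, domain.fun, F, inside, gid, axes, 0, dx, tol),
        1: _edge_crossings(book, domain.fun, F, inside, gid, axes, 1, dx, tol),
    }
    book.merge_clusters(tol)

    # cell centers for saddle disambiguation
    cx = 0.5 * (xs[:-1] + xs[1:])
    cy = 0.5 * (ys[:-1] + ys[1:])
    CX, CY = np.meshgrid(cx, cy, indexing="ij")
    Fc = np.asarray(domain.fun(np.column_stack([CX.ravel(), CY.ravel()])),
                    dtype=float).reshape(nx - 1, ny - 1)

    squares = []   # (ring keys,) full cells
    polygons = []  # cut-cell polygons (key lists)
    chords = []    # directed surface chords
    ncell_in = inside[:-1, :-1].astype(int) + inside[1:, :-1] + \
        inside[1:, 1:] + inside[:-1, 1:]
    for i, j in np.argwhere(ncell_in > 0):
        i, j = int(i), int(j)
        ring = [("g", int(gid[i, j])), ("g", int(gid[i + 1, j])),
                ("g", int(gid[i + 1, j + 1])), ("g", int(gid[i, j + 1]))]
        ins = [bool(inside[i, j]), bool(inside[i + 1, j]),
               bool(inside[i + 1, j + 1]), bool(inside[i, j + 1])]
        if all(ins):
            squares.append(ring)
            continue
        xing = [cross[0].get((i, j)), cross[1].get((i + 1, j)),
                cross[0].get((i, j + 1)), cross[1].get((i, j))]
        xing = [None if k is None else book.canon(k) for k in xing]
        polys, chds = _cut_ring(ring, ins, xing, bool(Fc[i, j] <= 0.0))
        for p in polys:
            p = _dedup_ring(p)
            if len(p) >= 3:
                polygons.append(p)
        for a, b in chds:
            if a != b:
                chords.append((a, b))

    if not squares and not polygons:
        raise EmptyDomainError("no grid cell intersects the domain")

    used = set()
    for ring in itertools.chain(squares, polygons):
        used.update(ring)
    for a, b in chords:
        used.add(a)
        used.add(b)
    mapping = book.finalize(used)
    P = np.zeros((len(mapping), 3))
    for key, n in mapping.items():
        P[n, :2] = book.coords(key)

    elements = []
    h = np.sqrt(2.0) * dx if squares else 0.0
    for ring in squares:
        idx = np.array([mapping[k] for k in ring], dtype=np.int64)
        elements.append(PolygonElement(P[idx], Pind=idx, is_square=True))
    for ring in polygons:
        idx = np.array([mapping[k] for k in ring], dtype=np.int64)
        el = PolygonElement(P[idx], Pind=idx)
        elements.append(el)
        h = max(h, el.diameter)
    surf = np.array(
        [[mapping[a], mapping[b]] for a, b in chords], dtype=np.int64
    ).reshape(-1, 2)
    return BulkSurfaceMesh(P=P, h=float(h), bulk_elements=elements,
                           surf_elements=surf, dim=2)


# --------------------------------------------------------------------------- #
# 3D generator
# --------------------------------------------------------------------------- #

# per cell: the 6 faces as (corner multi-index offsets ring, which is chosen so
# that the ring is counterclockwise seen from outside the cell)
_CUBE_FACES_3D = (
    # (ring of corner offsets, (axis of the face plane normal, fixed offset))
    (((0, 0, 0), (0, 0, 1), (0, 1, 1), (0, 1, 0)), (0, 0)),
    (((1, 0, 0), (1, 1, 0), (1, 1, 1), (1, 0, 1)), (0, 1)),
    (((0, 0, 0), (1, 0, 0), (1, 0, 1), (0, 0, 1)), (1, 0)),
    (((0, 1, 0), (0, 1, 1), (1, 1, 1), (1, 1, 0)), (1, 1)),
    (((0, 0, 0), (0, 1, 0), (1, 1, 0), (1, 0, 0)), (2, 0)),
    (((0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1)), (2, 1)),
)


def _ring_edge_key(a, b):
    """(axis, low-corner multi-index) of the grid edge between corner offsets."""
    axis = next(d for d in range(3) if a[d] != b[d])
    lo = tuple(min(a[d], b[d]) for d in range(3))
    return axis, lo


def generate_mesh_3d(
    domain: LevelSetDomain, xcut: Optional[float] = None
) -> BulkSurfaceMesh:
    """Marching-cubes bulk-surface mesh of a 3D level-set domain.

    Cut cells become polyhedra whose faces are the clipped portions of the
    six cube faces plus the isosurface patch triangles; the patch triangles
    are also the surface mesh.  With ``xcut`` given, ``plot_elements`` holds
    the boundary faces of the sub-mesh of elements with centroid x <= xcut.
    """
    if domain.dim != 3:
        raise ValueError("generate_mesh_3d needs a 3D domain")
    axes, dx = domain.grid()
    tol = domain.tol if domain.tol is not None else 1e-6 * dx
    xs, ys, zs = axes
    nx, ny, nz = len(xs), len(ys), len(zs)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    F = np.asarray(domain.fun(pts), dtype=float).reshape(nx, ny, nz)
    if not np.all(np.isfinite(F)):
        raise ValueError("level-set function is not finite on the bounding box")
    inside = F <= 0.0
    gid = np.arange(nx * ny * nz).reshape(nx, ny, nz)
    book = _NodeBook(pts)
    cross = {
        d: _edge_crossings(book, domain.fun, F, inside, gid, axes, d, dx, tol)
        for d in range(3)
    }
    book.merge_clusters(tol)

    def centers(axis_pts):
        return 0.5 * (axis_pts[:-1] + axis_pts[1:])

    cx, cy, cz = centers(xs), centers(ys), centers(zs)

    def fun_on(gridxyz):
        A, B, C = np.meshgrid(*gridxyz, indexing="ij")
        vals = domain.fun(np.column_stack([A.ravel(), B.ravel(), C.ravel()]))
        return np.asarray(vals, dtype=float).reshape(A.shape)

    Fcell = fun_on((cx, cy, cz))              # cell centers
    Fface = {
        0: fun_on((xs, cy, cz)),              # x-normal face centers
        1: fun_on((cx, ys, cz)),
        2: fun_on((cx, cy, zs)),
    }

    corner_in = np.zeros((nx - 1, ny - 1, nz - 1), dtype=int)
    for ox, oy, oz in itertools.product((0, 1), repeat=3):
        corner_in += inside[ox:nx - 1 + ox, oy:ny - 1 + oy, oz:nz - 1 + oz]

    cube_rings = []     # full cells: binary-order key lists
    cut_records = []    # (cell index, faces(key lists), patch triangles)
    surf_tris = []      # (keys triple, cell index)
    h_cut = 0.0

    for ci, cj, ck in np.argwhere(corner_in > 0):
        ci, cj, ck = int(ci), int(cj), int(ck)
        if corner_in[ci, cj, ck] == 8:
            ring = [("g", int(gid[ci + ox, cj + oy, ck + oz]))
                    for ox, oy, oz in itertools.product((0, 1), repeat=3)]
            cube_rings.append((ci, cj, ck, ring))
            continue
        faces = []
        chords = []
        for ring_off, (fax, fside) in _CUBE_FACES_3D:
            ring = []
            ins = []
            xing = []
            for t in range(4):
                a = ring_off[t]
                b = ring_off[(t + 1) % 4]
                ring.append(("g", int(gid[ci + a[0], cj + a[1], ck + a[2]])))
                ins.append(bool(inside[ci + a[0], cj + a[1], ck + a[2]]))
                axis, lo = _ring_edge_key(a, b)
                key = cross[axis].get((ci + lo[0], cj + lo[1], ck + lo[2]))
                xing.append(None if key is None else book.canon(key))
            fc_idx = [ci, cj, ck]
            fc_idx[fax] += fside
            fcenter_in = bool(Fface[fax][tuple(fc_idx)] <= 0.0)
            polys, chds = _cut_ring(ring, ins, xing, fcenter_in)
            for p in polys:
                p = _dedup_ring(p)
                if len(p) >= 3:
                    faces.append(p)
            for a, b in chds:
                if a != b:
                    chords.append((a, b))
        # assemble chords into closed loops and fan-triangulate
        start: dict[tuple, list] = {}
        for c in chords:
            start.setdefault(c[0], []).append(c)
        unused = set(range(len(chords)))
        tagged = {id(c): k for k, c in enumerate(chords)}
        loops = []
        for k0 in list(unused):
            if k0 not in unused:
                continue
            loop = []
            c = chords[k0]
            while True:
                kc = tagged[id(c)]
                if kc not in unused:
                    break
                unused.discard(kc)
                loop.append(c[0])
                nxt = None
                for cand in start.get(c[1], ()):
                    if tagged[id(cand)] in unused:
                        nxt = cand
                        break
                if nxt is None:
                    break
                c = nxt
            loop = _dedup_ring(loop)
            if len(loop) >= 3:
                loops.append(loop)
        cell_tris = []
        for loop in loops:
            for tri in _triangulate_loop(loop, book, domain.fun):
                if len(set(tri)) == 3:
                    cell_tris.append(tri)
        faces = faces + cell_tris
        if faces:
            cut_records.append(((ci, cj, ck), faces, cell_tris))

    if not cube_rings and not cut_records:
        raise EmptyDomainError("no grid cell intersects the domain")

    used = set()
    for _, _, _, ring in cube_rings:
        used.update(ring)
    for _, faces, _ in cut_records:
        for fkeys in faces:
            used.update(fkeys)
    mapping = book.finalize(used)
    P = np.zeros((len(mapping), 3))
    for key, n in mapping.items():
        P[n] = book.coords(key)

    elements = []
    h = np.sqrt(3.0) * dx if cube_rings else 0.0
    for ci, cj, ck, ring in cube_rings:
        idx = np.array([mapping[k] for k in ring], dtype=np.int64)
        elements.append(PolyhedronElement(
            P[idx], P0=np.array([cx[ci], cy[cj], cz[ck]]),
            Pind=idx, is_cube=True))

    for cell, faces, cell_tris in cut_records:
        elements_here = _split_components(faces)
        for comp_faces in elements_here:
            vkeys = sorted({k for f in comp_faces for k in f})
            if len(vkeys) < 4:
                continue
            lut = {k: i for i, k in enumerate(vkeys)}
            idx = np.array([mapping[k] for k in vkeys], dtype=np.int64)
            V = P[idx]
            face_objs = []
            face_local = []
            patch = {tuple(sorted(tri)) for tri in cell_tris}
            for fkeys in comp_faces:
                fl = np.array([lut[k] for k in fkeys], dtype=np.int64)
                is_patch = tuple(sorted(fkeys)) in patch
                face_objs.append(PolygonElement(
                    V[fl], Pind=idx[fl], is_boundary=is_patch))
                face_local.append(fl)
            try:
                el = PolyhedronElement(V, face_objs, Pind=idx,
                                       face_local=face_local, orient=True)
                el.check_watertight()
            except Exception as exc:
                raise type(exc)(
                    f"cut cell {cell} produced an invalid polyhedron: {exc}"
                ) from exc
            elements.append(el)
            h_cut = max(h_cut, el.diameter)
        for tri in cell_tris:
            surf_tris.append(tri)
    h = max(h, h_cut)

    # orient surface triangles outward (normal toward f > 0)
    surf = np.array([[mapping[k] for k in tri] for tri in surf_tris],
                    dtype=np.int64).reshape(-1, 3)
    if len(surf):
        eps = 0.01 * dx
        A, B, C = P[surf[:, 0]], P[surf[:, 1]], P[surf[:, 2]]
        nrm = np.cross(B - A, C - A)
        ln = np.linalg.norm(nrm, axis=1, keepdims=True)
        ln[ln == 0.0] = 1.0
        nrm /= ln
        cen = (A + B + C) / 3.0
        fout = np.asarray(domain.fun(cen + eps * nrm), dtype=float)
        fin = np.asarray(domain.fun(cen - eps * nrm), dtype=float)
        flip = fout < fin
        surf[flip] = surf[flip][:, ::-1]

    plot_elements = None
    if xcut is not None:
        plot_elements = _cut_plane_boundary(P, elements, xcut)

    return BulkSurfaceMesh(P=P, h=float(h), bulk_elements=elements,
                           surf_elements=surf, plot_elements=plot_elements,
                           dim=3)


def _triangulate_loop(loop, book, fun):
    """Triangulate an isosurface patch loop so it hugs the zero level set.

    Among all triangulations of the (possibly non-planar) loop, a small
    dynamic program picks the one minimizing the integrated deviation
    ``sum area(T) * |f(centroid(T))|`` — the patch counterpart of the
    asymptotic decider, and deterministic.
    """
    n = len(loop)
    if n == 3:
        return [list(loop)]
    pts = [book.coords(k) for k in loop]

    def cost(i, k, j):
        a, b, c = pts[i], pts[k], pts[j]
        cen = (a + b + c) / 3.0
        area = 0.5 * np.linalg.norm(np.cross(b - a, c - a))
        return area * abs(float(np.asarray(fun(cen[None, :])).ravel()[0]))

    best = {}
    choice = {}
    for i in range(n - 1):
        best[(i, i + 1)] = 0.0
    for span in range(2, n):
        for i in range(n - span):
            j = i + span
            val, arg = np.inf, i + 1
            for k in range(i + 1, j):
                q = cost(i, k, j) + best[(i, k)] + best[(k, j)]
                if q < val:
                    val, arg = q, k
            best[(i, j)] = val
            choice[(i, j)] = arg
    tris = []

    def emit(i, j):
        if j - i < 2:
            return
        k = choice[(i, j)]
        tris.append([loop[i], loop[k], loop[j]])
        emit(i, k)
        emit(k, j)

    emit(0, n - 1)
    return tris


def _split_components(faces):
    """Group face key-lists into edge-connected components."""
    if len(faces) <= 1:
        return [faces]
    edge_of = {}
    adj = [[] for _ in faces]
    for fi, fkeys in enumerate(faces):
        for t in range(len(fkeys)):
            e = tuple(sorted((fkeys[t], fkeys[(t + 1) % len(fkeys)])))
            if e in edge_of:
                fj = edge_of[e]
                adj[fi].append(fj)
                adj[fj].append(fi)
            else:
                edge_of[e] = fi
    seen = [False] * len(faces)
    comps = []
    for s in range(len(faces)):
        if seen[s]:
            continue
        stack, comp = [s], []
        seen[s] = True
        while stack:
            u = stack.pop()
            comp.append(faces[u])
            for v in adj[u]:
                if not seen[v]:
                    seen[v] = True
                    stack.append(v)
        comps.append(comp)
    return comps


def _cut_plane_boundary(P, elements, xcut):
    """Boundary faces of the element subset with centroid x <= xcut."""
    count: dict[tuple, tuple] = {}
    for el in elements:
        if P[el.Pind, 0].mean() > xcut:
            continue
        for face, fl in zip(el.faces, el.face_local):
            key = tuple(sorted(int(i) for i in el.Pind[fl]))
            if key in count:
                count[key] = None
            else:
                count[key] = (face, el.Pind[fl])
    out = []
    for key, rec in count.items():
        if rec is None:
            continue
        face, pind = rec
        out.append(PolygonElement(face.vertices, Pind=pind,
                                  is_boundary=face.is_boundary))
    return out


# --------------------------------------------------------------------------- #
# surface import
# --------------------------------------------------------------------------- #

def import_surface(nodes: np.ndarray, triangles: np.ndarray) -> BulkSurfaceMesh:
    """Surface-only mesh from a node table and a triangle connectivity table.

    The (N, 3) / (M, 3) two-table format is the common output of third-party
    surface mesh generators; the resulting mesh has no bulk elements and can
    be fed directly to the surface assembly and solvers.
    """
    P = np.atleast_2d(np.asarray(nodes, dtype=float))
    T = np.atleast_2d(np.asarray(triangles, dtype=np.int64))
    if P.shape[1] != 3 or T.shape[1] != 3:
        raise ValueError("nodes must be (N, 3) and triangles (M, 3)")
    if T.min(initial=0) < 0 or T.max(initial=-1) >= len(P):
        raise IndexError("triangle table contains out-of-range node indices")
    h = 0.0
    for ti, tri in enumerate(T):
        V = P[tri]
        area2 = np.linalg.norm(np.cross(V[1] - V[0], V[2] - V[0]))
        if area2 == 0.0:
            raise ValueError(f"triangle {ti} has zero area")
        h = max(h, polytope_diameter(V))
    return BulkSurfaceMesh(P=P, h=float(h), bulk_elements=[],
                           surf_elements=T, dim=3)
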