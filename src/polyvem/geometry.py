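"""Polytopal element data model and geometric primitives.

Bulk meshes are collections of polygonal (2D) or polyhedral (3D) elements.
Every element carries a *star point* ``P0`` with respect to which it is
star-shaped; the star decomposition into triangles/tetrahedra from ``P0`` is
what makes exact low-degree quadrature possible on arbitrary polytopes.

All vertices carry three coordinates, even for planar elements, because
polygons double as faces of polyhedra; 2D meshes simply keep the third
coordinate at zero.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from shapely.geometry import LineString, Polygon as _ShapelyPolygon


class DegenerateGeometryError(ValueError):
    """Raised for geometrically degenerate input (zero area/volume, collinear rings)."""


class NonWatertightError(ValueError):
    """Raised when a polyhedron's face list does not close up."""


# --------------------------------------------------------------------------- #
# free-standing primitives
# --------------------------------------------------------------------------- #

def polytope_diameter(vertices: np.ndarray) -> float:
    """Maximum pairwise Euclidean distance between the given points.

    The mesh size ``h`` of a bulk mesh is the maximum element diameter.
    """
    V = np.asarray(vertices, dtype=float)
    if V.ndim != 2 or V.shape[0] < 2:
        raise ValueError("polytope_diameter needs at least 2 points")
    # elements are small: the O(n^2) distance matrix is cheapest here
    d2 = np.sum((V[:, None, :] - V[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max()))


def _plane_frame(V: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Orthonormal in-plane axes (e1, e2) and unit normal n of a planar ring.

    The normal follows the vertex order by the right-hand rule (Newell's
    method), so a counterclockwise ring in the xy-plane yields n = +e_z.
    """
    n = np.zeros(3)
    for i in range(len(V)):
        a, b = V[i], V[(i + 1) % len(V)]
        n += np.cross(a, b)
    nn = np.linalg.norm(n)
    if nn == 0.0:
        raise DegenerateGeometryError("degenerate polygon: zero-area vertex ring")
    n /= nn
    # e1: global x-axis projected into the plane (falls back to y), so that
    # planar elements in the xy-plane use the global axes as local frame
    for axis in (np.array([1.0, 0, 0]), np.array([0, 1.0, 0])):
        ref = axis - n * (axis @ n)
        if np.linalg.norm(ref) > 1e-8:
            break
    e1 = ref / np.linalg.norm(ref)
    e2 = np.cross(n, e1)
    return e1, e2, n


def polygon_measure(element: "PolygonElement") -> tuple[float, np.ndarray, np.ndarray]:
    """Area, area centroid and unit normal of a planar polygon.

    The normal follows the vertex order (right-hand rule).  Raises
    :class:`DegenerateGeometryError` for rings of zero area.
    """
    V = element.vertices
    e1, e2, n = _plane_frame(V)
    o = V.mean(axis=0)
    x = (V - o) @ e1
    y = (V - o) @ e2
    xs, ys = np.roll(x, -1), np.roll(y, -1)
    cross = x * ys - xs * y
    area2 = cross.sum()
    area = abs(area2) / 2.0
    diam2 = max(np.ptp(x), np.ptp(y)) ** 2 + 1e-300
    if area < 1e-12 * diam2 or area == 0.0:
        raise DegenerateGeometryError("degenerate polygon: zero area")
    cx = ((x + xs) * cross).sum() / (3.0 * area2)
    cy = ((y + ys) * cross).sum() / (3.0 * area2)
    centroid = o + cx * e1 + cy * e2
    return float(area), centroid, n


def polyhedron_measure(element: "PolyhedronElement") -> tuple[float, np.ndarray]:
    """Volume and volume centroid by star decomposition into tetrahedra.

    Each face is fan-triangulated from its own star point and every face
    triangle is coned to the element star point ``P0``; with outward-oriented
    faces the signed tetrahedron volumes sum to the element volume.
    """
    element.check_watertight()
    P0 = element.P0
    vol = 0.0
    cmom = np.zeros(3)
    for face in element.faces:
        V = face.vertices
        c = V.mean(axis=0)
        for i in range(len(V)):
            a, b = V[i], V[(i + 1) % len(V)]
            v6 = np.dot(np.cross(a - P0, b - P0), c - P0)
            vol += v6
            cmom += v6 * (P0 + a + b + c)
    vol /= 6.0
    if vol <= 0.0:
        raise DegenerateGeometryError(
            "polyhedron has non-positive volume; check face orientation"
        )
    centroid = cmom / (24.0 * vol)
    return float(vol), centroid


def check_star_shaped(element) -> bool:
    """True iff the element is star-shaped with respect to its star point P0."""
    return element.is_star_shaped()


# --------------------------------------------------------------------------- #
# element classes
# --------------------------------------------------------------------------- #

class PolygonElement:
    """A planar polygonal element given by an ordered vertex ring.

    Parameters
    ----------
    vertices : (NVert, 3) array
        Ring of vertex coordinates, ordered clockwise or counterclockwise.
    P0 : (3,) array, optional
        Star point; defaults to the vertex average.
    Pind : sequence of int, optional
        Global node indices aligned with ``vertices`` when the element is
        part of a mesh (``P_mesh[Pind] == vertices``).
    is_square : bool
        Marks axis-aligned squares, for which local matrices are known in
        closed form.
    is_boundary : bool
        Marks faces of 3D elements lying on the surface.
    """

    __slots__ = ("vertices", "P0", "Pind", "is_square", "is_boundary")

    def __init__(
        self,
        vertices: np.ndarray,
        P0: Optional[np.ndarray] = None,
        Pind: Optional[Sequence[int]] = None,
        is_square: bool = False,
        is_boundary: bool = False,
    ):
        V = np.atleast_2d(np.asarray(vertices, dtype=float))
        if V.shape[1] == 2:
            V = np.column_stack([V, np.zeros(len(V))])
        if V.shape[0] < 3 or V.shape[1] != 3:
            raise DegenerateGeometryError("a polygon needs >=3 points with 3 coordinates")
        self.vertices = V
        self.P0 = np.asarray(P0, dtype=float) if P0 is not None else V.mean(axis=0)
        self.Pind = None if Pind is None else np.asarray(Pind, dtype=np.int64)
        self.is_square = bool(is_square)
        self.is_boundary = bool(is_boundary)

    @property
    def nvert(self) -> int:
        return len(self.vertices)

    @property
    def diameter(self) -> float:
        return polytope_diameter(self.vertices)

    def measure(self) -> tuple[float, np.ndarray, np.ndarray]:
        return polygon_measure(self)

    def local_coords(self):
        """In-plane coordinates (x, y) of the ring, counterclockwise.

        Returns (x, y, frame) with frame = (origin, e1, e2, n); the frame is
        flipped if needed so that the returned ring has positive signed area.
        """
        V = self.vertices
        e1, e2, n = _plane_frame(V)
        o = V.mean(axis=0)
        x = (V - o) @ e1
        y = (V - o) @ e2
        if 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y) < 0.0:
            e2, n = -e2, -n
            y = -y
        return x, y, (o, e1, e2, n)

    def is_star_shaped(self, tol: float = 1e-12) -> bool:
        """Visibility check: every segment from P0 to a vertex stays inside."""
        x, y, (o, e1, e2, _) = self.local_coords()
        try:
            poly = _ShapelyPolygon(np.column_stack([x, y]))
        except Exception:
            return False
        if not poly.is_valid or poly.area <= 0.0:
            return False
        p0 = np.array([(self.P0 - o) @ e1, (self.P0 - o) @ e2])
        eps = tol * max(1.0, self.diameter)
        fat = poly.buffer(eps)
        for xi, yi in zip(x, y):
            seg = LineString([p0, (xi, yi)])
            if not fat.covers(seg):
                return False
        return True


class PolyhedronElement:
    """A polyhedral element: vertices plus a closed list of polygonal faces.

    Faces are re-oriented at construction so their normals point outward of
    the star point ``P0`` (default: vertex average); the face list must be
    watertight (every edge shared by exactly two faces).
    """

    __slots__ = ("vertices", "_faces", "P0", "Pind", "is_cube", "_face_local")

    #: local vertex rings of the 6 faces of a cube whose vertices are listed
    #: in binary order (bits x,y,z with z fastest); rings are oriented so the
    #: face normals point outward.
    CUBE_FACE_RINGS = (
        (0, 1, 3, 2),  # x = 0
        (4, 6, 7, 5),  # x = 1
        (0, 4, 5, 1),  # y = 0
        (2, 3, 7, 6),  # y = 1
        (0, 2, 6, 4),  # z = 0
        (1, 5, 7, 3),  # z = 1
    )

    def __init__(
        self,
        vertices: np.ndarray,
        faces: Optional[Sequence[PolygonElement]] = None,
        P0: Optional[np.ndarray] = None,
        Pind: Optional[Sequence[int]] = None,
        is_cube: bool = False,
        face_local: Optional[Sequence[np.ndarray]] = None,
        orient: bool = True,
    ):
        V = np.atleast_2d(np.asarray(vertices, dtype=float))
        if V.shape[0] < 4 or V.shape[1] != 3:
            raise DegenerateGeometryError("a polyhedron needs >=4 points in 3-space")
        self.vertices = V
        self.P0 = np.asarray(P0, dtype=float) if P0 is not None else V.mean(axis=0)
        self.Pind = None if Pind is None else np.asarray(Pind, dtype=np.int64)
        self.is_cube = bool(is_cube)
        if faces is None:
            if not self.is_cube:
                raise ValueError("faces may only be omitted for cube elements")
            self._faces = None  # built lazily from CUBE_FACE_RINGS
            self._face_local = None
            return
        self._faces = list(faces)
        if face_local is not None:
            self._face_local = [np.asarray(fl, dtype=np.int64) for fl in face_local]
        else:
            self._face_local = self._match_faces()
        if orient:
            self._orient_faces_outward()

    @property
    def faces(self) -> list[PolygonElement]:
        if self._faces is None:
            self._build_cube_faces()
        return self._faces

    @property
    def face_local(self) -> list[np.ndarray]:
        if self._faces is None:
            self._build_cube_faces()
        return self._face_local

    def _build_cube_faces(self) -> None:
        self._face_local = [np.array(r, dtype=np.int64) for r in self.CUBE_FACE_RINGS]
        self._faces = [
            PolygonElement(
                self.vertices[list(r)],
                Pind=None if self.Pind is None else self.Pind[list(r)],
                is_square=True,
            )
            for r in self.CUBE_FACE_RINGS
        ]

    # -- construction helpers ------------------------------------------------

    def _match_faces(self) -> list[np.ndarray]:
        """Map each face vertex to an element vertex index (by coordinates)."""
        scale = polytope_diameter(self.vertices)
        tol = 1e-9 * max(scale, 1.0)
        out = []
        for face in self.faces:
            idx = np.empty(face.nvert, dtype=np.int64)
            for k, p in enumerate(face.vertices):
                d = np.linalg.norm(self.vertices - p, axis=1)
                j = int(np.argmin(d))
                if d[j] > tol:
                    raise ValueError("face vertex is not a vertex of the polyhedron")
                idx[k] = j
            out.append(idx)
        return out

    def _orient_faces_outward(self) -> None:
        for i, face in enumerate(self._faces):
            _, centroid, n = polygon_measure(face)
            if (centroid - self.P0) @ n < 0.0:
                face.vertices = face.vertices[::-1].copy()
                if face.Pind is not None:
                    face.Pind = face.Pind[::-1].copy()
                self._face_local[i] = self._face_local[i][::-1].copy()

    # -- queries -------------------------------------------------------------

    @property
    def nvert(self) -> int:
        return len(self.vertices)

    @property
    def diameter(self) -> float:
        return polytope_diameter(self.vertices)

    def measure(self) -> tuple[float, np.ndarray]:
        return polyhedron_measure(self)

    def check_watertight(self) -> None:
        """Every undirected face edge must be shared by exactly two faces."""
        count: dict[tuple[int, int], int] = {}
        for idx in self.face_local:
            for k in range(len(idx)):
                a, b = int(idx[k]), int(idx[(k + 1) % len(idx)])
                key = (a, b) if a < b else (b, a)
                count[key] = count.get(key, 0) + 1
        bad = [e for e, c in count.items() if c != 2]
        if bad:
            raise NonWatertightError(
                f"polyhedron is not watertight: edge {bad[0]} belongs to "
                f"{count[bad[0]]} face(s)"
            )

    def is_star_shaped(self, tol: float = 1e-10) -> bool:
        """P0 must lie strictly on the inner side of every outward face plane."""
        h = self.diameter
        for face in self.faces:
            try:
                _, centroid, n = polygon_measure(face)
            except DegenerateGeometryError:
                return False
            if (centroid - self.P0) @ n <= tol * h - h * 1e-9:
                if (centroid - self.P0) @ n <= 0.0:
                    return False
        return True
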