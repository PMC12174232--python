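"""Lowest-order (k=1) virtual element local matrices on polygons and polyhedra.

For each element the virtual space is spanned by one degree of freedom per
vertex.  The elliptic projector ``Pi`` maps a virtual function onto linear
polynomials using only boundary information; the local matrices are

* stiffness  ``K = K_cons + s_K (I - Pi)^T (I - Pi)``,
* consistency ``C = coeffs^T H coeffs``  (the Gram form of the projections),
* mass       ``M = C + |E| (I - Pi)^T (I - Pi)``,

with the "dofi-dofi" stabilization scaled by ``s_K = 1`` in 2D and by the
element diameter in 3D.  Scaled monomials are centered at the vertex average
and scaled by the element diameter.

On simplices (triangles / tetrahedra) the stabilization term vanishes on the
polynomial subspace and K, M coincide with the classical P1 finite element
matrices.  On axis-aligned squares and cubes the matrices are known in closed
form and exposed by :func:`closed_form_square` / :func:`closed_form_cube`.

Surface operators on curves (segments) and triangulated surfaces are plain
P1 finite elements (:func:`local_surface_segment`,
:func:`local_surface_triangle`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import (
    DegenerateGeometryError,
    PolygonElement,
    PolyhedronElement,
    polygon_measure,
    polyhedron_measure,
    polytope_diameter,
)

__all__ = [
    "LocalMatrixSet",
    "Projector",
    "monomial_gram",
    "pi_nabla",
    "pi_nabla_3d",
    "local_matrices_2d",
    "local_matrices_3d",
    "closed_form_square",
    "closed_form_cube",
    "local_surface_segment",
    "local_surface_triangle",
]


@dataclass
class LocalMatrixSet:
    """Dense local stiffness K, consistency C and mass M of one element."""

    K: np.ndarray
    C: np.ndarray
    M: np.ndarray


@dataclass
class Projector:
    """Elliptic projection onto linears for one element.

    ``coeffs`` maps vertex dofs to coefficients in the scaled monomial basis
    (dim P1 x NVert); ``dofmat`` evaluates the projected polynomial back at
    the vertices (NVert x NVert, idempotent).
    """

    coeffs: np.ndarray
    dofmat: np.ndarray
    center: np.ndarray
    h: float


# degree-2 exact quadrature on the reference triangle (edge midpoints)
_TRI_QP = np.array([[0.5, 0.0], [0.5, 0.5], [0.0, 0.5]])
_TRI_QW = np.full(3, 1.0 / 3.0)

# degree-2 exact quadrature on the reference tetrahedron
_a = (5.0 + 3.0 * np.sqrt(5.0)) / 20.0
_b = (5.0 - np.sqrt(5.0)) / 20.0
_TET_QP = np.array(
    [
        [_a, _b, _b],
        [_b, _a, _b],
        [_b, _b, _a],
        [_b, _b, _b],
    ]
)
_TET_QW = np.full(4, 0.25)


# --------------------------------------------------------------------------- #
# monomial Gram matrices
# --------------------------------------------------------------------------- #

def _gram_2d(element: PolygonElement, center: np.ndarray, h: float) -> np.ndarray:
    """H_ab = int_E m_a m_b for m = (1, xi, eta) on a planar polygon.

    Integrates exactly for quadratics on the star decomposition (triangle fan
    from P0).
    """
    x, y, (o, e1, e2, _) = element.local_coords()
    p0 = np.array([(element.P0 - o) @ e1, (element.P0 - o) @ e2])
    c2 = np.array([(center - o) @ e1, (center - o) @ e2])
    H = np.zeros((3, 3))
    n = len(x)
    for i in range(n):
        a = np.array([x[i], y[i]])
        b = np.array([x[(i + 1) % n], y[(i + 1) % n]])
        J = np.column_stack([a - p0, b - p0])
        det = J[0, 0] * J[1, 1] - J[0, 1] * J[1, 0]
        if det == 0.0:
            continue
        pts = p0 + _TRI_QP @ J.T
        w = _TRI_QW * (det / 2.0)  # signed: fan handles nonconvexity
        m = np.column_stack(
            [np.ones(len(pts)), (pts[:, 0] - c2[0]) / h, (pts[:, 1] - c2[1]) / h]
        )
        H += (m * w[:, None]).T @ m
    return H


def _gram_3d(element: PolyhedronElement, center: np.ndarray, h: float) -> np.ndarray:
    """H_ab = int_E m_a m_b on a polyhedron via the star tetrahedralization."""
    P0 = element.P0
    H = np.zeros((4, 4))
    for face in element.faces:
        V = face.vertices
        fc = V.mean(axis=0)
        for i in range(len(V)):
            a, b = V[i], V[(i + 1) % len(V)]
            # tetra (P0, fc, a, b); columns of J span it from P0
            J = np.column_stack([fc - P0, a - P0, b - P0])
            det = np.linalg.det(J)
            if det == 0.0:
                continue
            pts = P0 + _TET_QP @ J.T
            w = _TET_QW * (det / 6.0)
            m = np.column_stack([np.ones(len(pts)), (pts - center) / h])
            H += (m * w[:, None]).T @ m
    return H


def monomial_gram(element) -> np.ndarray:
    """Gram matrix of the scaled monomials (1, (x-xbar)/h, ...) on the element.

    ``xbar`` is the vertex average and ``h`` the element diameter.  Requires a
    star-shaped element (the quadrature rides on the star decomposition).
    """
    if isinstance(element, PolyhedronElement):
        if not element.is_star_shaped():
            raise DegenerateGeometryError("element is not star-shaped w.r.t. P0")
        return _gram_3d(element, element.vertices.mean(axis=0), element.diameter)
    if not element.is_star_shaped():
        raise DegenerateGeometryError("element is not star-shaped w.r.t. P0")
    x, y, (o, e1, e2, _) = element.local_coords()
    # center in 3D = vertex average; project to the same frame used internally
    return _gram_2d(element, element.vertices.mean(axis=0), element.diameter)


# --------------------------------------------------------------------------- #
# projectors
# --------------------------------------------------------------------------- #

def pi_nabla(element: PolygonElement) -> Projector:
    """Elliptic projector onto P1 for a polygon.

    Boundary integrals use the trapezoid rule edge-wise, which is exact
    because virtual functions are linear on edges; the constant part is fixed
    by matching the vertex average.
    """
    x, y, _frame = element.local_coords()
    n = len(x)
    h = element.diameter
    xb, yb = x.mean(), y.mean()
    # dof matrix of the monomials
    D = np.column_stack([np.ones(n), (x - xb) / h, (y - yb) / h])
    B = np.zeros((3, n))
    B[0, :] = 1.0 / n
    for i in range(n):
        j = (i + 1) % n
        ex, ey = x[j] - x[i], y[j] - y[i]
        ell = np.hypot(ex, ey)
        if ell == 0.0:
            raise DegenerateGeometryError("polygon has a zero-length edge")
        # outward normal of a CCW ring
        nx, ny = ey / ell, -ex / ell
        # int_e phi_k (grad m_a . n) : trapezoid, exact for linear traces
        B[1, i] += 0.5 * ell * nx / h
        B[1, j] += 0.5 * ell * nx / h
        B[2, i] += 0.5 * ell * ny / h
        B[2, j] += 0.5 * ell * ny / h
    G = B @ D
    coeffs = np.linalg.solve(G, B)
    return Projector(coeffs=coeffs, dofmat=D @ coeffs,
                     center=element.vertices.mean(axis=0), h=h)


def pi_nabla_3d(element: PolyhedronElement) -> Projector:
    """Elliptic projector onto P1 for a polyhedron.

    The boundary term sum_F (grad m . n_F) int_F v uses each face's own 2D
    projector: ``int_F v = |F| * (Pi_F v)(face centroid)``, computable from
    vertex dofs alone.  Faces must be star-shaped.
    """
    V = element.vertices
    n = len(V)
    h = element.diameter
    center = V.mean(axis=0)
    D = np.column_stack([np.ones(n), (V - center) / h])
    B = np.zeros((4, n))
    B[0, :] = 1.0 / n
    for face, loc in zip(element.faces, element.face_local):
        area, centroid, nrm = polygon_measure(face)
        w = _face_mean_weights(face, centroid)  # mean of Pi_F v over F
        for a in range(3):
            B[1 + a, loc] += (nrm[a] / h) * area * w
    G = B @ D
    coeffs = np.linalg.solve(G, B)
    return Projector(coeffs=coeffs, dofmat=D @ coeffs, center=center, h=h)


def _face_mean_weights(face: PolygonElement, centroid: np.ndarray) -> np.ndarray:
    """Weights w with (1/|F|) int_F Pi_F v = w . dofs for a polygonal face."""
    proj = pi_nabla(face)
    x, y, (o, e1, e2, _) = face.local_coords()
    cx = (centroid - o) @ e1
    cy = (centroid - o) @ e2
    m = np.array([1.0, (cx - x.mean()) / proj.h, (cy - y.mean()) / proj.h])
    return m @ proj.coeffs


# --------------------------------------------------------------------------- #
# local matrices
# --------------------------------------------------------------------------- #

def _matrices_from_projector(
    proj: Projector, H: np.ndarray, measure: float, stab_K: float
) -> LocalMatrixSet:
    s = proj.coeffs
    Pi = proj.dofmat
    n = Pi.shape[0]
    grad = s[1:, :] / proj.h  # rows: components of grad(Pi v)
    Kc = measure * (grad.T @ grad)
    S = (np.eye(n) - Pi).T @ (np.eye(n) - Pi)
    K = Kc + stab_K * S
    C = s.T @ H @ s
    M = C + measure * S
    return LocalMatrixSet(K=K, C=C, M=M)


def local_matrices_2d(element: PolygonElement) -> LocalMatrixSet:
    """Local K, C, M of a star-shaped polygon (stabilization factor 1)."""
    proj = pi_nabla(element)
    area, _, _ = polygon_measure(element)
    H = _gram_2d(element, element.vertices.mean(axis=0), element.diameter)
    return _matrices_from_projector(proj, H, area, stab_K=1.0)


def local_matrices_3d(element: PolyhedronElement) -> LocalMatrixSet:
    """Local K, C, M of a star-shaped polyhedron (stiffness stabilization h_E)."""
    proj = pi_nabla_3d(element)
    vol, _ = polyhedron_measure(element)
    H = _gram_3d(element, proj.center, proj.h)
    return _matrices_from_projector(proj, H, vol, stab_K=proj.h)


# reference matrices of the unit square, vertex ring (0,0),(0,1),(1,1),(1,0)
_SQ_K = np.array(
    [[3, -1, -1, -1], [-1, 3, -1, -1], [-1, -1, 3, -1], [-1, -1, -1, 3]], float
) / 4.0
_SQ_M = np.array(
    [[17, -9, 13, -9], [-9, 17, -9, 13], [13, -9, 17, -9], [-9, 13, -9, 17]], float
) / 48.0
_SQ_C = np.array(
    [[5, 3, 1, 3], [3, 5, 3, 1], [1, 3, 5, 3], [3, 1, 3, 5]], float
) / 48.0

# reference matrices of the unit cube, vertices in binary order
# (0,0,0),(0,0,1),(0,1,0),(0,1,1),(1,0,0),(1,0,1),(1,1,0),(1,1,1)
_CU_K_CONS = np.array(
    [
        [3, 1, 1, -1, 1, -1, -1, -3],
        [1, 3, -1, 1, -1, 1, -3, -1],
        [1, -1, 3, 1, -1, -3, 1, -1],
        [-1, 1, 1, 3, -3, -1, -1, 1],
        [1, -1, -1, -3, 3, 1, 1, -1],
        [-1, 1, -3, -1, 1, 3, -1, 1],
        [-1, -3, 1, -1, 1, -1, 3, 1],
        [-3, -1, -1, 1, -1, 1, 1, 3],
    ],
    float,
) / 16.0
_CU_K_STAB = np.array(
    [
        [2, -1, -1, 0, -1, 0, 0, 1],
        [-1, 2, 0, -1, 0, -1, 1, 0],
        [-1, 0, 2, -1, 0, 1, -1, 0],
        [0, -1, -1, 2, 1, 0, 0, -1],
        [-1, 0, 0, 1, 2, -1, -1, 0],
        [0, -1, 1, 0, -1, 2, 0, -1],
        [0, 1, -1, 0, -1, 0, 2, -1],
        [1, 0, 0, -1, 0, -1, -1, 2],
    ],
    float,
) / 4.0
_CU_C = np.array(
    [
        [3, 2, 2, 1, 2, 1, 1, 0],
        [2, 3, 1, 2, 1, 2, 0, 1],
        [2, 1, 3, 2, 1, 0, 2, 1],
        [1, 2, 2, 3, 0, 1, 1, 2],
        [2, 1, 1, 0, 3, 2, 2, 1],
        [1, 2, 0, 1, 2, 3, 1, 2],
        [1, 0, 2, 1, 2, 1, 3, 2],
        [0, 1, 1, 2, 1, 2, 2, 3],
    ],
    float,
) / 96.0
_CU_M = np.array(
    [
        [51, -22, -22, 1, -22, 1, 1, 24],
        [-22, 51, 1, -22, 1, -22, 24, 1],
        [-22, 1, 51, -22, 1, 24, -22, 1],
        [1, -22, -22, 51, 24, 1, 1, -22],
        [-22, 1, 1, 24, 51, -22, -22, 1],
        [1, -22, 24, 1, -22, 51, 1, -22],
        [1, 24, -22, 1, -22, 1, 51, -22],
        [24, 1, 1, -22, 1, -22, -22, 51],
    ],
    float,
) / 96.0


def closed_form_square(side: float = 1.0) -> LocalMatrixSet:
    """Closed-form k=1 matrices of a square of given side.

    Vertex ring order (0,0),(0,1),(1,1),(1,0) up to cyclic rotation /
    reversal (the reference matrices are circulant in the ring).  The
    stiffness is scale-invariant in 2D; mass and consistency scale with the
    area.
    """
    if side <= 0.0:
        raise ValueError("side must be positive")
    s2 = side * side
    return LocalMatrixSet(K=_SQ_K.copy(), C=s2 * _SQ_C, M=s2 * _SQ_M)


def closed_form_cube(side: float = 1.0) -> LocalMatrixSet:
    """Closed-form k=1 matrices of a cube of given side.

    Vertex order is the binary order (z fastest): (0,0,0),(0,0,1),(0,1,0),
    (0,1,1),(1,0,0),(1,0,1),(1,1,0),(1,1,1), scaled and translated.  The
    stiffness scales with the side (both the consistency part and the
    diameter-weighted stabilization), mass/consistency with the volume.
    """
    if side <= 0.0:
        raise ValueError("side must be positive")
    K = side * (_CU_K_CONS + np.sqrt(3.0) * _CU_K_STAB)
    s3 = side ** 3
    return LocalMatrixSet(K=K, C=s3 * _CU_C, M=s3 * _CU_M)


# --------------------------------------------------------------------------- #
# surface (curve / triangulated surface) P1 operators
# --------------------------------------------------------------------------- #

def local_surface_segment(p: np.ndarray, q: np.ndarray):
    """P1 stiffness and mass of a curve segment (the 1D surface element)."""
    ell = float(np.linalg.norm(np.asarray(q, float) - np.asarray(p, float)))
    if ell == 0.0:
        raise DegenerateGeometryError("zero-length surface segment")
    KS = np.array([[1.0, -1.0], [-1.0, 1.0]]) / ell
    MS = ell / 6.0 * np.array([[2.0, 1.0], [1.0, 2.0]])
    return KS, MS


def local_surface_triangle(p1, p2, p3):
    """P1 surface-gradient stiffness, mass and consistency of a flat triangle.

    For the lowest order on flat triangles the projector is the identity, so
    the consistency matrix equals the mass matrix; it is still returned
    separately to keep the 3D surface interface uniform.
    """
    p1, p2, p3 = (np.asarray(p, float) for p in (p1, p2, p3))
    e1 = p3 - p2
    e2 = p1 - p3
    e3 = p2 - p1
    nrm = np.cross(e3, -e2)
    area2 = np.linalg.norm(nrm)
    if area2 == 0.0:
        raise DegenerateGeometryError("zero-area surface triangle")
    area = area2 / 2.0
    E = [e1, e2, e3]
    KS = np.empty((3, 3))
    for i in range(3):
        for j in range(3):
            KS[i, j] = (E[i] @ E[j]) / (4.0 * area)
    MS = area / 12.0 * (np.ones((3, 3)) + np.eye(3))
    return KS, MS, MS.copy()
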