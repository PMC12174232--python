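"""Global sparse operators: scatter of local matrices and the reduction map.

Bulk stiffness/consistency/mass (K, C, M) are assembled element-wise; square
and cube elements take the closed-form shortcut.  Surface operators (KS, MS
and, in 3D, CS) are P1 finite element matrices on the boundary segments /
triangles, indexed in the order of the sorted surface node list.  The
reduction matrix R is the 0/1 inclusion of surface nodes into bulk nodes, so
``R.T @ u`` is the trace of bulk nodal data on the surface mesh.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.sparse as sp

from .meshgen import BulkSurfaceMesh
from .vem_local import (
    closed_form_cube,
    closed_form_square,
    local_matrices_2d,
    local_matrices_3d,
    local_surface_segment,
    local_surface_triangle,
)

__all__ = ["GlobalMatrices", "assembly_2d", "assembly_3d", "dirichlet_restriction"]


@dataclass
class GlobalMatrices:
    """Assembled sparse operators of a bulk-surface mesh.

    K, C, M are N x N (bulk); KS, MS, CS are NGamma x NGamma (surface, CS
    equals MS in 2D and on flat-triangle surfaces); R is the N x NGamma
    reduction matrix; ``surf_nodes`` lists the bulk indices of the surface
    nodes in ascending order (the surface matrices follow this ordering).
    """

    K: sp.spmatrix
    C: sp.spmatrix
    M: sp.spmatrix
    KS: Optional[sp.spmatrix]
    MS: Optional[sp.spmatrix]
    CS: Optional[sp.spmatrix]
    R: Optional[sp.spmatrix]
    surf_nodes: np.ndarray
    P: np.ndarray

    @property
    def num_nodes(self) -> int:
        return self.K.shape[0]

    @property
    def num_surf_nodes(self) -> int:
        return 0 if self.R is None else self.R.shape[1]

    def surface_points(self) -> np.ndarray:
        return self.P[self.surf_nodes]


class _Scatter:
    def __init__(self):
        self.rows, self.cols, self.vals = [], [], []

    def add(self, idx: np.ndarray, A: np.ndarray):
        n = len(idx)
        self.rows.append(np.repeat(idx, n))
        self.cols.append(np.tile(idx, n))
        self.vals.append(A.ravel())

    def build(self, n: int) -> sp.csr_matrix:
        if not self.rows:
            return sp.csr_matrix((n, n))
        return sp.csr_matrix(
            (np.concatenate(self.vals),
             (np.concatenate(self.rows), np.concatenate(self.cols))),
            shape=(n, n),
        )


def _element_side(el) -> float:
    return float(np.ptp(el.vertices[:, 0]))


def _check_pind(mesh: BulkSurfaceMesh, el, i: int) -> np.ndarray:
    if el.Pind is None:
        raise ValueError(f"bulk element {i} has no global index list Pind")
    idx = np.asarray(el.Pind)
    if not np.allclose(mesh.P[idx], el.vertices, atol=1e-12):
        raise ValueError(f"bulk element {i}: Pind is inconsistent with the node table")
    return idx


def _surface_matrices(mesh: BulkSurfaceMesh):
    surf_nodes = mesh.surface_node_indices()
    if len(surf_nodes) == 0:
        return None, None, None, None, surf_nodes
    glob2loc = {int(g): j for j, g in enumerate(surf_nodes)}
    ks, ms, cs = _Scatter(), _Scatter(), _Scatter()
    for facet in mesh.surf_elements:
        loc = np.array([glob2loc[int(g)] for g in facet], dtype=np.int64)
        pts = mesh.P[facet]
        if len(facet) == 2:
            KSl, MSl = local_surface_segment(pts[0], pts[1])
            CSl = MSl
        else:
            KSl, MSl, CSl = local_surface_triangle(*pts)
        ks.add(loc, KSl)
        ms.add(loc, MSl)
        cs.add(loc, CSl)
    ng = len(surf_nodes)
    KS, MS, CS = ks.build(ng), ms.build(ng), cs.build(ng)
    R = sp.csr_matrix(
        (np.ones(ng), (surf_nodes, np.arange(ng))),
        shape=(mesh.num_nodes, ng),
    )
    return KS, MS, CS, R, surf_nodes


def assembly_2d(mesh: BulkSurfaceMesh) -> GlobalMatrices:
    """Assemble the global operators of a 2D bulk-surface mesh."""
    if mesh.dim != 2:
        raise ValueError("assembly_2d needs a 2D mesh")
    N = mesh.num_nodes
    k, c, m = _Scatter(), _Scatter(), _Scatter()
    for i, el in enumerate(mesh.bulk_elements):
        idx = _check_pind(mesh, el, i)
        if el.is_square:
            loc = closed_form_square(_element_side(el))
        else:
            loc = local_matrices_2d(el)
        k.add(idx, loc.K)
        c.add(idx, loc.C)
        m.add(idx, loc.M)
    KS, MS, CS, R, surf_nodes = _surface_matrices(mesh)
    return GlobalMatrices(K=k.build(N), C=c.build(N), M=m.build(N),
                          KS=KS, MS=MS, CS=CS, R=R,
                          surf_nodes=surf_nodes, P=mesh.P)


def assembly_3d(mesh: BulkSurfaceMesh) -> GlobalMatrices:
    """Assemble the global operators of a 3D bulk-surface mesh.

    For a surface-only mesh (no bulk elements) the bulk blocks are empty and
    only KS, MS, CS are meaningful; R is then the identity on surface nodes.
    """
    if mesh.dim != 3:
        raise ValueError("assembly_3d needs a 3D mesh")
    N = mesh.num_nodes
    k, c, m = _Scatter(), _Scatter(), _Scatter()
    for i, el in enumerate(mesh.bulk_elements):
        idx = _check_pind(mesh, el, i)
        if el.is_cube:
            loc = closed_form_cube(_element_side(el))
        else:
            loc = local_matrices_3d(el)
        k.add(idx, loc.K)
        c.add(idx, loc.C)
        m.add(idx, loc.M)
    KS, MS, CS, R, surf_nodes = _surface_matrices(mesh)
    return GlobalMatrices(K=k.build(N), C=c.build(N), M=m.build(N),
                          KS=KS, MS=MS, CS=CS, R=R,
                          surf_nodes=surf_nodes, P=mesh.P)


def dirichlet_restriction(mats: GlobalMatrices):
    """Interior node set for homogeneous Dirichlet conditions.

    Boundary (surface) rows/columns are eliminated; solutions on the
    restricted system are re-expanded with zeros on the boundary.
    """
    if mats.num_surf_nodes == 0:
        raise ValueError("mesh has no surface: nothing to constrain")
    interior = np.setdiff1d(np.arange(mats.num_nodes), mats.surf_nodes)
    if len(interior) == 0:
        raise ValueError("no interior nodes: the Dirichlet problem is empty")
    return interior


def expand_with_zeros(values: np.ndarray, interior: np.ndarray, n: int) -> np.ndarray:
    """Scatter interior values into a length-n vector with zero boundary data."""
    out = np.zeros((n,) + values.shape[1:])
    out[interior] = values
    return out
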