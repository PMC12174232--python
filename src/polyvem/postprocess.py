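"""Relative L2 error evaluation and solution export.

Virtual basis functions are not known in closed form, so errors are measured
on the piecewise polynomial projection of the numerical solution: the bulk
consistency matrix C is exactly the Gram matrix of the projected basis, so
``e^T C e`` is the squared L2 norm of the projected error.  On the surface
the P1 mass matrix MS plays the same role.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assembly import GlobalMatrices
from . import vtkio

__all__ = ["ErrorReport", "compute_error", "export_solution"]


@dataclass
class ErrorReport:
    relative_error: float
    norm_kind: str


def _quad(Q, e):
    return float(np.asarray(e) @ (Q @ np.asarray(e)))


def compute_error(
    mats: GlobalMatrices,
    u=None,
    u_exact=None,
    v=None,
    v_exact=None,
) -> ErrorReport:
    """Relative L2 error of nodal solutions.

    Pass ``u``/``u_exact`` for a bulk problem, ``v``/``v_exact`` for a
    surface problem, or all four for a coupled problem; the norms are
    ``sqrt(e' C e)`` in the bulk and ``sqrt(e' MS e)`` on the surface, and
    the coupled error combines the two under a single square root.
    """
    num = 0.0
    den = 0.0
    kinds = []
    if u is not None:
        u = np.asarray(u, dtype=float).ravel()
        u_exact = np.asarray(u_exact, dtype=float).ravel()
        if u.shape != u_exact.shape or len(u) != mats.num_nodes:
            raise ValueError("u and u_exact must both have one value per bulk node")
        num += _quad(mats.C, u - u_exact)
        den += _quad(mats.C, u_exact)
        kinds.append("L2_bulk")
    if v is not None:
        v = np.asarray(v, dtype=float).ravel()
        v_exact = np.asarray(v_exact, dtype=float).ravel()
        if v.shape != v_exact.shape or len(v) != mats.num_surf_nodes:
            raise ValueError("v and v_exact must both have one value per surface node")
        num += _quad(mats.MS, v - v_exact)
        den += _quad(mats.MS, v_exact)
        kinds.append("L2_surface")
    if not kinds:
        raise ValueError("nothing to compare: pass u and/or v")
    if den <= 0.0:
        raise ZeroDivisionError("exact solution has zero norm")
    kind = "L2_bulk_x_surface" if len(kinds) == 2 else kinds[0]
    return ErrorReport(relative_error=float(np.sqrt(max(num, 0.0) / den)),
                       norm_kind=kind)


def export_solution(mesh, path, point_data: dict, which: str = "bulk") -> str:
    """Write mesh + nodal fields to a legacy-VTK unstructured grid file.

    ``which`` selects 'bulk' (polygon/polyhedron cells), 'surface'
    (lines/triangles on the full node table) or 'plot' (the cut-plane
    boundary faces of a 3D mesh).  Returns the path written.
    """
    return vtkio.write_mesh_vtk(mesh, path, point_data=point_data, which=which)
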