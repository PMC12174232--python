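"""Black-box solvers for elliptic and semilinear parabolic PDE problems.

Six problem classes are covered, on the bulk, on the surface, and coupled:

* elliptic bulk            ``-d_O Lap u + alpha u = f``  (Dirichlet/Neumann)
* parabolic bulk systems   ``du_i/dt - d_i Lap u_i = f_i(u, x, t)``
* elliptic surface         ``-d_G LapBel v + beta v = g``
* parabolic surface        ``dv_j/dt - d_j LapBel v_j = g_j(v, x, t)``
* elliptic bulk-surface    coupled through the flux  ``du/dn = gamma u + delta v``
* parabolic bulk-surface   coupled through fluxes ``d_i du_i/dn = h_i(u, v, x, t)``

Time stepping is IMEX Euler: diffusion implicit, kinetics explicit with
nodal evaluation weighted by the mass matrix.  Each implicit step matrix is
factorized once (sparse LU) and reused over all time steps.  Parabolic
solvers report two indicators of the first component, the L2 norm of the
discrete time derivative and the spatial average, commonly used to detect
when a reaction-diffusion simulation has reached a (Turing) steady state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .assembly import GlobalMatrices, dirichlet_restriction, expand_with_zeros

__all__ = [
    "EllipticBulkProblem",
    "ParabolicBulkProblem",
    "EllipticSurfaceProblem",
    "ParabolicSurfaceProblem",
    "EllipticBulkSurfaceProblem",
    "ParabolicBulkSurfaceProblem",
    "SolverResult",
    "solve_elliptic_bulk",
    "solve_parabolic_bulk",
    "solve_elliptic_surface",
    "solve_parabolic_surface",
    "solve_elliptic_bulk_surface",
    "solve_parabolic_bulk_surface",
]


def _check_bcond(bcond: str) -> str:
    if bcond not in ("dir", "neu"):
        raise ValueError("bcond must be 'dir' or 'neu'")
    return bcond


def _check_tau(T: float, tau: float) -> int:
    if tau <= 0.0:
        raise ValueError("timestep tau must be positive")
    if T < tau:
        raise ValueError("final time T must be at least one timestep")
    return int(np.ceil(T / tau))


# --------------------------------------------------------------------------- #
# problem definitions
# --------------------------------------------------------------------------- #

@dataclass
class EllipticBulkProblem:
    """``-d_omega Lap u + alpha u = f(x)`` with homogeneous 'dir'/'neu' data."""

    d_omega: float
    alpha: float
    f: Callable[[np.ndarray], np.ndarray]
    bcond: str = "neu"

    def __post_init__(self):
        if self.d_omega <= 0.0:
            raise ValueError("diffusion coefficient must be positive")
        if self.alpha < 0.0:
            raise ValueError("alpha must be nonnegative")
        _check_bcond(self.bcond)
        if self.alpha == 0.0 and self.bcond == "neu":
            raise ValueError("alpha = 0 with Neumann data gives a singular problem")


@dataclass
class ParabolicBulkProblem:
    """Semilinear system ``du_i/dt - d_i Lap u_i = f_i(u_1..u_n, x, t)``.

    ``kinetics[i]`` maps ``(u, P, t)`` with u of shape (N, n) to N values.
    """

    diffusion: Sequence[float]
    kinetics: Sequence[Callable]
    T: float
    tau: float
    u0: np.ndarray
    bcond: str = "neu"

    def __post_init__(self):
        self.diffusion = np.atleast_1d(np.asarray(self.diffusion, dtype=float))
        if np.any(self.diffusion <= 0.0):
            raise ValueError("diffusion coefficients must be positive")
        _check_bcond(self.bcond)
        _check_tau(self.T, self.tau)
        self.u0 = np.atleast_2d(np.asarray(self.u0, dtype=float).T).T
        if self.u0.shape[1] != len(self.diffusion) or \
                len(self.kinetics) != len(self.diffusion):
            raise ValueError("diffusion, kinetics and u0 must agree on the "
                             "number of components")


@dataclass
class EllipticSurfaceProblem:
    """``-d_gamma LapBel v + beta v = g(x)`` on a closed surface."""

    d_gamma: float
    beta: float
    g: Callable[[np.ndarray], np.ndarray]

    def __post_init__(self):
        if self.d_gamma <= 0.0 or self.beta <= 0.0:
            raise ValueError("d_gamma and beta must be positive")


@dataclass
class ParabolicSurfaceProblem:
    """Semilinear surface system ``dv_j/dt - d_j LapBel v_j = g_j(v, x, t)``."""

    diffusion: Sequence[float]
    kinetics: Sequence[Callable]
    T: float
    tau: float
    v0: np.ndarray

    def __post_init__(self):
        self.diffusion = np.atleast_1d(np.asarray(self.diffusion, dtype=float))
        if np.any(self.diffusion <= 0.0):
            raise ValueError("diffusion coefficients must be positive")
        _check_tau(self.T, self.tau)
        self.v0 = np.atleast_2d(np.asarray(self.v0, dtype=float).T).T
        if self.v0.shape[1] != len(self.diffusion):
            raise ValueError("diffusion and v0 must agree on the number of components")


@dataclass
class EllipticBulkSurfaceProblem:
    """Coupled elliptic system with flux condition ``du/dn = gamma u + delta v``.

    The coupling coefficients may take either sign.
    """

    d_omega: float
    d_gamma: float
    alpha: float
    beta: float
    gamma: float
    delta: float
    f: Callable[[np.ndarray], np.ndarray]
    g: Callable[[np.ndarray], np.ndarray]

    def __post_init__(self):
        if self.d_omega <= 0.0 or self.d_gamma <= 0.0:
            raise ValueError("diffusion coefficients must be positive")


@dataclass
class ParabolicBulkSurfaceProblem:
    """Coupled semilinear bulk-surface system.

    ``bulk_kinetics[i]`` maps (u, P, t) -> N values; ``surf_kinetics[j]``
    maps (v, u_trace, P_surf, t) -> NGamma values; ``fluxes[i]`` maps
    (u_trace, v, P_surf, t) -> NGamma values and supplies
    ``d_i * du_i/dn`` on the surface.
    """

    bulk_diffusion: Sequence[float]
    surf_diffusion: Sequence[float]
    bulk_kinetics: Sequence[Callable]
    surf_kinetics: Sequence[Callable]
    fluxes: Sequence[Callable]
    T: float
    tau: float
    u0: np.ndarray
    v0: np.ndarray

    def __post_init__(self):
        self.bulk_diffusion = np.atleast_1d(np.asarray(self.bulk_diffusion, float))
        self.surf_diffusion = np.atleast_1d(np.asarray(self.surf_diffusion, float))
        if np.any(self.bulk_diffusion <= 0) or np.any(self.surf_diffusion <= 0):
            raise ValueError("diffusion coefficients must be positive")
        _check_tau(self.T, self.tau)
        self.u0 = np.atleast_2d(np.asarray(self.u0, dtype=float).T).T
        self.v0 = np.atleast_2d(np.asarray(self.v0, dtype=float).T).T
        if self.u0.shape[1] != len(self.bulk_diffusion):
            raise ValueError("u0 and bulk_diffusion disagree on components")
        if self.v0.shape[1] != len(self.surf_diffusion):
            raise ValueError("v0 and surf_diffusion disagree on components")


@dataclass
class SolverResult:
    """Final-time nodal solution plus time-series indicators.

    ``t[k] = (k+1) tau``; ``uprime_norm[k]`` is the L2 norm of the discrete
    time derivative of the first component at step k+1 and ``u_average[k]``
    its spatial average, both computed with the relevant mass matrix.
    """

    u: Optional[np.ndarray]
    v: Optional[np.ndarray] = None
    t: Optional[np.ndarray] = None
    uprime_norm: Optional[np.ndarray] = None
    u_average: Optional[np.ndarray] = None

    def indicators_to_csv(self, path) -> str:
        """Write the time series (t, uprime_norm, u_average) as CSV."""
        if self.t is None:
            raise ValueError("no time series recorded")
        data = np.column_stack([self.t, self.uprime_norm, self.u_average])
        np.savetxt(path, data, delimiter=",",
                   header="t,uprime_norm,u_average", comments="")
        return str(path)


# --------------------------------------------------------------------------- #
# elliptic solvers
# --------------------------------------------------------------------------- #

def _spsolve(A: sp.spmatrix, b: np.ndarray) -> np.ndarray:
    return spla.spsolve(A.tocsc(), b)


def solve_elliptic_bulk(problem: EllipticBulkProblem, mats: GlobalMatrices
                        ) -> np.ndarray:
    """Sparse direct solve of ``(d_omega K + alpha M) u = M f(P)``."""
    A = (problem.d_omega * mats.K + problem.alpha * mats.M).tocsc()
    b = mats.M @ np.asarray(problem.f(mats.P), dtype=float)
    if problem.bcond == "neu":
        return _spsolve(A, b)
    interior = dirichlet_restriction(mats)
    ui = _spsolve(A[interior][:, interior], b[interior])
    return expand_with_zeros(ui, interior, mats.num_nodes)


def solve_elliptic_surface(problem: EllipticSurfaceProblem, mats: GlobalMatrices
                           ) -> np.ndarray:
    """Solve ``(d_gamma KS + beta MS) v = MS g`` (no boundary conditions)."""
    if mats.KS is None:
        raise ValueError("mesh has no surface elements")
    A = problem.d_gamma * mats.KS + problem.beta * mats.MS
    b = mats.MS @ np.asarray(problem.g(mats.surface_points()), dtype=float)
    return _spsolve(A, b)


def solve_elliptic_bulk_surface(problem: EllipticBulkSurfaceProblem,
                                mats: GlobalMatrices):
    """Monolithic solve of the coupled elliptic bulk-surface system.

    The flux ``du/dn = gamma u + delta v`` is substituted both in the bulk
    boundary term and in the conormal term of the surface equation, giving
    the (structurally unsymmetric) block system

        [ dO K + a M - g dO R MS R^T ,  -d dO R MS        ] [u]   [M f ]
        [ g dO MS R^T                ,  dG KS + b MS + d dO MS ] [v] = [MS g]
    """
    if mats.KS is None:
        raise ValueError("mesh has no surface elements")
    dO, dG = problem.d_omega, problem.d_gamma
    ga, de = problem.gamma, problem.delta
    R, MS = mats.R, mats.MS
    A11 = dO * mats.K + problem.alpha * mats.M - ga * dO * (R @ MS @ R.T)
    A12 = -de * dO * (R @ MS)
    A21 = ga * dO * (MS @ R.T)
    A22 = dG * mats.KS + problem.beta * MS + de * dO * MS
    A = sp.bmat([[A11, A12], [A21, A22]], format="csc")
    b = np.concatenate([
        mats.M @ np.asarray(problem.f(mats.P), dtype=float),
        MS @ np.asarray(problem.g(mats.surface_points()), dtype=float),
    ])
    try:
        x = spla.spsolve(A, b)
    except RuntimeError as exc:  # pragma: no cover - singular systems
        raise RuntimeError(
            "coupled elliptic system is singular; check alpha, beta, gamma, delta"
        ) from exc
    n = mats.num_nodes
    return x[:n], x[n:]


# --------------------------------------------------------------------------- #
# parabolic solvers (IMEX Euler)
# --------------------------------------------------------------------------- #

def _indicator_ops(Mmat: sp.spmatrix):
    one = np.ones(Mmat.shape[0])
    total = float(one @ (Mmat @ one))
    return total


def solve_parabolic_bulk(problem: ParabolicBulkProblem, mats: GlobalMatrices
                         ) -> SolverResult:
    """IMEX Euler for semilinear parabolic bulk systems.

    Step: ``(M + tau d_i K) u_i^k = M (u_i^{k-1} + tau f_i(u^{k-1}, P, t_{k-1}))``;
    the implicit matrix of every component is factorized once.
    """
    nT = _check_tau(problem.T, problem.tau)
    tau = problem.tau
    ncomp = len(problem.diffusion)
    u = np.array(problem.u0, dtype=float)
    if u.shape[0] != mats.num_nodes:
        raise ValueError("u0 has the wrong number of rows")
    P, M, K = mats.P, mats.M.tocsc(), mats.K.tocsc()
    if problem.bcond == "dir":
        interior = dirichlet_restriction(mats)
        Mi = M[interior][:, interior]
        solvers = [spla.factorized((Mi + tau * d * K[interior][:, interior]).tocsc())
                   for d in problem.diffusion]
    else:
        interior = None
        solvers = [spla.factorized((M + tau * d * K).tocsc())
                   for d in problem.diffusion]
    total = _indicator_ops(M)
    t_nodes = tau * np.arange(1, nT + 1)
    upn = np.empty(nT)
    uav = np.empty(nT)
    for k in range(nT):
        t_prev = k * tau
        rhs = u + tau * np.column_stack(
            [problem.kinetics[i](u, P, t_prev) for i in range(ncomp)])
        unew = np.empty_like(u)
        for i in range(ncomp):
            b = M @ rhs[:, i]
            if interior is None:
                unew[:, i] = solvers[i](b)
            else:
                unew[:, i] = expand_with_zeros(
                    solvers[i](b[interior]), interior, mats.num_nodes)
        du = unew[:, 0] - u[:, 0]
        upn[k] = np.sqrt(max(du @ (M @ du), 0.0)) / tau
        uav[k] = (M @ unew[:, 0]).sum() / total
        u = unew
    return SolverResult(u=u, t=t_nodes, uprime_norm=upn, u_average=uav)


def solve_parabolic_surface(problem: ParabolicSurfaceProblem, mats: GlobalMatrices
                            ) -> SolverResult:
    """IMEX Euler on a closed surface; indicators use the surface mass MS."""
    if mats.KS is None:
        raise ValueError("mesh has no surface elements")
    nT = _check_tau(problem.T, problem.tau)
    tau = problem.tau
    ncomp = len(problem.diffusion)
    v = np.array(problem.v0, dtype=float)
    if v.shape[0] != mats.KS.shape[0]:
        raise ValueError("v0 has the wrong number of rows")
    PG = mats.surface_points()
    MS, KS = mats.MS.tocsc(), mats.KS.tocsc()
    solvers = [spla.factorized((MS + tau * d * KS).tocsc())
               for d in problem.diffusion]
    total = _indicator_ops(MS)
    t_nodes = tau * np.arange(1, nT + 1)
    upn = np.empty(nT)
    uav = np.empty(nT)
    for k in range(nT):
        t_prev = k * tau
        rhs = v + tau * np.column_stack(
            [problem.kinetics[j](v, PG, t_prev) for j in range(ncomp)])
        vnew = np.column_stack([solvers[j](MS @ rhs[:, j]) for j in range(ncomp)])
        dv = vnew[:, 0] - v[:, 0]
        upn[k] = np.sqrt(max(dv @ (MS @ dv), 0.0)) / tau
        uav[k] = (MS @ vnew[:, 0]).sum() / total
        v = vnew
    return SolverResult(u=None, v=v, t=t_nodes, uprime_norm=upn, u_average=uav)


def solve_parabolic_bulk_surface(problem: ParabolicBulkSurfaceProblem,
                                 mats: GlobalMatrices) -> SolverResult:
    """IMEX Euler for coupled bulk-surface reaction-diffusion systems.

    Bulk step adds the boundary-flux load ``R MS h_i`` to the explicit
    kinetics; surface kinetics may read the bulk trace ``R^T u``.
    Indicators follow the first bulk component with the bulk mass matrix.
    """
    if mats.KS is None:
        raise ValueError("mesh has no surface elements")
    nT = _check_tau(problem.T, problem.tau)
    tau = problem.tau
    nb, ns = len(problem.bulk_diffusion), len(problem.surf_diffusion)
    u = np.array(problem.u0, dtype=float)
    v = np.array(problem.v0, dtype=float)
    if u.shape[0] != mats.num_nodes or v.shape[0] != mats.num_surf_nodes:
        raise ValueError("u0 / v0 shapes do not match the mesh "
                         f"({u.shape} vs N={mats.num_nodes}, "
                         f"{v.shape} vs NGamma={mats.num_surf_nodes})")
    P, PG = mats.P, mats.surface_points()
    M, K = mats.M.tocsc(), mats.K.tocsc()
    MS, KS = mats.MS.tocsc(), mats.KS.tocsc()
    R = mats.R.tocsr()
    bulk_solvers = [spla.factorized((M + tau * d * K).tocsc())
                    for d in problem.bulk_diffusion]
    surf_solvers = [spla.factorized((MS + tau * d * KS).tocsc())
                    for d in problem.surf_diffusion]
    total = _indicator_ops(M)
    t_nodes = tau * np.arange(1, nT + 1)
    upn = np.empty(nT)
    uav = np.empty(nT)
    for k in range(nT):
        t_prev = k * tau
        utr = u[mats.surf_nodes]
        unew = np.empty_like(u)
        for i in range(nb):
            load = M @ (u[:, i] + tau * np.asarray(
                problem.bulk_kinetics[i](u, P, t_prev), dtype=float))
            hload = MS @ np.asarray(
                problem.fluxes[i](utr, v, PG, t_prev), dtype=float)
            unew[:, i] = bulk_solvers[i](load + tau * (R @ hload))
        vnew = np.empty_like(v)
        for j in range(ns):
            rhs = v[:, j] + tau * np.asarray(
                problem.surf_kinetics[j](v, utr, PG, t_prev), dtype=float)
            vnew[:, j] = surf_solvers[j](MS @ rhs)
        du = unew[:, 0] - u[:, 0]
        upn[k] = np.sqrt(max(du @ (M @ du), 0.0)) / tau
        uav[k] = (M @ unew[:, 0]).sum() / total
        u, v = unew, vnew
    return SolverResult(u=u, v=v, t=t_nodes, uprime_norm=upn, u_average=uav)
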