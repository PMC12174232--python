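"""Built-in level sets, reaction-kinetics presets and initial data.

Everything the worked experiments need is generated here, self-contained:

* a small library of level-set domains (disc, sphere, torus, box, ellipsoid)
  with the bounding boxes used in the experiments;
* the activator-depleted (Schnakenberg) kinetics and the coupled
  bulk-surface reaction-diffusion preset, with their spatially uniform
  steady states;
* seeded random perturbations of a uniform steady state, used as initial
  data for Turing-pattern simulations;
* a synthetic coarse ellipsoid triangulation (subdivided icosahedron mapped
  onto the ellipsoid) standing in for a third-party surface mesh generator,
  to exercise the surface-import path offline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .meshgen import LevelSetDomain

__all__ = [
    "level_set",
    "schnakenberg_steady_state",
    "schnakenberg_kinetics",
    "bulk_surface_rds_preset",
    "perturbed_ic",
    "ellipsoid_surface_mesh",
]


def level_set(name: str, Nx: int = 30, tol: float | None = None) -> LevelSetDomain:
    """Named level-set domains with their experiment bounding boxes.

    'disc' and 'sphere' are the unit ball in 2D/3D on [-1,1]^d; 'torus' has
    major radius 0.7 and minor radius 0.3 in the tight box
    [-1,1] x [-1,1] x [-0.31,0.31]; 'box' is the whole bounding box (f = -1);
    'ellipsoid' has semi-axes (2, 1, 1.5).
    """
    if name == "disc":
        return LevelSetDomain(lambda P: P[:, 0] ** 2 + P[:, 1] ** 2 - 1.0,
                              [[-1, 1], [-1, 1]], Nx, tol)
    if name == "sphere":
        return LevelSetDomain(lambda P: (P ** 2).sum(axis=1) - 1.0,
                              [[-1, 1], [-1, 1], [-1, 1]], Nx, tol)
    if name == "torus":
        def torus(P):
            return (np.sqrt(P[:, 0] ** 2 + P[:, 1] ** 2) - 0.7) ** 2 \
                + P[:, 2] ** 2 - 0.09
        return LevelSetDomain(torus, [[-1, 1], [-1, 1], [-0.31, 0.31]], Nx, tol)
    if name == "box":
        return LevelSetDomain(lambda P: -np.ones(len(P)),
                              [[-1, 1], [-1, 1], [-1, 1]], Nx, tol)
    if name == "ellipsoid":
        def ell(P):
            return P[:, 0] ** 2 / 4.0 + P[:, 1] ** 2 + P[:, 2] ** 2 / 2.25 - 1.0
        return LevelSetDomain(ell, [[-2, 2], [-1, 1], [-1.5, 1.5]], Nx, tol)
    raise KeyError(f"unknown level set '{name}'")


# --------------------------------------------------------------------------- #
# kinetics presets
# --------------------------------------------------------------------------- #

def schnakenberg_steady_state(a: float, b: float):
    """Spatially uniform steady state (a+b, b/(a+b)^2) of the
    activator-depleted kinetics."""
    if a + b == 0:
        raise ValueError("a + b must be nonzero")
    return (a + b, b / (a + b) ** 2)


def schnakenberg_kinetics(a: float = 0.1, b: float = 0.9, gamma: float = 300.0):
    """Activator-depleted kinetics g1 = gamma(a - v1 + v1^2 v2),
    g2 = gamma(b - v1^2 v2), as (v, P, t) callables for the surface solver."""

    def g1(v, P, t):
        return gamma * (a - v[:, 0] + v[:, 0] ** 2 * v[:, 1])

    def g2(v, P, t):
        return gamma * (b - v[:, 0] ** 2 * v[:, 1])

    return [g1, g2]


@dataclass
class BulkSurfaceRDSPreset:
    """Coupled bulk-surface activator-depleted system.

    Bulk pair (u1, u2) and surface pair (v1, v2) share the Schnakenberg
    kinetics; the membrane exchange laws are ``h1 = a1 v1 - b1 u1 - k1 u1``
    and ``h2 = a2 v2 - b2 u1 - k2 u2`` (the supplied fluxes equal
    ``d_i du_i/dn``), and the surface kinetics subtract the exchange again.
    The uniform state (a+b, b/(a+b)^2, a+b, b/(a+b)^2) zeroes every reaction
    and flux term.
    """

    a: float = 0.1
    b: float = 0.9
    alpha1: float = 5.0 / 12.0
    alpha2: float = 5.0
    beta1: float = 5.0 / 12.0
    beta2: float = 0.0
    kappa1: float = 0.0
    kappa2: float = 5.0
    d2_omega: float = 10.0
    d2_gamma: float = 10.0
    gamma_omega: float = 300.0
    gamma_gamma: float = 300.0

    def steady_state(self):
        s = schnakenberg_steady_state(self.a, self.b)
        return np.array([s[0], s[1]]), np.array([s[0], s[1]])

    def _f(self, w1, w2):
        return (self.a - w1 + w1 ** 2 * w2, self.b - w1 ** 2 * w2)

    def _h(self, u1, u2, v1, v2):
        h1 = self.alpha1 * v1 - self.beta1 * u1 - self.kappa1 * u1
        h2 = self.alpha2 * v2 - self.beta2 * u1 - self.kappa2 * u2
        return h1, h2

    def problem_pieces(self):
        """Diffusion vectors plus kinetics/flux callables for the coupled
        parabolic solver."""
        gO, gG = self.gamma_omega, self.gamma_gamma

        def f1(u, P, t):
            return gO * self._f(u[:, 0], u[:, 1])[0]

        def f2(u, P, t):
            return gO * self._f(u[:, 0], u[:, 1])[1]

        def g1(v, utr, P, t):
            f = self._f(v[:, 0], v[:, 1])[0]
            h = self._h(utr[:, 0], utr[:, 1], v[:, 0], v[:, 1])[0]
            return gG * (f - h)

        def g2(v, utr, P, t):
            f = self._f(v[:, 0], v[:, 1])[1]
            h = self._h(utr[:, 0], utr[:, 1], v[:, 0], v[:, 1])[1]
            return gG * (f - h)

        def h1(utr, v, P, t):
            return gG * self._h(utr[:, 0], utr[:, 1], v[:, 0], v[:, 1])[0]

        def h2(utr, v, P, t):
            return gG * self._h(utr[:, 0], utr[:, 1], v[:, 0], v[:, 1])[1]

        return dict(
            bulk_diffusion=[1.0, self.d2_omega],
            surf_diffusion=[1.0, self.d2_gamma],
            bulk_kinetics=[f1, f2],
            surf_kinetics=[g1, g2],
            fluxes=[h1, h2],
        )


def bulk_surface_rds_preset(**kwargs) -> BulkSurfaceRDSPreset:
    return BulkSurfaceRDSPreset(**kwargs)


def perturbed_ic(base, amplitude: float, seed: int, n_nodes: int) -> np.ndarray:
    """Uniform steady state plus seeded uniform noise in [-amplitude, amplitude].

    Returns an (n_nodes, len(base)) array; reproducible for a fixed seed.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be nonnegative")
    base = np.atleast_1d(np.asarray(base, dtype=float))
    rng = np.random.default_rng(seed)
    noise = rng.uniform(-1.0, 1.0, size=(n_nodes, len(base)))
    return base[None, :] + amplitude * noise


# --------------------------------------------------------------------------- #
# synthetic ellipsoid triangulation
# --------------------------------------------------------------------------- #

def _icosahedron():
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    V = np.array([
        [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
        [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
        [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
    ], dtype=float)
    V /= np.linalg.norm(V, axis=1, keepdims=True)
    T = np.array([
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ], dtype=np.int64)
    return V, T


def ellipsoid_surface_mesh(refine: int = 3, semi_axes=(2.0, 1.0, 1.5)):
    """Synthetic triangulated ellipsoid surface (subdivided icosahedron).

    A stand-in for an externally generated surface mesh: returns the node
    table (N, 3) and triangle table (M, 3) in the common two-table format.
    ``refine`` loop-subdivides each triangle 4-fold per level.
    """
    V, T = _icosahedron()
    for _ in range(refine):
        edge_mid: dict[tuple[int, int], int] = {}
        verts = list(V)

        def midpoint(i, j):
            key = (min(i, j), max(i, j))
            if key not in edge_mid:
                p = verts[i] + verts[j]
                p = p / np.linalg.norm(p)
                edge_mid[key] = len(verts)
                verts.append(p)
            return edge_mid[key]

        newT = []
        for a, b, c in T:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            newT += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        V = np.asarray(verts)
        T = np.asarray(newT, dtype=np.int64)
    return V * np.asarray(semi_axes, dtype=float)[None, :], T
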