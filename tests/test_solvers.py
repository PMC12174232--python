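import numpy as np
import pytest

from polyvem.assembly import assembly_2d, assembly_3d
from polyvem.fixtures import (
    bulk_surface_rds_preset,
    ellipsoid_surface_mesh,
    level_set,
    perturbed_ic,
    schnakenberg_kinetics,
    schnakenberg_steady_state,
)
from polyvem.meshgen import generate_mesh_2d, generate_mesh_3d, import_surface
from polyvem.postprocess import compute_error
from polyvem.solvers import (
    EllipticBulkProblem,
    EllipticBulkSurfaceProblem,
    EllipticSurfaceProblem,
    ParabolicBulkProblem,
    ParabolicBulkSurfaceProblem,
    ParabolicSurfaceProblem,
    solve_elliptic_bulk,
    solve_elliptic_bulk_surface,
    solve_elliptic_surface,
    solve_parabolic_bulk,
    solve_parabolic_bulk_surface,
    solve_parabolic_surface,
)


@pytest.fixture(scope="module")
def disc12():
    mesh = generate_mesh_2d(level_set("disc", 12))
    return mesh, assembly_2d(mesh)


@pytest.fixture(scope="module")
def sphere10():
    mesh = generate_mesh_3d(level_set("sphere", 10))
    return mesh, assembly_3d(mesh)


class TestEllipticBulk:
    def test_constant_solution_neumann(self, disc12):
        _, mats = disc12
        u = solve_elliptic_bulk(
            EllipticBulkProblem(1.0, 1.0, lambda P: 3.0 * np.ones(len(P)), "neu"),
            mats)
        assert np.allclose(u, 3.0, atol=1e-10)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            EllipticBulkProblem(1.0, 0.0, lambda P: P[:, 0], "neu")
        with pytest.raises(ValueError):
            EllipticBulkProblem(1.0, 1.0, lambda P: P[:, 0], "robin")
        with pytest.raises(ValueError):
            EllipticBulkProblem(-1.0, 1.0, lambda P: P[:, 0], "dir")

    def test_dirichlet_zero_on_boundary(self, disc12):
        _, mats = disc12
        u = solve_elliptic_bulk(
            EllipticBulkProblem(1.0, 1.0, lambda P: np.ones(len(P)), "dir"), mats)
        assert np.all(u[mats.surf_nodes] == 0.0)
        assert u.max() > 0.0

    def test_spatial_convergence_order(self):
        errs, hs = [], []
        f = lambda P: 8 * (1 - 2 * (P[:, 0] ** 2 + P[:, 1] ** 2)) \
            + (1 - (P[:, 0] ** 2 + P[:, 1] ** 2)) ** 2
        for Nx in (10, 20, 40):
            mesh = generate_mesh_2d(level_set("disc", Nx))
            mats = assembly_2d(mesh)
            u = solve_elliptic_bulk(EllipticBulkProblem(1.0, 1.0, f, "neu"), mats)
            uex = (1 - (mesh.P[:, 0] ** 2 + mesh.P[:, 1] ** 2)) ** 2
            errs.append(compute_error(mats, u=u, u_exact=uex).relative_error)
            hs.append(mesh.h)
        slope = np.polyfit(np.log(hs), np.log(errs), 1)[0]
        assert slope == pytest.approx(2.0, abs=0.2)


class TestEllipticSurface:
    def test_constant_solution(self, sphere10):
        _, mats = sphere10
        v = solve_elliptic_surface(
            EllipticSurfaceProblem(1.0, 1.0, lambda P: 2.0 * np.ones(len(P))),
            mats)
        assert np.allclose(v, 2.0, atol=1e-10)

    def test_spherical_harmonic_eigenfunction(self, sphere10):
        # -LapBel x = 2x on the unit sphere, so (dG LapBel + beta) v = 3x -> v = x
        _, mats = sphere10
        v = solve_elliptic_surface(
            EllipticSurfaceProblem(1.0, 1.0, lambda P: 3.0 * P[:, 0]), mats)
        PG = mats.surface_points()
        err = compute_error(mats, v=v, v_exact=PG[:, 0]).relative_error
        assert err < 4 * (0.35) ** 2  # O(h^2) at this resolution

    def test_linearity(self, sphere10):
        _, mats = sphere10
        g = lambda P: P[:, 0] ** 2 - P[:, 2]
        v1 = solve_elliptic_surface(EllipticSurfaceProblem(1.0, 1.0, g), mats)
        v10 = solve_elliptic_surface(
            EllipticSurfaceProblem(1.0, 1.0, lambda P: 10 * g(P)), mats)
        assert np.allclose(v10, 10 * v1, atol=1e-9)


class TestEllipticBulkSurface:
    def test_decoupled_constants(self, sphere10):
        _, mats = sphere10
        c = 2.5
        u, v = solve_elliptic_bulk_surface(
            EllipticBulkSurfaceProblem(
                1.0, 1.0, alpha=2.0, beta=3.0, gamma=0.0, delta=0.0,
                f=lambda P: 2.0 * c * np.ones(len(P)),
                g=lambda P: 3.0 * c * np.ones(len(P))), mats)
        assert np.allclose(u, c, atol=1e-9)
        assert np.allclose(v, c, atol=1e-9)

    def test_linearity(self, sphere10):
        _, mats = sphere10
        xyz = lambda P: P[:, 0] * P[:, 1] * P[:, 2]
        prob = dict(d_omega=1.0, d_gamma=1.0, alpha=1.0, beta=1.0,
                    gamma=-1.0, delta=2.0)
        u1, v1 = solve_elliptic_bulk_surface(
            EllipticBulkSurfaceProblem(**prob, f=xyz,
                                       g=lambda P: 29 * xyz(P)), mats)
        u2, v2 = solve_elliptic_bulk_surface(
            EllipticBulkSurfaceProblem(**prob, f=lambda P: 2 * xyz(P),
                                       g=lambda P: 58 * xyz(P)), mats)
        assert np.allclose(u2, 2 * u1, atol=1e-9)
        assert np.allclose(v2, 2 * v1, atol=1e-9)


class TestParabolicBulk:
    def test_constant_steady_state(self, disc12):
        _, mats = disc12
        c = 4.0
        res = solve_parabolic_bulk(
            ParabolicBulkProblem([1.0], [lambda u, P, t: np.zeros(len(P))],
                                 T=0.1, tau=0.01,
                                 u0=c * np.ones(mats.num_nodes)), mats)
        assert np.allclose(res.u[:, 0], c, atol=1e-12)
        assert np.allclose(res.uprime_norm, 0.0, atol=1e-9)
        assert np.allclose(res.u_average, c, atol=1e-12)
        assert len(res.t) == 10

    def test_single_step_linear_decay(self):
        # one unit square, f = -u: (M + tau K) u1 = M (1 - tau); K 1 = 0
        from test_assembly import square_mesh
        mats = assembly_2d(square_mesh(1, 1))
        tau = 0.05
        res = solve_parabolic_bulk(
            ParabolicBulkProblem([1.0], [lambda u, P, t: -u[:, 0]],
                                 T=tau, tau=tau, u0=np.ones(4)), mats)
        assert np.allclose(res.u[:, 0], 1.0 - tau, atol=1e-13)

    def test_mean_preserved_without_source(self, disc12):
        _, mats = disc12
        rng = np.random.default_rng(1)
        u0 = rng.normal(size=mats.num_nodes)
        res = solve_parabolic_bulk(
            ParabolicBulkProblem([1.0], [lambda u, P, t: np.zeros(len(P))],
                                 T=0.05, tau=0.01, u0=u0), mats)
        one = np.ones(mats.num_nodes)
        assert one @ (mats.M @ res.u[:, 0]) == pytest.approx(
            one @ (mats.M @ u0), rel=1e-12)

    def test_temporal_convergence_order(self, disc12):
        # du/dt - Lap u = e^-t problem with spatially constant exact solution:
        # u(t) = 1 + t e^-t  (f = e^-t - t e^-t + 0); constants kill K exactly,
        # so the error is purely temporal
        _, mats = disc12
        errs = []
        taus = [0.2, 0.1, 0.05]
        for tau in taus:
            res = solve_parabolic_bulk(
                ParabolicBulkProblem(
                    [1.0],
                    [lambda u, P, t: (1 - t) * np.exp(-t) * np.ones(len(P))],
                    T=1.0, tau=tau, u0=np.ones(mats.num_nodes)), mats)
            exact = 1 + res.t[-1] * np.exp(-res.t[-1])
            errs.append(np.abs(res.u[:, 0] - exact).max())
        slope = np.polyfit(np.log(taus), np.log(errs), 1)[0]
        assert slope == pytest.approx(1.0, abs=0.2)

    def test_bad_shapes(self, disc12):
        _, mats = disc12
        with pytest.raises(ValueError):
            ParabolicBulkProblem([1.0], [lambda u, P, t: 0], T=1.0, tau=-0.1,
                                 u0=np.ones(3))
        with pytest.raises(ValueError):
            solve_parabolic_bulk(
                ParabolicBulkProblem([1.0], [lambda u, P, t: np.zeros(len(P))],
                                     T=0.1, tau=0.01, u0=np.ones(3)), mats)


class TestParabolicSurface:
    def test_constant_in_time(self, sphere10):
        _, mats = sphere10
        c = 1.5
        res = solve_parabolic_surface(
            ParabolicSurfaceProblem([1.0], [lambda v, P, t: np.zeros(len(P))],
                                    T=0.1, tau=0.02,
                                    v0=c * np.ones(mats.num_surf_nodes)), mats)
        assert np.allclose(res.v[:, 0], c, atol=1e-12)

    def test_schnakenberg_fixed_point_exact(self):
        V, T = ellipsoid_surface_mesh(refine=2)
        mats = assembly_3d(import_surface(V, T))
        v1s, v2s = schnakenberg_steady_state(0.1, 0.9)
        v0 = np.column_stack([np.full(mats.num_surf_nodes, v1s),
                              np.full(mats.num_surf_nodes, v2s)])
        res = solve_parabolic_surface(
            ParabolicSurfaceProblem([1.0, 10.0],
                                    schnakenberg_kinetics(0.1, 0.9, 300.0),
                                    T=0.01, tau=1e-3, v0=v0), mats)
        assert np.allclose(res.v, v0, atol=1e-10)


class TestParabolicBulkSurface:
    def test_zero_kinetics_constant(self, sphere10):
        _, mats = sphere10
        zero_b = lambda u, P, t: np.zeros(len(P))
        zero_s = lambda v, utr, P, t: np.zeros(len(P))
        zero_f = lambda utr, v, P, t: np.zeros(len(P))
        res = solve_parabolic_bulk_surface(
            ParabolicBulkSurfaceProblem(
                [1.0], [1.0], [zero_b], [zero_s], [zero_f],
                T=0.05, tau=0.01,
                u0=2.0 * np.ones(mats.num_nodes),
                v0=3.0 * np.ones(mats.num_surf_nodes)), mats)
        assert np.allclose(res.u, 2.0, atol=1e-12)
        assert np.allclose(res.v, 3.0, atol=1e-12)

    def test_bsrds_uniform_steady_state_exact(self, sphere10):
        _, mats = sphere10
        preset = bulk_surface_rds_preset()
        ustar, vstar = preset.steady_state()
        u0 = np.tile(ustar, (mats.num_nodes, 1))
        v0 = np.tile(vstar, (mats.num_surf_nodes, 1))
        # tau within the explicit-flux stability range (the study runs use 1e-5)
        res = solve_parabolic_bulk_surface(
            ParabolicBulkSurfaceProblem(T=2e-3, tau=1e-4, u0=u0, v0=v0,
                                        **preset.problem_pieces()), mats)
        assert np.allclose(res.u, u0, atol=1e-9)
        assert np.allclose(res.v, v0, atol=1e-9)

    def test_shape_mismatch(self, sphere10):
        _, mats = sphere10
        preset = bulk_surface_rds_preset()
        with pytest.raises(ValueError, match="shapes"):
            solve_parabolic_bulk_surface(
                ParabolicBulkSurfaceProblem(
                    T=0.01, tau=1e-3,
                    u0=np.ones((3, 2)), v0=np.ones((4, 2)),
                    **preset.problem_pieces()), mats)


class TestTuringPatterns:
    def test_schnakenberg_pattern_scaled_down(self):
        # coarse ellipsoid, larger timestep: perturbation grows into a
        # spatially inhomogeneous field while the time derivative decays
        V, T = ellipsoid_surface_mesh(refine=2)
        mats = assembly_3d(import_surface(V, T))
        vstar = schnakenberg_steady_state(0.1, 0.9)
        v0 = perturbed_ic(vstar, 1e-3, seed=4, n_nodes=mats.num_surf_nodes)
        res = solve_parabolic_surface(
            ParabolicSurfaceProblem([1.0, 10.0],
                                    schnakenberg_kinetics(0.1, 0.9, 300.0),
                                    T=2.0, tau=1e-3, v0=v0), mats)
        rng = res.v[:, 0].max() - res.v[:, 0].min()
        assert rng > 0.1  # far beyond the 1e-3 perturbation: a pattern
        tail = res.uprime_norm[-200:]
        head = res.uprime_norm[len(res.uprime_norm) // 2:
                               len(res.uprime_norm) // 2 + 200]
        assert tail.mean() < head.mean()  # settling toward a steady state
        assert tail.mean() < 0.1 * res.uprime_norm.max()


def test_indicators_csv_roundtrip(tmp_path, disc12):
    _, mats = disc12
    res = solve_parabolic_bulk(
        ParabolicBulkProblem([1.0], [lambda u, P, t: np.zeros(len(P))],
                             T=0.05, tau=0.01, u0=np.ones(mats.num_nodes)),
        mats)
    path = res.indicators_to_csv(tmp_path / "ind.csv")
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    assert data.shape == (5, 3)
    assert np.allclose(data[:, 0], res.t)
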