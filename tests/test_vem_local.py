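import numpy as np
import pytest

from polyvem.geometry import PolygonElement, PolyhedronElement
from polyvem.vem_local import (
    closed_form_cube,
    closed_form_square,
    local_matrices_2d,
    local_matrices_3d,
    local_surface_segment,
    local_surface_triangle,
    monomial_gram,
    pi_nabla,
    pi_nabla_3d,
)

from conftest import make_unit_cube, make_unit_square, p1_fem_tetra, p1_fem_triangle


def random_star_polygon(rng, nvert):
    """Random star-shaped polygon: jittered radii around a convex fan."""
    th = np.sort(rng.uniform(0, 2 * np.pi, nvert))
    if np.min(np.diff(th)) < 0.1:
        th = np.linspace(0, 2 * np.pi, nvert, endpoint=False)
    r = rng.uniform(0.5, 1.5, nvert)
    V = np.column_stack([r * np.cos(th), r * np.sin(th), np.zeros(nvert)])
    return PolygonElement(V, P0=np.zeros(3))


class TestMonomialGram:
    def test_unit_square(self):
        H = monomial_gram(make_unit_square())
        # int (x-1/2)^2 = 1/12, scaled by h^2 = 2
        assert H == pytest.approx(np.diag([1.0, 1 / 24, 1 / 24]), abs=1e-14)

    def test_unit_cube(self):
        H = monomial_gram(make_unit_cube())
        assert H == pytest.approx(np.diag([1.0, 1 / 36, 1 / 36, 1 / 36]), abs=1e-14)

    def test_h11_is_measure(self):
        rng = np.random.default_rng(7)
        for n in (4, 5, 7):
            el = random_star_polygon(rng, n)
            from polyvem.geometry import polygon_measure
            assert monomial_gram(el)[0, 0] == pytest.approx(
                polygon_measure(el)[0], rel=1e-12)


class TestProjector2D:
    def test_constants(self):
        proj = pi_nabla(make_unit_square())
        assert proj.coeffs @ np.ones(4) == pytest.approx([1, 0, 0], abs=1e-14)

    def test_linear_x(self):
        # dofs = x-coordinates; projection is x itself: 0.5 + sqrt(2)*m_x
        proj = pi_nabla(make_unit_square())
        dofs = np.array([0.0, 0.0, 1.0, 1.0])
        assert proj.coeffs @ dofs == pytest.approx([0.5, np.sqrt(2), 0.0],
                                                   abs=1e-14)

    def test_checkerboard_kernel_mode(self):
        proj = pi_nabla(make_unit_square())
        dofs = np.array([1.0, -1.0, 1.0, -1.0])
        assert proj.coeffs @ dofs == pytest.approx([0, 0, 0], abs=1e-14)

    def test_idempotent_and_p1_exact_random(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            el = random_star_polygon(rng, int(rng.integers(3, 9)))
            proj = pi_nabla(el)
            assert np.abs(proj.dofmat @ proj.dofmat - proj.dofmat).max() < 1e-12
            a, b, c = rng.normal(size=3)
            dofs = a + b * el.vertices[:, 0] + c * el.vertices[:, 1]
            assert np.abs(proj.dofmat @ dofs - dofs).max() < 1e-12


class TestProjector3D:
    def test_constants_and_linear_x(self):
        proj = pi_nabla_3d(make_unit_cube())
        assert proj.coeffs @ np.ones(8) == pytest.approx([1, 0, 0, 0], abs=1e-14)
        dofs = make_unit_cube().vertices[:, 0]
        assert proj.coeffs @ dofs == pytest.approx([0.5, np.sqrt(3), 0, 0],
                                                   abs=1e-14)

    def test_p1_exactness_general_polyhedron(self):
        # slightly squashed octahedron: triangular faces, not a cube/tetra
        V = np.array([[1.1, 0, 0], [-1, 0, 0], [0, 0.9, 0],
                      [0, -1, 0], [0, 0, 1.2], [0, 0, -1]], float)
        tris = [[0, 2, 4], [2, 1, 4], [1, 3, 4], [3, 0, 4],
                [2, 0, 5], [1, 2, 5], [3, 1, 5], [0, 3, 5]]
        el = PolyhedronElement(V, [PolygonElement(V[t]) for t in tris])
        proj = pi_nabla_3d(el)
        dofs = 2 * V[:, 0] - V[:, 1] + 3 * V[:, 2] + 1
        assert np.abs(proj.dofmat @ dofs - dofs).max() < 1e-12


class TestLocalMatrices:
    def test_square_closed_form(self):
        loc = local_matrices_2d(make_unit_square())
        ref = closed_form_square(1.0)
        for a, b in ((loc.K, ref.K), (loc.C, ref.C), (loc.M, ref.M)):
            assert np.abs(a - b).max() <= 1e-14

    def test_cube_closed_form(self):
        loc = local_matrices_3d(make_unit_cube())
        ref = closed_form_cube(1.0)
        for a, b in ((loc.K, ref.K), (loc.C, ref.C), (loc.M, ref.M)):
            assert np.abs(a - b).max() <= 1e-14

    def test_triangle_equals_fem(self):
        V = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], float)
        loc = local_matrices_2d(PolygonElement(V))
        K, M = p1_fem_triangle(V)
        assert np.abs(loc.K - K).max() < 1e-12
        assert np.abs(loc.M - M).max() < 1e-12

    def test_tetra_equals_fem(self):
        V = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        faces = [PolygonElement(V[list(f)])
                 for f in ([0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3])]
        loc = local_matrices_3d(PolyhedronElement(V, faces))
        K, M = p1_fem_tetra(V)
        assert np.abs(loc.K - K).max() < 1e-12
        assert np.abs(loc.M - M).max() < 1e-12

    def test_invariants_random_polygons(self):
        rng = np.random.default_rng(3)
        from polyvem.geometry import polygon_measure
        for _ in range(20):
            el = random_star_polygon(rng, int(rng.integers(4, 8)))
            loc = local_matrices_2d(el)
            area = polygon_measure(el)[0]
            assert np.abs(loc.K.sum(axis=1)).max() < 1e-12   # constants in kernel
            assert loc.M.sum() == pytest.approx(area, rel=1e-12)
            assert loc.C.sum() == pytest.approx(area, rel=1e-12)
            w = np.linalg.eigvalsh(loc.M)
            assert w.min() > 0.0                              # M positive definite
            assert np.linalg.eigvalsh(loc.K).min() > -1e-12   # K PSD

    def test_patch_consistency_linear_field(self):
        # K applied to a linear field equals its exact boundary flux load
        rng = np.random.default_rng(5)
        el = random_star_polygon(rng, 6)
        loc = local_matrices_2d(el)
        a, b = 2.0, -1.5
        dofs = a * el.vertices[:, 0] + b * el.vertices[:, 1]
        # exact: int_E grad v . grad phi_i = sum_edges (grad v . n) int_e phi_i
        V = el.vertices
        n = len(V)
        expected = np.zeros(n)
        x, y = V[:, 0], V[:, 1]
        import numpy.linalg as la
        for i in range(n):
            j = (i + 1) % n
            ex, ey = x[j] - x[i], y[j] - y[i]
            ell = np.hypot(ex, ey)
            nx, ny = ey / ell, -ex / ell
            flux = a * nx + b * ny
            expected[i] += 0.5 * ell * flux
            expected[j] += 0.5 * ell * flux
        assert np.abs(loc.K @ dofs - expected).max() < 1e-12

    @pytest.mark.parametrize("side", [0.5, 2.0])
    def test_closed_form_scaling(self, side):
        ref1 = closed_form_square(1.0)
        refs = closed_form_square(side)
        assert np.abs(refs.K - ref1.K).max() < 1e-15
        assert np.abs(refs.M - side ** 2 * ref1.M).max() < 1e-15
        cub1, cubs = closed_form_cube(1.0), closed_form_cube(side)
        assert np.abs(cubs.K - side * cub1.K).max() < 1e-14
        assert np.abs(cubs.M - side ** 3 * cub1.M).max() < 1e-14

    def test_closed_form_rejects_bad_side(self):
        with pytest.raises(ValueError):
            closed_form_square(0.0)
        with pytest.raises(ValueError):
            closed_form_cube(-1.0)


class TestSurfaceLocals:
    def test_segment(self):
        KS, MS = local_surface_segment([0, 0, 0], [1, 0, 0])
        assert MS == pytest.approx(np.array([[1 / 3, 1 / 6], [1 / 6, 1 / 3]]))
        assert np.abs(KS.sum(axis=1)).max() < 1e-15
        KS2, MS2 = local_surface_segment([0, 0, 0], [2, 0, 0])
        assert MS2 == pytest.approx(2 * MS)
        assert KS2 == pytest.approx(KS / 2)

    def test_right_triangle(self):
        KS, MS, CS = local_surface_triangle([0, 0, 0], [1, 0, 0], [0, 1, 0])
        assert MS == pytest.approx((np.ones((3, 3)) + np.eye(3)) / 24.0)
        assert KS == pytest.approx(0.5 * np.array(
            [[2, -1, -1], [-1, 1, 0], [-1, 0, 1]]))
        assert CS == pytest.approx(MS)

    def test_equilateral_cotangent(self):
        p = [[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0]]
        KS, _, _ = local_surface_triangle(*p)
        off = -1.0 / (2 * np.sqrt(3))
        assert KS == pytest.approx(np.full((3, 3), off) + np.eye(3) * (1 / np.sqrt(3) - off))

    def test_out_of_plane_invariance(self):
        KS, MS, _ = local_surface_triangle([0, 0, 1], [1, 0, 2], [0, 1, 1])
        # same triangle rotated into a plane: compare spectra
        assert np.abs(KS.sum(axis=1)).max() < 1e-14
        assert MS.sum() > 0
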