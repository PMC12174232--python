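import numpy as np
import pytest

from polyvem.assembly import assembly_2d, assembly_3d
from polyvem.fixtures import level_set
from polyvem.geometry import PolygonElement, PolyhedronElement
from polyvem.meshgen import generate_mesh_2d, generate_mesh_3d


def make_unit_square(order="paper"):
    """Unit square element; 'paper' order (0,0),(0,1),(1,1),(1,0)."""
    V = np.array([[0, 0, 0], [0, 1, 0], [1, 1, 0], [1, 0, 0]], dtype=float)
    return PolygonElement(V, is_square=True)


def make_unit_cube():
    """Unit cube element with vertices in binary order (z fastest)."""
    import itertools
    V = np.array(list(itertools.product((0.0, 1.0), repeat=3)))
    faces = [PolygonElement(V[list(r)])
             for r in PolyhedronElement.CUBE_FACE_RINGS]
    return PolyhedronElement(V, faces, is_cube=True)


def p1_fem_triangle(V):
    """Exact P1 stiffness/mass of a triangle (independent oracle)."""
    V = np.asarray(V, dtype=float)[:, :2]
    B = np.array([V[1] - V[0], V[2] - V[0]]).T
    area = abs(np.linalg.det(B)) / 2.0
    G = np.linalg.inv(B).T @ np.array([[-1.0, -1.0], [1.0, 0.0], [0.0, 1.0]]).T
    K = area * G.T @ G
    M = area / 12.0 * (np.ones((3, 3)) + np.eye(3))
    return K, M


def p1_fem_tetra(V):
    """Exact P1 stiffness/mass of a tetrahedron (independent oracle)."""
    V = np.asarray(V, dtype=float)
    B = np.array([V[1] - V[0], V[2] - V[0], V[3] - V[0]]).T
    vol = abs(np.linalg.det(B)) / 6.0
    G = np.linalg.inv(B).T @ np.array(
        [[-1.0, -1.0, -1.0], [1, 0, 0], [0, 1, 0], [0, 0, 1]]).T
    K = vol * G.T @ G
    M = vol / 20.0 * (np.ones((4, 4)) + np.eye(4))
    return K, M


@pytest.fixture(scope="session")
def sphere_mesh_mats():
    """The unit-ball mesh at the study resolution (Nx=30) and its operators.

    Built once per session; several experiments share it.
    """
    mesh = generate_mesh_3d(level_set("sphere", 30))
    mats = assembly_3d(mesh)
    return mesh, mats


@pytest.fixture(scope="session")
def disc_mesh_mats():
    mesh = generate_mesh_2d(level_set("disc", 40))
    mats = assembly_2d(mesh)
    return mesh, mats


@pytest.fixture(scope="session")
def coarse_sphere_mesh():
    return generate_mesh_3d(level_set("sphere", 8))
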