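import numpy as np
import pytest

from hullcom.mesh import TriMesh

CUBE_VERTICES = np.array(
    [
        [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
        [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1],
    ],
    dtype=float,
)
CUBE_FACES = np.array(
    [
        [0, 2, 1], [0, 3, 2],   # bottom
        [4, 5, 6], [4, 6, 7],   # top
        [0, 1, 5], [0, 5, 4],   # y = 0
        [2, 3, 7], [2, 7, 6],   # y = 1
        [0, 4, 7], [0, 7, 3],   # x = 0
        [1, 2, 6], [1, 6, 5],   # x = 1
    ]
)


def make_cube(edge: float = 1.0, origin=(0.0, 0.0, 0.0)) -> TriMesh:
    """Outward-oriented closed unit cube scaled/translated as requested."""
    return TriMesh(CUBE_VERTICES * edge + np.asarray(origin, dtype=float),
                   CUBE_FACES.copy())


def make_tetrahedron() -> TriMesh:
    verts = np.array(
        [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float
    )
    faces = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return TriMesh(verts, faces)


@pytest.fixture
def cube() -> TriMesh:
    return make_cube()


@pytest.fixture
def tetrahedron() -> TriMesh:
    return make_tetrahedron()


def random_rotation(rng) -> np.ndarray:
    """Uniform-ish random proper rotation via QR decomposition."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
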