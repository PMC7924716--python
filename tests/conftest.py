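import numpy as np
import pytest

from morphowarp import build_scheme, make_face_mesh


@pytest.fixture(scope="session")
def face():
    """Small synthetic face mesh + its 16 named anatomical points."""
    return make_face_mesh(24, seed=0)


@pytest.fixture(scope="session")
def face_mesh(face):
    return face[0]


@pytest.fixture(scope="session")
def face_points(face):
    return face[1]


@pytest.fixture(scope="session")
def small_scheme(face):
    """16 fixed landmarks + 40 surface semi-landmarks on the small face."""
    mesh, pts = face
    return build_scheme(mesh, pts, n_semis=40, spacing_radius=1.5, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def flat_square_mesh(side_mm=100.0, n=21):
    """Flat triangulated square in the z=0 plane (helper for tests)."""
    lin = np.linspace(0.0, side_mm, n)
    u, v = np.meshgrid(lin, lin, indexing="ij")
    verts = np.stack([u.ravel(), v.ravel(), np.zeros(n * n)], axis=1)
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            b = (i + 1) * n + j
            c = (i + 1) * n + j + 1
            d = i * n + j + 1
            faces.append([a, b, c])
            faces.append([a, c, d])
    from morphowarp import TriangleMesh

    return TriangleMesh(verts, np.array(faces))
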