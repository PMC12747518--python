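import numpy as np
import pytest

from gyralkit.io import cut_hemisphere
from gyralkit.synth import make_brainlike_solid, make_icosphere, make_landmark_curves


@pytest.fixture(scope="session")
def icosphere4():
    return make_icosphere(4, 1.0)


@pytest.fixture(scope="session")
def hemisphere(icosphere4):
    return cut_hemisphere(icosphere4, (0.0, 0.0, 0.0), (0.0, 0.0, 1.0))


@pytest.fixture(scope="session")
def hemi_landmarks(hemisphere):
    return make_landmark_curves(hemisphere, n_curves=3, seed=7, min_separation=0.15)


@pytest.fixture(scope="session")
def small_brain_volume():
    """Coarse brain-like solid, cheap enough for solver unit tests."""
    return make_brainlike_solid(
        seed=1, semi_axes=(1.0, 0.8, 0.7), n_modes=3, amplitude=0.03, target_edge=0.2
    )


@pytest.fixture(scope="session")
def unit_ball_volume():
    """Unperturbed unit ball for analytic distance-field checks."""
    return make_brainlike_solid(
        seed=0, semi_axes=(1.0, 1.0, 1.0), n_modes=1, amplitude=0.0, target_edge=0.25
    )


@pytest.fixture(scope="session")
def random_tet_mesh():
    """Small irregular tet mesh (Delaunay of seeded points, reoriented)."""
    from scipy.spatial import Delaunay

    from gyralkit.types import TetVolume

    rng = np.random.default_rng(3)
    pts = rng.random((12, 3))
    tets = Delaunay(pts).simplices
    v = pts
    vol = (
        np.einsum(
            "ij,ij->i",
            np.cross(v[tets[:, 1]] - v[tets[:, 0]], v[tets[:, 2]] - v[tets[:, 0]]),
            v[tets[:, 3]] - v[tets[:, 0]],
        )
        / 6.0
    )
    tets[vol < 0] = tets[vol < 0][:, [0, 1, 3, 2]]
    return TetVolume(pts, tets)
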