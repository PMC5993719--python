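import numpy as np
import pytest

from spheroidgeom.geometry import convex_hull_mesh


@pytest.fixture
def rng():
    return np.random.default_rng(20180608)


@pytest.fixture
def unit_cube_mesh():
    corners = np.array(
        [[x, y, z] for x in (0.0, 1.0) for y in (0.0, 1.0) for z in (0.0, 1.0)]
    )
    return convex_hull_mesh(corners)


def random_rotation(rng) -> np.ndarray:
    """Haar-ish random rotation matrix via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 2] *= -1
    return q
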