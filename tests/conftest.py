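import numpy as np
import pytest

from critnet import ContactNetwork


@pytest.fixture
def p3_network():
    """Path graph on 3 nodes (0-1-2)."""
    return ContactNetwork.from_edges(3, [(0, 1), (1, 2)])


@pytest.fixture
def k4_network():
    """Complete graph on 4 nodes."""
    return ContactNetwork.from_edges(4, [(i, j) for i in range(4) for j in range(i + 1, 4)])


@pytest.fixture
def two_triangles():
    """Two disconnected triangles (nodes 0-2 and 3-5)."""
    return ContactNetwork.from_edges(
        6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_rotation(rng):
    """Haar-random 3x3 rotation matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
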