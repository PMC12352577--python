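import numpy as np
import pytest

from conntopo import FCMatrix
from conntopo.datasets import two_cycle_toy_network


@pytest.fixture(scope="session")
def toy():
    """The 10-node two-cycle example network and its 3-class partition."""
    return two_cycle_toy_network()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240131)


def random_fc(rng, n: int) -> FCMatrix:
    """Random valid FC: symmetric, entries in [0, 1], unit diagonal."""
    A = rng.random((n, n))
    W = (A + A.T) / 2.0
    np.fill_diagonal(W, 1.0)
    return FCMatrix(W)


def random_diagram(rng, m: int) -> np.ndarray:
    """m random finite intervals with birth <= death, as an (m, 2) array."""
    pts = rng.random((m, 2))
    return np.sort(pts, axis=1)
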