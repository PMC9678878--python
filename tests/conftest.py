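import numpy as np
import pytest

from gride.neighbors import NeighborTable, build_neighbor_table


@pytest.fixture
def rng():
    return np.random.default_rng(1729)


@pytest.fixture
def collinear_table():
    """Three collinear 1-D points {0, 1, 3}: distances known by hand."""
    return build_neighbor_table(np.array([[0.0], [1.0], [3.0]]), kmax=2)


@pytest.fixture
def random_table(rng):
    """100 Gaussian points in 5-D with a deep neighbor table."""
    x = rng.standard_normal((100, 5))
    return x, build_neighbor_table(x, kmax=20)
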