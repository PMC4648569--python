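import numpy as np
import pytest

from ecotrap.landscape import Aridity, GridMap, Species


def make_map(host_rows, aridity=Aridity.WET):
    """Build a GridMap from a nested list of Species codes; uniform aridity."""
    host = np.array([[int(s) for s in row] for row in host_rows], dtype=np.int8)
    arid = np.full(host.shape, int(aridity), dtype=np.int8)
    return GridMap(host, arid)


def uniform_map(n_rows, n_cols, species, aridity=Aridity.WET):
    host = np.full((n_rows, n_cols), int(species), dtype=np.int8)
    arid = np.full((n_rows, n_cols), int(aridity), dtype=np.int8)
    return GridMap(host, arid)


@pytest.fixture(scope="session")
def small_fixture_map():
    """A small corridor landscape for fast simulation tests."""
    from ecotrap.landscape import generate_fixture_landscape

    return generate_fixture_landscape(n_rows=120, n_cols=1600, seed=2)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
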