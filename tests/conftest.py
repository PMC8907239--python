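import networkx as nx
import numpy as np
import pytest

from percolearn import (
    build_state_matrix,
    configuration_model_graph,
    make_square_lattice,
    sample_powerlaw_degrees,
)


@pytest.fixture(scope="session")
def lattice32():
    return make_square_lattice(32)


@pytest.fixture(scope="session")
def lattice6():
    return make_square_lattice(6)


@pytest.fixture(scope="session")
def powerlaw_net():
    """One configuration-model realization at the standard study conditions."""
    deg = sample_powerlaw_degrees(1000, 3.1, kmin=2, seed=1)
    return configuration_model_graph(deg, seed=1)


@pytest.fixture(scope="session")
def small_state_matrix(lattice6):
    """Coarse-grid (M=100) state matrix of the 6x6 lattice, coupled process."""
    return build_state_matrix(lattice6, dphi=0.01, seed=5)


@pytest.fixture
def path3():
    g = nx.path_graph(3)
    return g


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
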