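import networkx as nx
import numpy as np
import pytest

from prscan import fixtures, gnm, prs


def random_connected_graph(n: int, p: float, seed: int) -> nx.Graph:
    """Erdos-Renyi graph resampled until connected (deterministic in seed)."""
    rng = np.random.default_rng(seed)
    for _ in range(200):
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31 - 1)))
        if g.number_of_nodes() >= 2 and nx.is_connected(g):
            return g
    raise RuntimeError("could not draw a connected graph")


def covariance_oracle(g: nx.Graph) -> np.ndarray:
    """Brute-force Laplacian pseudo-inverse via numpy.linalg.pinv (gamma=1)."""
    nodes = sorted(g.nodes())
    lap = nx.laplacian_matrix(g, nodelist=nodes).toarray().astype(float)
    return np.linalg.pinv(lap, hermitian=True)


@pytest.fixture(scope="session")
def catalogue():
    return fixtures.make_closed_form_graphs()


@pytest.fixture(scope="session")
def planted():
    return fixtures.make_core_periphery(rng_seed=7)


@pytest.fixture(scope="session")
def planted_prs(planted):
    model = gnm.build_laplacian(planted.network)
    return prs.compute_prs(gnm.compute_covariance(model))
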