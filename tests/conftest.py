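import sys
from pathlib import Path

import networkx as nx
import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper module

from evmirnet.config import SimConfig


def random_connected_graph(rng: np.random.Generator, n_min=3, n_max=7) -> nx.Graph:
    """Small random connected graph for oracle-equivalence suites."""
    n = int(rng.integers(n_min, n_max + 1))
    while True:
        p = float(rng.uniform(0.3, 0.9))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if nx.is_connected(g):
            return g


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """Reduced study dimensions for fast unit tests."""
    return SimConfig(
        n_mirnas_total=100,
        n_subjects=5,
        detect_fraction=0.2,
        n_up=40,
        n_down=20,
        p_base=0.1,
        enrichment_ratio=2.0,
        ppi_n_nodes=40,
        ppi_model_params={"model": "communities", "n_communities": 2, "p_within": 0.3, "p_between": 0.01},
        n_planted_hubs=1,
        seed=7,
    )


@pytest.fixture
def sim_bundle(small_config):
    from evmirnet import simulate

    return simulate.simulate_all(small_config)
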