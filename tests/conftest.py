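import networkx as nx
import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ppiclust.interactome import Interactome

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def path_graph() -> Interactome:
    """a-b-c-d-e chain plus an isolated pair x-y (two components)."""
    g = nx.Graph()
    nx.add_path(g, list("ABCDE"), confidence=900)
    g.add_edge("X", "Y", confidence=900)
    return Interactome(g)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_er_interactome(rng, n_max=50, p=0.15) -> tuple[Interactome, nx.Graph]:
    """A random Erdős–Rényi graph with synthetic symbols, as (Interactome, raw graph)."""
    n = int(rng.integers(5, n_max + 1))
    raw = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31 - 1)))
    raw = nx.relabel_nodes(raw, {i: f"N{i:03d}" for i in raw.nodes})
    g = nx.Graph()
    g.add_nodes_from(raw.nodes)
    g.add_edges_from(((a, b, {"confidence": 900}) for a, b in raw.edges))
    return Interactome(g), raw
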