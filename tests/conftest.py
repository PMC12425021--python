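import networkx as nx
import numpy as np
import pytest

from sharp.netcore import Interactome


@pytest.fixture
def path_net():
    """Path graph a-b-c-d."""
    return Interactome.from_edges([("a", "b"), ("b", "c"), ("c", "d")])


def random_net(n: int, p: float, seed: int) -> Interactome:
    """Connected-ish G(n, p) with string node labels n00..."""
    g = nx.gnp_random_graph(n, p, seed=seed)
    g = nx.relabel_nodes(g, {i: f"n{i:03d}" for i in range(n)})
    g.add_nodes_from(f"n{i:03d}" for i in range(n))
    return Interactome(g)


def heavy_tail_net(n: int, seed: int, exponent: float = 2.5) -> Interactome:
    """Simple configuration-model graph with a power-law degree sequence."""
    rng = np.random.default_rng(seed)
    kmax = max(2, int(np.sqrt(n)))
    k = np.arange(1, kmax + 1, dtype=float)
    p = k ** -exponent
    p /= p.sum()
    degs = rng.choice(np.arange(1, kmax + 1), size=n, p=p)
    if degs.sum() % 2:
        degs[0] += 1
    g = nx.Graph(nx.configuration_model(degs.tolist(), seed=seed))
    g.remove_edges_from(nx.selfloop_edges(g))
    g = nx.relabel_nodes(g, {i: f"n{i:04d}" for i in range(n)})
    g.add_nodes_from(f"n{i:04d}" for i in range(n))
    return Interactome(g)
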