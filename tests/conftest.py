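import networkx as nx
import numpy as np
import pytest

from menstab import AbundanceTable
from menstab.network import SignedNetwork


def make_table(counts, group_of=None, lineage_of=None):
    counts = np.asarray(counts, dtype=float)
    return AbundanceTable(
        taxa_ids=[f"t{i+1}" for i in range(counts.shape[0])],
        sample_ids=[f"s{j+1}" for j in range(counts.shape[1])],
        counts=counts,
        group_of=group_of,
        lineage_of=lineage_of,
    )


def signed_from_graph(g: nx.Graph, positive_fraction: float = 1.0, seed: int = 0):
    """Wrap a plain graph as a SignedNetwork with randomly dealt signs."""
    rng = np.random.default_rng(seed)
    h = nx.Graph()
    h.add_nodes_from(str(n) for n in g.nodes)
    n_edges = g.number_of_edges()
    n_pos = int(round(positive_fraction * n_edges))
    signs = np.full(n_edges, -1, int)
    if n_pos:
        signs[rng.choice(n_edges, size=n_pos, replace=False)] = 1
    for k, (u, v) in enumerate(g.edges):
        h.add_edge(str(u), str(v), sign=int(signs[k]), weight=1.0)
    return SignedNetwork(graph=h)


@pytest.fixture
def small_table():
    return make_table(
        [[10, 0, 3, 7], [1, 5, 2, 2], [0, 4, 4, 1], [2, 2, 2, 2]],
    )


@pytest.fixture
def grouped_table():
    rng = np.random.default_rng(42)
    counts = rng.integers(0, 50, size=(12, 8)).astype(float)
    counts[counts.sum(axis=1) == 0, 0] = 1
    group_of = {f"s{j+1}": ("A" if j < 4 else "B") for j in range(8)}
    return make_table(counts, group_of=group_of)
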