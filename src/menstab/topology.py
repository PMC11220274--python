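"""Topological indices, Maslov–Sneppen null ensembles, small-world check.

All indices treat the graph as unweighted and unsigned: edge signs matter for
cohesion and the positive-edge fraction, not for path lengths or clustering.
The null model preserves each node's degree exactly (double-edge swaps) and
the global count of positive edges (sign reassignment), so differences from
the empirical network isolate wiring beyond the degree sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .network import SignedNetwork

__all__ = [
    "TopologySummary",
    "NullEnsembleSummary",
    "SmallWorldReport",
    "topology_summary",
    "maslov_sneppen_randomize",
    "null_ensemble",
    "small_world_check",
]


@dataclass
class TopologySummary:
    n_nodes: int
    n_links: int
    avgK: float
    avgCC: float
    GD: float
    CD: float
    density: float
    transitivity: float
    modularity: float
    module_count: int
    powerlaw_r2: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class NullEnsembleSummary:
    n_random: int
    avgCC_mean: float
    avgCC_sd: float
    GD_mean: float
    GD_sd: float
    modularity_mean: float
    modularity_sd: float
    seed: int


@dataclass
class SmallWorldReport:
    GD: float
    log_n: float
    gd_within_factor: bool
    avgCC_ratio: float
    is_small_world: bool


def _mean_geodesic(g: nx.Graph) -> float:
    """Average shortest-path length over connected pairs only.

    Multi-component graphs stay finite: unreachable pairs are excluded from
    the average rather than padded with infinity.
    """
    total = 0.0
    n_pairs = 0
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        if sub.number_of_nodes() < 2:
            continue
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            total += sum(dists.values())
            n_pairs += len(dists) - 1  # excludes self
    if n_pairs == 0:
        return 0.0
    return total / n_pairs


def _degree_centralization(g: nx.Graph) -> float:
    """Freeman degree centralization: Σ(k_max − k_i) / ((n−1)(n−2))."""
    n = g.number_of_nodes()
    if n < 3:
        raise ValueError("degree centralization needs at least 3 nodes")
    degrees = np.array([d for _, d in g.degree()], dtype=float)
    return float((degrees.max() - degrees).sum() / ((n - 1) * (n - 2)))


def _powerlaw_r2(g: nx.Graph) -> float:
    """R² of OLS on log10(frequency of degree k) vs log10(k).

    Fits the scale-free index of the degree distribution the simple way:
    degree-frequency pairs with k ≥ 1, no xmin search.  Returns NaN when
    fewer than 3 distinct degrees exist.
    """
    degrees = np.array([d for _, d in g.degree() if d >= 1])
    if degrees.size == 0:
        return float("nan")
    ks, counts = np.unique(degrees, return_counts=True)
    if ks.size < 3:
        return float("nan")
    x = np.log10(ks.astype(float))
    y = np.log10(counts.astype(float))
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return 1.0
    return 1.0 - ss_res / ss_tot


def topology_summary(net: SignedNetwork, partition=None, seed: int = 0) -> TopologySummary:
    """Compute the standard index panel for a signed network.

    ``partition`` (a :class:`menstab.stability.Partition`) may be passed to
    reuse an existing module decomposition; otherwise greedy modularity
    maximisation is run internally.
    """
    g = net.graph
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("empty network")
    L = g.number_of_edges()
    if partition is None:
        from .stability import module_partition

        partition = module_partition(net, seed=seed)
    return TopologySummary(
        n_nodes=n,
        n_links=L,
        avgK=2.0 * L / n,
        avgCC=float(nx.average_clustering(g, count_zeros=True)),
        GD=_mean_geodesic(g),
        CD=_degree_centralization(g),
        density=2.0 * L / (n * (n - 1)) if n > 1 else 0.0,
        transitivity=float(nx.transitivity(g)),
        modularity=partition.modularity,
        module_count=partition.n_modules,
        powerlaw_r2=_powerlaw_r2(g),
    )


def maslov_sneppen_randomize(
    net: SignedNetwork,
    n_swaps: int | None = None,
    seed: int | np.random.Generator = 0,
    max_tries_factor: int = 100,
) -> SignedNetwork:
    """Degree-preserving rewiring by repeated double-edge swaps.

    A swap picks two edges (a,b), (c,d) and rewires to (a,d), (c,b),
    rejecting self-loops and parallel edges, so every node keeps its degree
    exactly.  Edge signs are then redealt uniformly over the new edge set,
    preserving the global count of positive edges.  Defaults to 10 × L swaps.
    If no legal swap exists (e.g. a triangle) the input is returned unchanged
    with a warning.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g = net.graph
    L = g.number_of_edges()
    if L < 2:
        raise ValueError("need at least 2 edges to rewire")
    if n_swaps is None:
        n_swaps = 10 * L
    nodes = list(g.nodes)
    edges = [tuple(e) for e in g.edges]
    edge_set = set(frozenset(e) for e in edges)
    n_pos = int((net.edge_signs() > 0).sum())

    successes = 0
    tries = 0
    max_tries = max_tries_factor * n_swaps
    while successes < n_swaps and tries < max_tries:
        tries += 1
        i, j = rng.integers(0, L), rng.integers(0, L)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if rng.random() < 0.5:
            c, d = d, c
        # propose (a,d) and (c,b)
        if a == d or c == b:
            continue
        if frozenset((a, d)) in edge_set or frozenset((c, b)) in edge_set:
            continue
        edge_set.discard(frozenset((a, b)))
        edge_set.discard(frozenset((c, d)))
        edge_set.add(frozenset((a, d)))
        edge_set.add(frozenset((c, b)))
        edges[i] = (a, d)
        edges[j] = (c, b)
        successes += 1

    if successes == 0:
        warnings.warn(
            "no legal double-edge swap found; returning the network unchanged",
            stacklevel=2,
        )
        return SignedNetwork(graph=g.copy(), threshold_used=net.threshold_used)

    new_g = nx.Graph()
    new_g.add_nodes_from(nodes)
    signs = np.full(L, -1, dtype=int)
    signs[rng.choice(L, size=n_pos, replace=False)] = 1
    weights = [d.get("weight", 1.0) for _, _, d in g.edges(data=True)]
    perm = rng.permutation(L)
    for k, (u, v) in enumerate(edges):
        new_g.add_edge(u, v, sign=int(signs[k]), weight=float(weights[perm[k]]))
    return SignedNetwork(graph=new_g, threshold_used=net.threshold_used)


def null_ensemble(
    net: SignedNetwork, n_random: int = 100, seed: int = 0
) -> NullEnsembleSummary:
    """Mean ± sd of avgCC, GD and modularity over rewired replicates."""
    if net.n_nodes == 0:
        raise ValueError("empty network")
    rng = np.random.default_rng(seed)
    from .stability import module_partition

    avgcc, gd, mod = [], [], []
    for _ in range(n_random):
        rand = maslov_sneppen_randomize(net, seed=rng)
        avgcc.append(nx.average_clustering(rand.graph, count_zeros=True))
        gd.append(_mean_geodesic(rand.graph))
        mod.append(module_partition(rand, seed=0).modularity)
    avgcc, gd, mod = map(np.asarray, (avgcc, gd, mod))
    return NullEnsembleSummary(
        n_random=n_random,
        avgCC_mean=float(avgcc.mean()),
        avgCC_sd=float(avgcc.std(ddof=1)) if n_random > 1 else 0.0,
        GD_mean=float(gd.mean()),
        GD_sd=float(gd.std(ddof=1)) if n_random > 1 else 0.0,
        modularity_mean=float(mod.mean()),
        modularity_sd=float(mod.std(ddof=1)) if n_random > 1 else 0.0,
        seed=seed if isinstance(seed, int) else -1,
    )


def small_world_check(
    obs: TopologySummary,
    null: NullEnsembleSummary,
    gd_factor: float = 2.0,
    cc_sigma: float = 2.0,
) -> SmallWorldReport:
    """Flag small-world structure: geodesic distance near ln(n) combined with
    clustering above the degree-matched null ensemble.

    Clustering must exceed the null mean by ``cc_sigma`` ensemble standard
    deviations (ratio > 1 alone would flag half of all degree-matched random
    graphs by chance).
    """
    log_n = float(np.log(obs.n_nodes))
    gd_ok = bool(log_n / gd_factor <= obs.GD <= log_n * gd_factor)
    ratio = obs.avgCC / null.avgCC_mean if null.avgCC_mean > 0 else float("inf")
    cc_ok = obs.avgCC > null.avgCC_mean + cc_sigma * null.avgCC_sd and ratio > 1.0
    return SmallWorldReport(
        GD=obs.GD,
        log_n=log_n,
        gd_within_factor=gd_ok,
        avgCC_ratio=float(ratio),
        is_small_world=bool(gd_ok and cc_ok),
    )
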