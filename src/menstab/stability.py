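"""Module detection, Zi–Pi node roles, robustness and cohesion.

These are the stability-facing statistics of the network analysis: which taxa
occupy hub/connector roles, how much of the community survives random node
loss, and how strongly positively/negatively connected the community is per
sample (cohesion).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .network import SignedNetwork

__all__ = [
    "Partition",
    "NodeRole",
    "RobustnessResult",
    "CohesionResult",
    "StabilityComparison",
    "module_partition",
    "zi_pi",
    "robustness",
    "cohesion",
    "stability_report",
    "ZI_HUB_CUTOFF",
    "PI_CONNECTOR_CUTOFF",
]

# Olesen-convention role cutoffs: within-module degree z-score and
# among-module participation coefficient.
ZI_HUB_CUTOFF = 2.5
PI_CONNECTOR_CUTOFF = 0.62


@dataclass
class Partition:
    """Node → module assignment with its modularity score."""

    module_of: dict[str, int]
    modularity: float

    @property
    def n_modules(self) -> int:
        return len(set(self.module_of.values()))

    def module_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for m in self.module_of.values():
            sizes[m] = sizes.get(m, 0) + 1
        return sizes

    def members(self, module: int) -> list[str]:
        return [n for n, m in self.module_of.items() if m == module]


@dataclass
class NodeRole:
    node: str
    zi: float
    pi: float
    role: str  # peripheral | connector | module hub | network hub


@dataclass
class RobustnessResult:
    removal_fraction: float
    n_replicates: int
    mean: float
    sd: float
    seed: int
    replicate_values: np.ndarray = field(repr=False, default=None)


@dataclass
class CohesionResult:
    """Per-sample positive (≥0) and negative (≤0) cohesion plus the per-taxon
    connectedness vectors they are built from."""

    sample_ids: list[str]
    positive: np.ndarray
    negative: np.ndarray
    taxa_ids: list[str]
    connectedness_pos: np.ndarray
    connectedness_neg: np.ndarray


@dataclass
class StabilityComparison:
    metric: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    statistic: float
    p_value: float
    stars: str


def modularity_score(g: nx.Graph, module_of: dict[str, int]) -> float:
    """Newman modularity Q = Σ_c [L_c/L − (d_c/2L)²] for an unweighted graph."""
    L = g.number_of_edges()
    if L == 0:
        return 0.0
    within: dict[int, int] = {}
    degsum: dict[int, int] = {}
    for u, v in g.edges:
        mu, mv = module_of[u], module_of[v]
        if mu == mv:
            within[mu] = within.get(mu, 0) + 1
    for n, d in g.degree():
        m = module_of[n]
        degsum[m] = degsum.get(m, 0) + d
    q = 0.0
    for m in set(module_of.values()):
        q += within.get(m, 0) / L - (degsum.get(m, 0) / (2.0 * L)) ** 2
    return q


def module_partition(net: SignedNetwork, seed: int = 0) -> Partition:
    """Greedy modularity-maximising agglomeration (Clauset–Newman–Moore).

    Deterministic for a given graph; ``seed`` is accepted for interface
    symmetry with the stochastic operations but does not influence the
    greedy agglomeration.
    """
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    if g.number_of_edges() == 0:
        module_of = {n: i for i, n in enumerate(sorted(g.nodes))}
        return Partition(module_of=module_of, modularity=0.0)
    communities = nx.community.greedy_modularity_communities(g)
    module_of: dict[str, int] = {}
    for i, comm in enumerate(sorted(communities, key=lambda c: (-len(c), sorted(c)[0]))):
        for n in comm:
            module_of[n] = i
    return Partition(module_of=module_of, modularity=modularity_score(g, module_of))


def zi_pi(net: SignedNetwork, partition: Partition) -> list[NodeRole]:
    """Within-module degree z-score (Zi) and participation coefficient (Pi).

    Zi standardises a node's within-module link count against its module's
    mean and sd (sd = 0 → Zi = 0, so regular or single-node modules classify
    as non-hubs).  Pi = 1 − Σ_m (k_i,m / k_i)² measures how evenly the node's
    links spread over modules.  Roles follow the fixed cutoffs: network hub
    (Zi > 2.5 and Pi > 0.62), module hub (Zi only), connector (Pi only),
    else peripheral.
    """
    g = net.graph
    missing = set(g.nodes) - set(partition.module_of)
    if missing:
        raise ValueError(f"partition does not cover nodes: {sorted(missing)[:5]}")
    module_of = partition.module_of
    # within-module degree per node
    k_within: dict[str, int] = {n: 0 for n in g.nodes}
    k_by_module: dict[str, dict[int, int]] = {n: {} for n in g.nodes}
    for u, v in g.edges:
        mu, mv = module_of[u], module_of[v]
        k_by_module[u][mv] = k_by_module[u].get(mv, 0) + 1
        k_by_module[v][mu] = k_by_module[v].get(mu, 0) + 1
        if mu == mv:
            k_within[u] += 1
            k_within[v] += 1

    stats_by_module: dict[int, tuple[float, float]] = {}
    for m in set(module_of.values()):
        vals = np.array([k_within[n] for n in g.nodes if module_of[n] == m], float)
        stats_by_module[m] = (float(vals.mean()), float(vals.std(ddof=0)))

    roles: list[NodeRole] = []
    for n in g.nodes:
        k = g.degree(n)
        mean_own, sd_own = stats_by_module[module_of[n]]
        zi = 0.0 if sd_own == 0 else (k_within[n] - mean_own) / sd_own
        pi = 1.0 - sum((km / k) ** 2 for km in k_by_module[n].values())
        if zi > ZI_HUB_CUTOFF and pi > PI_CONNECTOR_CUTOFF:
            role = "network hub"
        elif zi > ZI_HUB_CUTOFF:
            role = "module hub"
        elif pi > PI_CONNECTOR_CUTOFF:
            role = "connector"
        else:
            role = "peripheral"
        roles.append(NodeRole(node=n, zi=float(zi), pi=float(pi), role=role))
    return roles


def robustness(
    net: SignedNetwork,
    removal_fraction: float = 0.5,
    n_replicates: int = 100,
    seed: int = 0,
) -> RobustnessResult:
    """Fraction of taxa remaining after random removal plus secondary extinction.

    Each replicate removes ⌊fraction × n⌋ uniformly chosen nodes, then
    iteratively deletes survivors whose degree has dropped to zero (a taxon
    that has lost all its associations is taken to go extinct) until a fixed
    point; the replicate value is survivors / original node count.
    """
    if not 0.0 < removal_fraction < 1.0:
        raise ValueError("removal_fraction must lie in (0, 1)")
    g = net.graph
    n = g.number_of_nodes()
    if n < 4:
        raise ValueError("robustness needs at least 4 nodes")
    n_remove = int(np.floor(removal_fraction * n))
    rng = np.random.default_rng(seed)
    nodes = list(g.nodes)
    # adjacency as index lists for speed
    index = {u: i for i, u in enumerate(nodes)}
    neighbors = [np.array([index[v] for v in g.neighbors(u)], int) for u in nodes]
    degrees0 = np.array([g.degree(u) for u in nodes], int)

    values = np.empty(n_replicates)
    for rep in range(n_replicates):
        removed = np.zeros(n, bool)
        removed[rng.choice(n, size=n_remove, replace=False)] = True
        deg = degrees0.copy()
        for i in np.flatnonzero(removed):
            deg[neighbors[i]] -= 1
        # cascade: drop isolated survivors
        queue = [i for i in range(n) if not removed[i] and deg[i] == 0]
        while queue:
            i = queue.pop()
            if removed[i]:
                continue
            removed[i] = True
            for j in neighbors[i]:
                if not removed[j]:
                    deg[j] -= 1
                    if deg[j] == 0:
                        queue.append(j)
        values[rep] = (n - removed.sum()) / n
    return RobustnessResult(
        removal_fraction=removal_fraction,
        n_replicates=n_replicates,
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)) if n_replicates > 1 else 0.0,
        seed=seed,
        replicate_values=values,
    )


def cohesion(
    table,
    null_iterations: int = 0,
    seed: int = 0,
) -> CohesionResult:
    """Positive and negative cohesion per sample.

    Each taxon's positive (negative) connectedness is the mean of its positive
    (negative) pairwise Pearson correlations with the other taxa, 0 when it
    has none.  A sample's positive cohesion is the relative-abundance-weighted
    sum of positive connectedness (≥ 0); negative cohesion likewise (≤ 0).
    With ``null_iterations > 0`` the Herren–McMahon-style taxon-shuffle null
    mean of each correlation is subtracted before averaging.
    """
    if table.n_samples < 4:
        raise ValueError("cohesion needs at least 4 samples")
    from .tables import relative_abundance

    rel = relative_abundance(table)
    variances = rel.counts.var(axis=1)
    constant = variances == 0
    if constant.any():
        warnings.warn(
            f"excluding {int(constant.sum())} constant taxa from cohesion",
            stacklevel=2,
        )
        rel = rel.select_taxa(~constant)
    x = rel.counts  # taxa × samples, proportions
    r = np.corrcoef(x)
    np.fill_diagonal(r, 0.0)

    if null_iterations > 0:
        rng = np.random.default_rng(seed)
        null_mean = np.zeros_like(r)
        for _ in range(null_iterations):
            shuffled = np.apply_along_axis(rng.permutation, 1, x)
            rn = np.corrcoef(shuffled)
            np.fill_diagonal(rn, 0.0)
            null_mean += rn
        r = r - null_mean / null_iterations
        np.fill_diagonal(r, 0.0)

    n_taxa = x.shape[0]
    conn_pos = np.zeros(n_taxa)
    conn_neg = np.zeros(n_taxa)
    for i in range(n_taxa):
        row = np.delete(r[i], i)
        pos = row[row > 0]
        neg = row[row < 0]
        conn_pos[i] = pos.mean() if pos.size else 0.0
        conn_neg[i] = neg.mean() if neg.size else 0.0

    positive = x.T @ conn_pos
    negative = x.T @ conn_neg
    return CohesionResult(
        sample_ids=list(rel.sample_ids),
        positive=positive,
        negative=negative,
        taxa_ids=list(rel.taxa_ids),
        connectedness_pos=conn_pos,
        connectedness_neg=conn_neg,
    )


_STAR_TIERS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def _stars(p: float) -> str:
    for cut, s in _STAR_TIERS:
        if p < cut:
            return s
    return ""


def stability_report(
    group_a: dict[str, np.ndarray],
    group_b: dict[str, np.ndarray],
    label_a: str = "A",
    label_b: str = "B",
) -> list[StabilityComparison]:
    """Two-sided Mann–Whitney comparison of stability metrics between groups.

    ``group_a`` / ``group_b`` map metric name → vector of replicate or
    per-sample values (e.g. robustness replicates, positive cohesion,
    negative cohesion).  Negative cohesion is compared on absolute values so
    'larger' means more intense competition.
    """
    out: list[StabilityComparison] = []
    for metric in group_a:
        if metric not in group_b:
            continue
        a = np.asarray(group_a[metric], float)
        b = np.asarray(group_b[metric], float)
        if a.size < 3 or b.size < 3:
            raise ValueError(f"need ≥ 3 values per group for metric {metric!r}")
        if "negative" in metric.lower():
            a, b = np.abs(a), np.abs(b)
        if np.array_equal(a, b) and np.all(a == a[0]):
            u, p = a.size * b.size / 2.0, 1.0  # identical constant groups
        else:
            u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        out.append(
            StabilityComparison(
                metric=metric,
                mean_a=float(a.mean()),
                sd_a=float(a.std(ddof=1)),
                mean_b=float(b.mean()),
                sd_b=float(b.std(ddof=1)),
                statistic=float(u),
                p_value=float(p),
                stars=_stars(float(p)),
            )
        )
    return out
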