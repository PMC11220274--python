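"""Alpha/beta diversity, NMDS ordination and permutation tests.

Covers the community-comparison toolkit: richness/Chao1/Shannon per sample,
Jaccard and Bray–Curtis distance matrices, non-metric multidimensional
scaling, and the four permutation tests (PERMANOVA, ANOSIM, MRPP, Mantel)
used to ask whether two cropping regimes host different communities.

All permutation p-values follow the add-one (Phipson–Smyth) rule
``p = (1 + #extreme) / (1 + n_permutations)`` and therefore never return 0.
With ``n_perm="exhaustive"`` every distinct relabelling is enumerated and the
p-value is the exact fraction ``#extreme / #relabellings`` (the identity
labelling is part of the enumeration).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import squareform
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import smacof

__all__ = [
    "DistanceMatrix",
    "PermutationTestResult",
    "NMDSResult",
    "alpha_diversity",
    "beta_distance",
    "nmds",
    "permanova",
    "anosim",
    "mrpp",
    "mantel",
]


@dataclass
class DistanceMatrix:
    """Symmetric samples × samples dissimilarity matrix with zero diagonal."""

    sample_ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.sample_ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be exactly 0")
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.d, checks=False)


@dataclass
class PermutationTestResult:
    statistic_name: str
    observed: float
    n_permutations: int
    p_value: float
    seed: int | None
    exhaustive: bool = False


@dataclass
class NMDSResult:
    sample_ids: list[str]
    coordinates: np.ndarray
    stress: float
    n_starts: int
    seed: int


# ---------------------------------------------------------------------------
# Alpha diversity


def alpha_diversity(table) -> pd.DataFrame:
    """Per-sample richness, Chao1 and Shannon index.

    richness = number of taxa with count > 0; Chao1 = S_obs + F1²/(2 F2)
    (bias-corrected S_obs + F1(F1−1)/(2(F2+1)) when no doubletons exist);
    Shannon = −Σ p_i ln p_i over non-zero proportions (natural log).
    Chao1 requires integer counts (it reasons about singletons/doubletons).
    """
    counts = table.counts
    if np.any(counts.sum(axis=0) == 0):
        j = int(np.argmax(counts.sum(axis=0) == 0))
        raise ValueError(f"sample {table.sample_ids[j]!r} is empty; diversity undefined")
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("chao1 requires integer counts")
    rows = []
    for j, sample in enumerate(table.sample_ids):
        col = counts[:, j]
        present = col[col > 0]
        s_obs = present.size
        f1 = int((present == 1).sum())
        f2 = int((present == 2).sum())
        if f2 > 0:
            chao1 = s_obs + f1 * f1 / (2.0 * f2)
        else:
            chao1 = s_obs + f1 * (f1 - 1) / 2.0  # bias-corrected, F2 = 0
        p = present / present.sum()
        shannon = float(-(p * np.log(p)).sum())
        rows.append(
            {"sample_id": sample, "richness": s_obs, "chao1": chao1, "shannon": shannon}
        )
    return pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# Beta diversity


def beta_distance(
    table, metric: Literal["jaccard", "bray_curtis"] = "jaccard"
) -> DistanceMatrix:
    """Pairwise sample dissimilarity.

    ``jaccard`` uses presence/absence: 1 − |A∩B| / |A∪B|.  ``bray_curtis``
    uses counts: Σ|x−y| / Σ(x+y).  A pair of all-zero samples has no defined
    dissimilarity and raises.
    """
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    x = table.counts.T  # samples × taxa
    n = x.shape[0]
    d = np.zeros((n, n))
    if metric == "jaccard":
        pres = x > 0
        for i in range(n):
            for j in range(i + 1, n):
                union = np.logical_or(pres[i], pres[j]).sum()
                if union == 0:
                    raise ValueError(
                        f"samples {table.sample_ids[i]!r} and {table.sample_ids[j]!r} "
                        "are both empty; Jaccard undefined"
                    )
                inter = np.logical_and(pres[i], pres[j]).sum()
                d[i, j] = d[j, i] = 1.0 - inter / union
    elif metric == "bray_curtis":
        for i in range(n):
            for j in range(i + 1, n):
                denom = (x[i] + x[j]).sum()
                if denom == 0:
                    raise ValueError(
                        f"samples {table.sample_ids[i]!r} and {table.sample_ids[j]!r} "
                        "are both empty; Bray-Curtis undefined"
                    )
                d[i, j] = d[j, i] = np.abs(x[i] - x[j]).sum() / denom
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(sample_ids=list(table.sample_ids), d=d)


# ---------------------------------------------------------------------------
# NMDS


def kruskal_stress1(d: np.ndarray, coords: np.ndarray) -> float:
    """Kruskal stress-1 of an embedding against target dissimilarities.

    Disparities come from isotonic (monotone) regression of embedded distances
    on dissimilarities with the primary (averaging) treatment of ties.
    """
    iu = np.triu_indices(d.shape[0], k=1)
    diss = d[iu]
    emb = np.sqrt(((coords[iu[0]] - coords[iu[1]]) ** 2).sum(axis=1))
    disp = IsotonicRegression().fit_transform(diss, emb)
    denom = float((emb**2).sum())
    if denom == 0:
        return 0.0
    return float(np.sqrt(((emb - disp) ** 2).sum() / denom))


def nmds(
    dm: DistanceMatrix,
    k: int = 2,
    n_starts: int = 4,
    max_iter: int = 300,
    seed: int = 0,
) -> NMDSResult:
    """Non-metric multidimensional scaling minimising Kruskal stress-1.

    Runs ``n_starts`` SMACOF initialisations and keeps the embedding with the
    lowest stress-1 (recomputed via isotonic regression, so the reported value
    does not depend on the optimiser's internal normalisation).
    """
    if k >= dm.n_samples:
        raise ValueError("embedding dimension must be below the number of samples")
    if k < 1:
        raise ValueError("k must be ≥ 1")
    rng = np.random.default_rng(seed)
    best_coords, best_stress = None, np.inf
    for _ in range(max(1, n_starts)):
        coords, _ = smacof(
            dm.d,
            metric=False,
            n_components=k,
            n_init=1,
            max_iter=max_iter,
            random_state=int(rng.integers(0, 2**31 - 1)),
            normalized_stress=True,
        )
        stress = kruskal_stress1(dm.d, coords)
        if stress < best_stress:
            best_stress, best_coords = stress, coords
    return NMDSResult(
        sample_ids=list(dm.sample_ids),
        coordinates=best_coords,
        stress=float(best_stress),
        n_starts=n_starts,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Permutation machinery


def _group_indices(groups: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    labels = sorted(set(groups))
    codes = np.array([labels.index(g) for g in groups], int)
    return codes, labels


def _check_groups(dm: DistanceMatrix, groups: Sequence[str]) -> np.ndarray:
    if len(groups) != dm.n_samples:
        raise ValueError("one group label per sample required")
    codes, labels = _group_indices(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    sizes = np.bincount(codes)
    if np.any(sizes < 2):
        small = labels[int(np.argmin(sizes))]
        raise ValueError(f"group {small!r} has fewer than 2 samples")
    return codes

def _distinct_labelings(codes: np.ndarray):
    """All distinct assignments of the multiset of labels to positions."""
    seen = set()
    for perm in permutations(codes.tolist()):
        if perm not in seen:
            seen.add(perm)
            yield np.array(perm, int)


def _permutation_pvalue(
    observed: float,
    statistic,
    codes: np.ndarray,
    n_perm,
    seed: int | None,
    tail: Literal["upper", "lower"],
) -> tuple[float, int, bool]:
    """Shared permutation engine for the group-label tests."""
    if n_perm == "exhaustive":
        vals = np.array([statistic(lab) for lab in _distinct_labelings(codes)])
        if tail == "upper":
            extreme = int((vals >= observed - 1e-12).sum())
        else:
            extreme = int((vals <= observed + 1e-12).sum())
        return extreme / vals.size, int(vals.size), True
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(int(n_perm)):
        lab = rng.permutation(codes)
        v = statistic(lab)
        if tail == "upper" and v >= observed - 1e-12:
            count += 1
        elif tail == "lower" and v <= observed + 1e-12:
            count += 1
    return (1 + count) / (1 + int(n_perm)), int(n_perm), False


# ---------------------------------------------------------------------------
# PERMANOVA


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """Anderson's pseudo-F from squared distances.

    SS_total = Σ_{i<j} d²_ij / N; SS_within = Σ_g Σ_{i<j∈g} d²_ij / n_g;
    F = (SS_between/(a−1)) / (SS_within/(N−a)).
    """
    n = codes.size
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, k=1)].sum() / idx.size
    ss_between = ss_total - ss_within
    a = n_groups
    denom = ss_within / (n - a)
    if denom == 0:
        return np.inf if ss_between > 0 else 0.0
    return (ss_between / (a - 1)) / denom


def permanova(
    dm: DistanceMatrix,
    groups: Sequence[str],
    n_perm: int | str = 999,
    seed: int = 0,
) -> PermutationTestResult:
    """Permutational multivariate analysis of variance (one-way)."""
    codes = _check_groups(dm, groups)
    a = codes.max() + 1
    d2 = dm.d**2
    obs = _pseudo_f(d2, codes, a)
    p, n_used, exhaustive = _permutation_pvalue(
        obs, lambda lab: _pseudo_f(d2, lab, a), codes, n_perm, seed, "upper"
    )
    return PermutationTestResult("PERMANOVA-pseudoF", float(obs), n_used, p, seed, exhaustive)


# ---------------------------------------------------------------------------
# ANOSIM


def anosim(
    dm: DistanceMatrix,
    groups: Sequence[str],
    n_perm: int | str = 999,
    seed: int = 0,
) -> PermutationTestResult:
    """Analysis of similarities: rank-based between/within separation R ∈ [−1, 1]."""
    codes = _check_groups(dm, groups)
    n = codes.size
    iu = np.triu_indices(n, k=1)
    ranks = stats.rankdata(dm.d[iu])
    denom = n * (n - 1) / 4.0

    def statistic(lab: np.ndarray) -> float:
        within = lab[iu[0]] == lab[iu[1]]
        return (ranks[~within].mean() - ranks[within].mean()) / denom

    obs = statistic(codes)
    p, n_used, exhaustive = _permutation_pvalue(
        obs, statistic, codes, n_perm, seed, "upper"
    )
    return PermutationTestResult("ANOSIM-R", float(obs), n_used, p, seed, exhaustive)


# ---------------------------------------------------------------------------
# MRPP


def mrpp(
    dm: DistanceMatrix,
    groups: Sequence[str],
    n_perm: int | str = 999,
    seed: int = 0,
) -> PermutationTestResult:
    """Multi-response permutation procedure.

    δ = Σ_g (n_g/N) × mean within-group distance; small δ means cohesive
    groups, so the permutation p-value is lower-tailed.  The chance-corrected
    effect size A = 1 − δ_obs/mean(δ_perm) is reported as the statistic.
    """
    codes = _check_groups(dm, groups)
    n = codes.size
    n_groups = codes.max() + 1

    def delta(lab: np.ndarray) -> float:
        val = 0.0
        for g in range(n_groups):
            idx = np.flatnonzero(lab == g)
            sub = dm.d[np.ix_(idx, idx)]
            pairs = sub[np.triu_indices(idx.size, k=1)]
            val += (idx.size / n) * pairs.mean()
        return val

    obs_delta = delta(codes)
    if n_perm == "exhaustive":
        deltas = np.array([delta(lab) for lab in _distinct_labelings(codes)])
        p = float((deltas <= obs_delta + 1e-12).sum() / deltas.size)
        n_used, exhaustive = int(deltas.size), True
        mean_perm = float(deltas.mean())
    else:
        rng = np.random.default_rng(seed)
        deltas = np.array(
            [delta(rng.permutation(codes)) for _ in range(int(n_perm))]
        )
        p = float((1 + (deltas <= obs_delta + 1e-12).sum()) / (1 + int(n_perm)))
        n_used, exhaustive = int(n_perm), False
        mean_perm = float(deltas.mean())
    a_stat = 1.0 - obs_delta / mean_perm if mean_perm > 0 else 0.0
    return PermutationTestResult("MRPP-A", float(a_stat), n_used, p, seed, exhaustive)


# ---------------------------------------------------------------------------
# Mantel


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    method: Literal["pearson", "spearman"] = "pearson",
    n_perm: int | str = 999,
    seed: int = 0,
) -> PermutationTestResult:
    """Mantel correlation between two distance matrices over the same samples.

    The p-value permutes rows and columns of the second matrix simultaneously
    (preserving its internal structure) and is upper-tailed on r.
    """
    if d1.sample_ids != d2.sample_ids:
        raise ValueError("distance matrices must share the same samples in order")
    n = d1.n_samples
    iu = np.triu_indices(n, k=1)
    v1 = d1.d[iu]

    if method == "spearman":
        v1r = stats.rankdata(v1)
    elif method == "pearson":
        v1r = v1
    else:
        raise ValueError(f"unknown method {method!r}")

    def corr(mat: np.ndarray) -> float:
        v2 = mat[iu]
        if method == "spearman":
            v2 = stats.rankdata(v2)
        if v1r.std() == 0 or np.std(v2) == 0:
            raise ValueError("constant distance vector; Mantel r undefined")
        return float(np.corrcoef(v1r, v2)[0, 1])

    obs = corr(d2.d)
    if n_perm == "exhaustive":
        vals = []
        for perm in permutations(range(n)):
            idx = np.array(perm)
            vals.append(corr(d2.d[np.ix_(idx, idx)]))
        vals = np.array(vals)
        p = float((vals >= obs - 1e-12).sum() / vals.size)
        n_used, exhaustive = int(vals.size), True
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(int(n_perm)):
            idx = rng.permutation(n)
            if corr(d2.d[np.ix_(idx, idx)]) >= obs - 1e-12:
                count += 1
        p = float((1 + count) / (1 + int(n_perm)))
        n_used, exhaustive = int(n_perm), False
    return PermutationTestResult("Mantel-r", float(obs), n_used, p, seed, exhaustive)
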