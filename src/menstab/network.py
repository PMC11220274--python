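"""Co-occurrence network inference with random-matrix-theory thresholding.

Pipeline: Spearman rank correlation between all taxon pairs → scan candidate
similarity thresholds → pick the lowest threshold at which the
nearest-neighbour spacing distribution (NNSD) of the thresholded matrix's
unfolded eigenvalues turns Poisson (uncorrelated) rather than GOE
(Wigner–Dyson) → keep every pair with |r| at or above that threshold as a
signed edge.

The GOE→Poisson transition is the classical random-matrix diagnostic: a
correlation matrix dominated by noise has level repulsion (Wigner surmise
``P(d) = (πd/2) exp(−πd²/4)``), while a matrix reduced to independent
modules has uncorrelated eigenvalues (``P(d) = exp(−d)``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats
from scipy.interpolate import PchipInterpolator

__all__ = [
    "CorrelationMatrix",
    "ThresholdScanResult",
    "SignedNetwork",
    "spearman_matrix",
    "rmt_threshold_scan",
    "build_network",
    "positive_edge_fraction",
    "nnsd_statistics",
]


@dataclass
class CorrelationMatrix:
    """Symmetric taxa × taxa rank-correlation matrix with unit diagonal."""

    taxa_ids: list[str]
    r: np.ndarray
    n_samples_used: int

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        n = len(self.taxa_ids)
        if self.r.shape != (n, n):
            raise ValueError("correlation matrix shape mismatch")
        if not np.allclose(self.r, self.r.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if np.any(np.abs(self.r) > 1 + 1e-10):
            raise ValueError("correlation entries must lie in [-1, 1]")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-10):
            raise ValueError("correlation diagonal must equal 1")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa_ids)


@dataclass
class ThresholdScanRecord:
    threshold: float
    n_retained_taxa: int
    n_spacings: int
    nnsd_chi2: float
    nnsd_p: float
    fits_poisson: bool


@dataclass
class ThresholdScanResult:
    """Per-threshold NNSD records plus the selected similarity threshold."""

    grid: list[float]
    records: list[ThresholdScanRecord]
    selected_threshold: float

    def to_rows(self) -> list[dict]:
        return [
            {
                "threshold": rec.threshold,
                "n_retained_taxa": rec.n_retained_taxa,
                "n_spacings": rec.n_spacings,
                "nnsd_chi2": rec.nnsd_chi2,
                "nnsd_p": rec.nnsd_p,
                "fits_poisson": rec.fits_poisson,
                "selected": rec.threshold == self.selected_threshold,
            }
            for rec in self.records
        ]


@dataclass
class SignedNetwork:
    """Undirected co-occurrence graph; every edge carries sign and |r| weight."""

    graph: nx.Graph
    threshold_used: float = 0.0

    def __post_init__(self) -> None:
        if any(u == v for u, v in self.graph.edges):
            raise ValueError("signed network must not contain self-edges")
        self.graph.graph["threshold_used"] = self.threshold_used

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_links(self) -> int:
        return self.graph.number_of_edges()

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def edge_signs(self) -> np.ndarray:
        return np.array([d["sign"] for _, _, d in self.graph.edges(data=True)], int)


def spearman_matrix(table, normalize: bool = True) -> CorrelationMatrix:
    """Tie-corrected Spearman correlation between every pair of taxa.

    Constant taxa (zero variance across samples) have no defined rank
    correlation; they are excluded with a warning before computing the matrix.
    By default correlations are computed on relative abundances, the
    convention for sequencing count tables; at uniform sequencing depth the
    normalisation leaves every cross-sample rank unchanged.  For data that is
    already on an abundance scale (not closed compositions) pass
    ``normalize=False`` to correlate the raw values.
    """
    if table.n_samples < 4:
        raise ValueError("need at least 4 samples for a usable correlation matrix")
    from .tables import relative_abundance

    rel = relative_abundance(table) if normalize else table
    variances = rel.counts.var(axis=1)
    constant = variances == 0
    if constant.any():
        dropped = [t for t, c in zip(rel.taxa_ids, constant) if c]
        warnings.warn(
            f"excluding {len(dropped)} constant taxa from correlation "
            f"(first: {dropped[0]!r})",
            stacklevel=2,
        )
        rel = rel.select_taxa(~constant)
    if rel.n_taxa < 2:
        raise ValueError("fewer than 2 non-constant taxa; no correlations to compute")
    # rank-then-Pearson with average ranks == tie-corrected Spearman
    ranks = np.apply_along_axis(stats.rankdata, 1, rel.counts)
    r = np.corrcoef(ranks)
    np.fill_diagonal(r, 1.0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    return CorrelationMatrix(
        taxa_ids=list(rel.taxa_ids), r=r, n_samples_used=table.n_samples
    )


# ---------------------------------------------------------------------------
# RMT machinery


def _unfold_eigenvalues(eigs: np.ndarray, bins_per_100: int = 10) -> np.ndarray:
    """Map eigenvalues to uniform density via a smooth monotone fit of the
    cumulative spectral distribution.

    Numerically equal eigenvalues are collapsed beforehand; the staircase
    cumulative count is smoothed with a monotone cubic (PCHIP) through binned
    quantile knots (10 knots per 100 eigenvalues), and each eigenvalue is
    mapped to the fitted cumulative count.
    """
    eigs = np.sort(eigs)
    # collapse degeneracies
    uniq = [eigs[0]]
    for e in eigs[1:]:
        if e - uniq[-1] > 1e-8:
            uniq.append(e)
    uniq = np.asarray(uniq)
    n = uniq.size
    if n < 5:
        raise ValueError("too few distinct eigenvalues to unfold")
    cum = np.arange(1, n + 1, dtype=float)
    n_knots = max(4, int(round(bins_per_100 * n / 100.0)))
    knot_idx = np.unique(
        np.round(np.linspace(0, n - 1, n_knots)).astype(int)
    )
    fit = PchipInterpolator(uniq[knot_idx], cum[knot_idx])
    return np.asarray(fit(uniq))


def nnsd_statistics(
    eigs: np.ndarray,
    bin_width: float = 0.5,
    max_spacing: float = 3.0,
    min_expected: float = 5.0,
) -> tuple[float, float, int]:
    """Chi-square goodness of fit of unfolded eigenvalue spacings against the
    Poisson form ``P(d) = exp(−d)``.

    Returns ``(chi2, p, n_spacings)``.  Spacings are normalised to unit mean,
    histogrammed in ``bin_width`` bins on ``[0, max_spacing]`` (with a final
    open bin to infinity), and adjacent bins are pooled until every expected
    count reaches ``min_expected``.
    """
    unfolded = _unfold_eigenvalues(np.asarray(eigs, dtype=float))
    spacings = np.diff(unfolded)
    spacings = spacings[spacings > 0]
    if spacings.size < 10:
        raise ValueError("too few spacings for a goodness-of-fit test")
    spacings = spacings / spacings.mean()

    edges = list(np.arange(0.0, max_spacing + bin_width / 2, bin_width)) + [np.inf]
    observed, _ = np.histogram(spacings, bins=edges)
    # Poisson(1) spacing CDF: 1 - exp(-d)
    cdf = np.array([1.0 - np.exp(-e) if np.isfinite(e) else 1.0 for e in edges])
    expected = np.diff(cdf) * spacings.size

    obs_pooled, exp_pooled = [], []
    o_acc = e_acc = 0.0
    for o, e in zip(observed, expected):
        o_acc += o
        e_acc += e
        if e_acc >= min_expected:
            obs_pooled.append(o_acc)
            exp_pooled.append(e_acc)
            o_acc = e_acc = 0.0
    if o_acc or e_acc:
        if exp_pooled:
            obs_pooled[-1] += o_acc
            exp_pooled[-1] += e_acc
        else:
            obs_pooled, exp_pooled = [o_acc], [e_acc]
    obs_arr = np.asarray(obs_pooled, float)
    exp_arr = np.asarray(exp_pooled, float)
    if obs_arr.size < 2:
        raise ValueError("spacing histogram degenerate after pooling")
    exp_arr *= obs_arr.sum() / exp_arr.sum()
    chi2 = float(((obs_arr - exp_arr) ** 2 / exp_arr).sum())
    dof = obs_arr.size - 1
    p = float(stats.chi2.sf(chi2, dof))
    return chi2, p, int(spacings.size)


def _thresholded_submatrix(r: np.ndarray, s: float) -> np.ndarray:
    """Zero |r| < s off the diagonal and drop rows/columns left with no
    off-diagonal entry."""
    m = r.copy()
    off = np.abs(m) < s
    np.fill_diagonal(off, False)
    m[off] = 0.0
    mask = np.abs(m) >= s
    np.fill_diagonal(mask, False)
    keep = mask.any(axis=1)
    return m[np.ix_(keep, keep)]


def rmt_threshold_scan(
    c: CorrelationMatrix,
    grid: np.ndarray | None = None,
    alpha: float = 0.05,
    min_taxa: int = 50,
    min_eigenvalues: int = 30,
    rejection_tolerance: float = 0.2,
) -> ThresholdScanResult:
    """Scan similarity thresholds and select the GOE→Poisson transition point.

    For each candidate ``s``: entries with |r| < s are zeroed, empty
    rows/columns dropped, the spectrum of the retained matrix unfolded, and
    the NNSD tested against the Poisson form.  The selected threshold is the
    smallest ``s`` that fits Poisson (p > ``alpha``) and stays Poisson at the
    larger evaluable thresholds on the grid.  Because each goodness-of-fit
    test falsely rejects at rate ``alpha`` under the Poisson null, the
    stay-Poisson requirement tolerates a ``rejection_tolerance`` fraction of
    isolated rejections among the larger thresholds; thresholds retaining
    fewer than ``min_eigenvalues`` distinct eigenvalues cannot be tested and
    do not veto the run.
    """
    if grid is None:
        grid = np.round(np.arange(0.30, 0.995, 0.01), 2)
    grid = np.sort(np.asarray(grid, dtype=float))
    if c.n_taxa < min_taxa:
        warnings.warn(
            f"only {c.n_taxa} taxa (< {min_taxa}); RMT spectrum unreliable — "
            "consider a fixed threshold override",
            stacklevel=2,
        )
    records: list[ThresholdScanRecord] = []
    for s in grid:
        sub = _thresholded_submatrix(c.r, s)
        n_kept = sub.shape[0]
        if n_kept < min_eigenvalues:
            records.append(ThresholdScanRecord(float(s), n_kept, 0, np.nan, np.nan, False))
            continue
        eigs = np.linalg.eigvalsh(sub)
        try:
            chi2, p, n_sp = nnsd_statistics(eigs)
        except ValueError:
            records.append(ThresholdScanRecord(float(s), n_kept, 0, np.nan, np.nan, False))
            continue
        records.append(
            ThresholdScanRecord(float(s), n_kept, n_sp, chi2, p, bool(p > alpha))
        )

    evaluable = [rec for rec in records if rec.n_spacings > 0]
    selected = None
    for i, rec in enumerate(evaluable):
        tail = evaluable[i:]
        n_reject = sum(not r2.fits_poisson for r2 in tail)
        if rec.fits_poisson and n_reject <= rejection_tolerance * len(tail):
            selected = rec.threshold
            break
    if selected is None:
        raise RuntimeError(
            "no threshold on the grid yields a Poisson nearest-neighbour spacing "
            "distribution; widen the grid or provide more taxa"
        )
    return ThresholdScanResult(
        grid=[float(s) for s in grid], records=records, selected_threshold=selected
    )


def build_network(c: CorrelationMatrix, s: float) -> SignedNetwork:
    """Threshold the correlation matrix into a signed undirected graph.

    An edge joins every taxon pair with |r| ≥ s; its sign is the sign of r and
    its weight |r|.  Taxa left without any edge are dropped, so every retained
    node has degree ≥ 1.
    """
    if not 0.0 < s < 1.0:
        raise ValueError("similarity threshold must lie in (0, 1)")
    g = nx.Graph()
    n = c.n_taxa
    iu, ju = np.triu_indices(n, k=1)
    vals = c.r[iu, ju]
    hits = np.abs(vals) >= s
    for i, j, v in zip(iu[hits], ju[hits], vals[hits]):
        g.add_edge(
            c.taxa_ids[i],
            c.taxa_ids[j],
            sign=int(np.sign(v)) if v != 0 else 1,
            weight=float(abs(v)),
        )
    return SignedNetwork(graph=g, threshold_used=float(s))


def positive_edge_fraction(net: SignedNetwork) -> float:
    """Fraction of edges with positive correlation sign."""
    if net.n_links == 0:
        raise ValueError("network has no edges; positive-edge fraction undefined")
    signs = net.edge_signs()
    return float((signs > 0).sum() / signs.size)
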