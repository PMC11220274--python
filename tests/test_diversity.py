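"""Diversity indices, distances, NMDS, and the four permutation tests.

The permutation tests are checked against brute-force oracles that
re-enumerate every labelling and recompute the statistic from first
principles, and (where available) against scikit-bio's implementations.
"""

from itertools import permutations

import numpy as np
import pytest
from scipy import stats

import menstab as m

from conftest import make_table


class TestAlphaDiversity:
    def test_even_two_taxon_sample(self):
        t = make_table([[10], [10]])
        row = m.alpha_diversity(t).loc["s1"]
        assert row["richness"] == 2
        assert row["shannon"] == pytest.approx(np.log(2))

    def test_chao1_direct_formula(self):
        # counts [1,1,2]: F1=2, F2=1 → chao1 = 3 + 4/2 = 5
        t = make_table([[1], [1], [2]])
        assert m.alpha_diversity(t).loc["s1", "chao1"] == pytest.approx(5.0)

    def test_chao1_bias_corrected_when_no_doubletons(self):
        # counts [1,1,5]: F1=2, F2=0 → 3 + 2*1/2 = 4
        t = make_table([[1], [1], [5]])
        assert m.alpha_diversity(t).loc["s1", "chao1"] == pytest.approx(4.0)

    def test_single_taxon_shannon_zero(self):
        t = make_table([[5]])
        assert m.alpha_diversity(t).loc["s1", "shannon"] == 0.0

    def test_empty_sample_errors(self):
        t = make_table([[1, 0], [2, 0]])
        with pytest.raises(ValueError, match="s2"):
            m.alpha_diversity(t)


class TestBetaDistance:
    def test_jaccard_hand_value(self):
        # {t1,t2} vs {t2,t3}: 1 − 1/3
        t = make_table([[1, 0], [1, 1], [0, 1]])
        d = m.beta_distance(t, "jaccard")
        assert d.d[0, 1] == pytest.approx(2 / 3)

    def test_bray_curtis_disjoint_is_one(self):
        t = make_table([[1, 0], [0, 1]])
        assert m.beta_distance(t, "bray_curtis").d[0, 1] == 1.0

    def test_identical_samples_zero(self):
        t = make_table([[3, 3], [1, 1]])
        for metric in ("jaccard", "bray_curtis"):
            assert m.beta_distance(t, metric).d[0, 1] == 0.0

    def test_bounds_symmetry_diagonal(self, grouped_table):
        for metric in ("jaccard", "bray_curtis"):
            dm = m.beta_distance(grouped_table, metric)
            assert np.all(dm.d >= 0) and np.all(dm.d <= 1)
            np.testing.assert_allclose(dm.d, dm.d.T, atol=1e-15)
            assert np.all(np.diag(dm.d) == 0)

    def test_matches_scipy_pdist(self, grouped_table):
        from scipy.spatial.distance import pdist, squareform

        dm = m.beta_distance(grouped_table, "bray_curtis")
        ref = squareform(pdist(grouped_table.counts.T, metric="braycurtis"))
        np.testing.assert_allclose(dm.d, ref, atol=1e-12)

    def test_two_empty_samples_error(self):
        t = make_table([[1, 0, 0], [2, 0, 0]])
        with pytest.raises(ValueError, match="undefined|empty"):
            m.beta_distance(t, "jaccard")


class TestNMDS:
    def test_planar_configuration_low_stress(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(6, 2))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        dm = m.DistanceMatrix([f"s{i}" for i in range(6)], d)
        res = m.nmds(dm, k=2, n_starts=8, seed=0)
        assert res.stress < 0.01

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(7, 3))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        dm = m.DistanceMatrix([f"s{i}" for i in range(7)], d)
        r1 = m.nmds(dm, seed=5)
        r2 = m.nmds(dm, seed=5)
        np.testing.assert_array_equal(r1.coordinates, r2.coordinates)
        assert r1.stress == r2.stress

    def test_k_too_large_errors(self):
        dm = m.DistanceMatrix(["a", "b", "c"], 1 - np.eye(3))
        with pytest.raises(ValueError, match="dimension"):
            m.nmds(dm, k=3)


# ---------------------------------------------------------------------------
# Brute-force oracles (independent implementations)


def oracle_pseudo_f(d, labels):
    labels = np.asarray(labels)
    n = len(labels)
    groups = sorted(set(labels.tolist()))
    ss_total = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for g in groups:
        idx = [i for i in range(n) if labels[i] == g]
        ss_g = sum(d[i, j] ** 2 for i in idx for j in idx if i < j)
        ss_within += ss_g / len(idx)
    a = len(groups)
    return ((ss_total - ss_within) / (a - 1)) / (ss_within / (n - a))


def oracle_anosim_r(d, labels):
    labels = np.asarray(labels)
    n = len(labels)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    ranks = stats.rankdata([d[i, j] for i, j in pairs])
    within = [r for r, (i, j) in zip(ranks, pairs) if labels[i] == labels[j]]
    between = [r for r, (i, j) in zip(ranks, pairs) if labels[i] != labels[j]]
    return (np.mean(between) - np.mean(within)) / (n * (n - 1) / 4)


def oracle_mrpp_delta(d, labels):
    labels = np.asarray(labels)
    n = len(labels)
    delta = 0.0
    for g in sorted(set(labels.tolist())):
        idx = [i for i in range(n) if labels[i] == g]
        pair_d = [d[i, j] for i in idx for j in idx if i < j]
        delta += (len(idx) / n) * np.mean(pair_d)
    return delta


def two_cluster_distance(seed=0, n_per=3, sep=10.0):
    rng = np.random.default_rng(seed)
    pts = np.vstack(
        [rng.normal(0, 1, (n_per, 2)), rng.normal(sep, 1, (n_per, 2))]
    )
    d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
    ids = [f"s{i}" for i in range(2 * n_per)]
    labels = ["A"] * n_per + ["B"] * n_per
    return m.DistanceMatrix(ids, d), labels


class TestPermanova:
    def test_exhaustive_two_cluster_p(self):
        dm, labels = two_cluster_distance()
        res = m.permanova(dm, labels, n_perm="exhaustive")
        # all C(6,3)=20 assignments; observed and its mirror are maximal
        assert res.n_permutations == 20
        assert res.p_value == pytest.approx(2 / 20)
        assert res.observed == pytest.approx(oracle_pseudo_f(dm.d, labels))

    def test_exhaustive_matches_oracle_everywhere(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(6, 2))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        dm = m.DistanceMatrix([f"s{i}" for i in range(6)], d)
        labels = ["A", "A", "A", "B", "B", "B"]
        res = m.permanova(dm, labels, n_perm="exhaustive")
        stats_all = {
            oracle_pseudo_f(d, perm)
            for perm in set(permutations(labels))
        }
        count = sum(
            1
            for perm in set(permutations(labels))
            if oracle_pseudo_f(d, perm) >= res.observed - 1e-12
        )
        assert res.p_value == pytest.approx(count / 20)
        assert len(stats_all) > 1

    def test_matches_scikit_bio(self):
        pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix as SkbioDM
        from skbio.stats.distance import permanova as skbio_permanova

        dm, labels = two_cluster_distance(seed=2)
        ours = m.permanova(dm, labels, n_perm=999, seed=0)
        theirs = skbio_permanova(SkbioDM(dm.d, ids=dm.sample_ids), labels)
        assert ours.observed == pytest.approx(theirs["test statistic"], rel=1e-10)

    def test_equal_distances_degenerate(self):
        d = 1 - np.eye(6)
        dm = m.DistanceMatrix([f"s{i}" for i in range(6)], d)
        res = m.permanova(dm, ["A"] * 3 + ["B"] * 3, n_perm="exhaustive")
        assert np.isfinite(res.observed)
        assert res.p_value == 1.0

    def test_group_of_one_errors(self):
        dm, _ = two_cluster_distance()
        with pytest.raises(ValueError, match="fewer than 2"):
            m.permanova(dm, ["A"] * 5 + ["B"], n_perm=99)


class TestAnosim:
    def test_perfect_separation_r_one(self):
        dm, labels = two_cluster_distance(sep=100.0)
        res = m.anosim(dm, labels, n_perm=99, seed=0)
        assert res.observed == pytest.approx(1.0)

    def test_matches_oracle_on_four_samples(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(4, 2))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        dm = m.DistanceMatrix(["a", "b", "c", "d"], d)
        labels = ["A", "A", "B", "B"]
        res = m.anosim(dm, labels, n_perm="exhaustive")
        assert res.observed == pytest.approx(oracle_anosim_r(d, labels), abs=1e-12)

    def test_matches_scikit_bio(self):
        pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix as SkbioDM
        from skbio.stats.distance import anosim as skbio_anosim

        dm, labels = two_cluster_distance(seed=5)
        ours = m.anosim(dm, labels, n_perm=99, seed=0)
        theirs = skbio_anosim(SkbioDM(dm.d, ids=dm.sample_ids), labels)
        assert ours.observed == pytest.approx(theirs["test statistic"], rel=1e-10)

    def test_null_mean_r_near_zero(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(8, 2))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        dm = m.DistanceMatrix([f"s{i}" for i in range(8)], d)
        vals = []
        for _ in range(50):
            labels = rng.permutation(["A"] * 4 + ["B"] * 4).tolist()
            vals.append(m.anosim(dm, labels, n_perm=9, seed=1).observed)
        assert abs(np.mean(vals)) < 0.1


class TestMrpp:
    def test_tight_clusters_significant(self):
        dm, labels = two_cluster_distance(sep=50.0)
        res = m.mrpp(dm, labels, n_perm="exhaustive")
        assert res.observed > 0  # chance-corrected A
        assert res.p_value == pytest.approx(2 / 20)  # minimal under enumeration

    def test_delta_hand_computation(self):
        d = np.array(
            [
                [0.0, 1.0, 4.0, 5.0],
                [1.0, 0.0, 6.0, 7.0],
                [4.0, 6.0, 0.0, 2.0],
                [5.0, 7.0, 2.0, 0.0],
            ]
        )
        dm = m.DistanceMatrix(["a", "b", "c", "d"], d)
        labels = ["A", "A", "B", "B"]
        # delta = 0.5*1 + 0.5*2 = 1.5
        assert oracle_mrpp_delta(d, labels) == pytest.approx(1.5)
        res = m.mrpp(dm, labels, n_perm="exhaustive")
        deltas = [
            oracle_mrpp_delta(d, perm) for perm in sorted(set(permutations(labels)))
        ]
        expected_p = np.mean([dd <= 1.5 + 1e-12 for dd in deltas])
        assert res.p_value == pytest.approx(expected_p)

    def test_null_expectation_a_near_zero(self):
        rng = np.random.default_rng(13)
        pts = rng.normal(size=(8, 2))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        dm = m.DistanceMatrix([f"s{i}" for i in range(8)], d)
        vals = [
            m.mrpp(dm, rng.permutation(["A"] * 4 + ["B"] * 4).tolist(),
                   n_perm=49, seed=i).observed
            for i in range(30)
        ]
        assert abs(np.mean(vals)) < 0.1


class TestMantel:
    def test_identity_r_one(self):
        rng = np.random.default_rng(17)
        pts = rng.normal(size=(6, 2))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        dm = m.DistanceMatrix([f"s{i}" for i in range(6)], d)
        res = m.mantel(dm, dm, n_perm=99, seed=0)
        assert res.observed == pytest.approx(1.0)

    def test_scale_invariance_pearson(self):
        rng = np.random.default_rng(19)
        pts = rng.normal(size=(6, 2))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        d1 = m.DistanceMatrix([f"s{i}" for i in range(6)], d)
        d2 = m.DistanceMatrix([f"s{i}" for i in range(6)], 3.0 * d)
        res = m.mantel(d1, d2, method="pearson", n_perm=99, seed=0)
        assert res.observed == pytest.approx(1.0)

    def test_matches_scikit_bio(self):
        pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix as SkbioDM, mantel as sk_mantel

        rng = np.random.default_rng(23)
        a = rng.random((6, 6))
        b = rng.random((6, 6))
        a = (a + a.T) / 2; np.fill_diagonal(a, 0)
        b = (b + b.T) / 2; np.fill_diagonal(b, 0)
        ids = [f"s{i}" for i in range(6)]
        ours = m.mantel(
            m.DistanceMatrix(ids, a), m.DistanceMatrix(ids, b), n_perm=99, seed=0
        )
        r, _, _ = sk_mantel(SkbioDM(a, ids=ids), SkbioDM(b, ids=ids),
                            permutations=0)
        assert ours.observed == pytest.approx(r, rel=1e-10)

    def test_mismatched_samples_error(self):
        d1 = m.DistanceMatrix(["a", "b", "c"], 1 - np.eye(3))
        d2 = m.DistanceMatrix(["a", "b", "x"], 1 - np.eye(3))
        with pytest.raises(ValueError, match="same samples"):
            m.mantel(d1, d2)


class TestPValueContract:
    def test_add_one_rule_never_zero(self):
        dm, labels = two_cluster_distance(sep=100.0)
        for fn in (m.permanova, m.anosim, m.mrpp):
            res = fn(dm, labels, n_perm=99, seed=0)
            assert res.p_value >= 1 / 100
            assert 0 < res.p_value <= 1
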