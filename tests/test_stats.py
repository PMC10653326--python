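"""Ordination and permutation statistics against hand values and oracles."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest
import scipy.stats as ss
from skbio import DistanceMatrix
from skbio.stats.distance import mantel as skbio_mantel

from metacomm.stats import (
    bray_curtis,
    kruskal_wallis,
    mantel,
    n_distinct_arrangements,
    partial_correlation,
    partial_mantel,
    pcoa,
    permanova,
    stage_dendrogram,
    t_test,
    taxon_trends,
    upgma_linkage,
)
from .conftest import random_counts


class TestBrayCurtis:
    def test_identical_samples_distance_zero(self):
        t = pd.DataFrame({"a": [3, 1], "b": [3, 1]})
        assert bray_curtis(t)["a", "b"] == 0.0

    def test_disjoint_samples_distance_one(self):
        t = pd.DataFrame({"a": [3, 0], "b": [0, 5]})
        assert bray_curtis(t)["a", "b"] == 1.0

    def test_hand_example(self):
        t = pd.DataFrame({"a": [6, 0, 2], "b": [2, 2, 0]})
        assert bray_curtis(t)["a", "b"] == pytest.approx(8 / 12)

    def test_zero_total_sample_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis(pd.DataFrame({"a": [1, 0], "b": [0, 0]}))


class TestPcoa:
    def test_two_points(self):
        d = DistanceMatrix([[0, 0.8], [0.8, 0]], ids=["a", "b"])
        res = pcoa(d)
        coords = res.samples.iloc[:, 0].to_numpy()
        assert np.abs(coords) == pytest.approx([0.4, 0.4])

    def test_euclidean_round_trip(self, rng):
        pts = rng.normal(size=(6, 2))
        from scipy.spatial.distance import pdist, squareform

        d = DistanceMatrix(squareform(pdist(pts)), ids=[str(i) for i in range(6)])
        res = pcoa(d)
        rec = res.samples.to_numpy()[:, :2]
        d_rec = squareform(pdist(rec))
        assert d_rec == pytest.approx(squareform(pdist(pts)), abs=1e-9)

    def test_positive_eigenvalues_sum_to_centered_trace(self, rng):
        # Euclidean distances -> centered matrix is PSD, so positive
        # eigenvalues account for the whole trace
        from scipy.spatial.distance import pdist, squareform

        pts = rng.normal(size=(5, 3))
        d = DistanceMatrix(squareform(pdist(pts)), ids=[str(i) for i in range(5)])
        res = pcoa(d)
        m = np.asarray(d.data) ** 2
        j = np.eye(5) - np.ones((5, 5)) / 5
        centered = -0.5 * j @ m @ j
        pos = res.eigvals[res.eigvals > 1e-12]
        assert pos.sum() == pytest.approx(np.trace(centered), abs=1e-9)


def _permanova_oracle(d2, labels):
    """Independent pseudo-F: sums of squared distances per group."""
    n = len(labels)
    sst = sum(d2[i, j] for i in range(n) for j in range(i + 1, n)) / n
    ssw = 0.0
    for g in set(labels):
        idx = [i for i, l in enumerate(labels) if l == g]
        ssw += sum(d2[i, j] for i in idx for j in idx if i < j) / len(idx)
    a = len(set(labels))
    return ((sst - ssw) / (a - 1)) / (ssw / (n - a))


class TestPermanova:
    def test_exhaustive_p_matches_complete_enumeration(self, rng):
        # 6 samples, 2 groups of 3 -> 20 distinct arrangements
        t = random_counts(rng, n_taxa=8, n_samples=6)
        d = bray_curtis(t)
        labels = ["A", "A", "A", "B", "B", "B"]
        res = permanova(d, labels, exhaustive=True)
        assert res.n_permutations == n_distinct_arrangements([3, 3]) == 20
        d2 = np.asarray(d.data) ** 2
        f_obs = _permanova_oracle(d2, labels)
        assert res.statistic == pytest.approx(f_obs, abs=1e-9)
        seen, hits = set(), 0
        for perm in permutations(range(6)):
            key = tuple(labels[i] for i in perm)
            if key in seen:
                continue
            seen.add(key)
            hits += _permanova_oracle(d2, list(key)) >= f_obs - 1e-12
        assert res.p_value == pytest.approx(hits / 20)

    def test_separated_clusters_reach_minimum_p(self):
        # groups large enough that a random label shuffle essentially never
        # reproduces the two-cluster split
        x = np.concatenate([np.arange(8) * 0.1, 10 + np.arange(8) * 0.1])[:, None]
        from scipy.spatial.distance import pdist, squareform

        d = DistanceMatrix(squareform(pdist(x)), ids=[str(i) for i in range(16)])
        res = permanova(d, ["A"] * 8 + ["B"] * 8, n_perm=99, seed=0)
        assert res.p_value == pytest.approx(1 / 100)

    def test_euclidean_f_matches_centroid_formulation(self, rng):
        # for Euclidean distances, PERMANOVA pseudo-F equals classic one-way
        # MANOVA-style F computed from centroids
        pts = rng.normal(size=(9, 3))
        labels = ["A"] * 3 + ["B"] * 3 + ["C"] * 3
        from scipy.spatial.distance import pdist, squareform

        d = DistanceMatrix(squareform(pdist(pts)), ids=[str(i) for i in range(9)])
        res = permanova(d, labels, n_perm=9, seed=0)
        grand = pts.mean(axis=0)
        ss_total = ((pts - grand) ** 2).sum()
        ssw = 0.0
        for g in "ABC":
            sub = pts[[i for i, l in enumerate(labels) if l == g]]
            ssw += ((sub - sub.mean(axis=0)) ** 2).sum()
        f = ((ss_total - ssw) / 2) / (ssw / 6)
        assert res.statistic == pytest.approx(f, abs=1e-9)

    def test_single_sample_group_rejected(self, rng):
        t = random_counts(rng, n_samples=5)
        with pytest.raises(ValueError):
            permanova(bray_curtis(t), ["A", "A", "A", "A", "B"])


class TestMantel:
    def _pair(self, rng, n=8):
        from scipy.spatial.distance import pdist, squareform

        a = squareform(pdist(rng.normal(size=(n, 2))))
        b = squareform(pdist(rng.normal(size=(n, 2))))
        ids = [str(i) for i in range(n)]
        return DistanceMatrix(a, ids=ids), DistanceMatrix(b, ids=ids)

    def test_self_correlation_is_one(self, rng):
        d1, _ = self._pair(rng)
        assert mantel(d1, d1, n_perm=9, seed=0).statistic == pytest.approx(1.0)

    def test_affine_transform_correlation_is_one(self, rng):
        d1, _ = self._pair(rng)
        d2 = DistanceMatrix(2.5 * np.asarray(d1.data), ids=d1.ids)
        assert mantel(d1, d2, n_perm=9, seed=0).statistic == pytest.approx(1.0)

    def test_r_agrees_with_skbio(self, rng):
        d1, d2 = self._pair(rng)
        r_ours = mantel(d1, d2, n_perm=99, seed=0).statistic
        r_ref, _, _ = skbio_mantel(d1, d2, permutations=0)
        assert r_ours == pytest.approx(float(r_ref), abs=1e-12)

    def test_partial_correlation_closed_form(self, rng):
        d1, d2 = self._pair(rng)
        _, dc = self._pair(rng)
        iu = np.triu_indices(8, 1)
        v1, v2, vc = (np.asarray(m.data)[iu] for m in (d1, d2, dc))
        r12 = np.corrcoef(v1, v2)[0, 1]
        r13 = np.corrcoef(v1, vc)[0, 1]
        r23 = np.corrcoef(v2, vc)[0, 1]
        expected = (r12 - r13 * r23) / np.sqrt((1 - r13**2) * (1 - r23**2))
        assert partial_correlation(r12, r13, r23) == pytest.approx(expected)
        res = partial_mantel(d1, d2, dc, n_perm=49, seed=1)
        assert res.statistic == pytest.approx(expected, abs=1e-12)

    def test_id_mismatch_rejected(self, rng):
        d1, d2 = self._pair(rng)
        d2b = DistanceMatrix(np.asarray(d2.data), ids=list(reversed(d2.ids)))
        with pytest.raises(ValueError):
            mantel(d1, d2b)

    def test_p_values_never_zero(self, rng):
        d1, d2 = self._pair(rng)
        _, dc = self._pair(rng)
        for res in (mantel(d1, d2, n_perm=99, seed=0),
                    partial_mantel(d1, d2, dc, n_perm=99, seed=0)):
            assert res.p_value >= 1 / 100


class TestUnivariate:
    def test_kruskal_identical_groups(self):
        res = kruskal_wallis([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(0.0)

    def test_kruskal_degenerate_all_equal(self):
        with pytest.warns(UserWarning):
            res = kruskal_wallis([5, 5], [5, 5, 5])
        assert res.p_value == 1.0

    def test_kruskal_matches_rank_based_recomputation(self, rng):
        groups = [rng.normal(size=4) for _ in range(3)]
        res = kruskal_wallis(*groups)
        pooled = np.concatenate(groups)
        ranks = ss.rankdata(pooled)
        n = len(pooled)
        start, h = 0, 0.0
        for g in groups:
            r = ranks[start:start + len(g)]
            h += r.sum() ** 2 / len(g)
            start += len(g)
        h = 12 / (n * (n + 1)) * h - 3 * (n + 1)
        # no ties in normal draws -> no tie correction
        assert res.statistic == pytest.approx(h, abs=1e-9)

    def test_t_test_identical_vectors(self):
        res = t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_t_test_welch_matches_scipy(self, rng):
        x, y = rng.normal(size=6), rng.normal(1, 2, size=8)
        res = t_test(x, y)
        t_ref, p_ref = ss.ttest_ind(x, y, equal_var=False)
        assert res.statistic == pytest.approx(float(t_ref))
        assert res.p_value == pytest.approx(float(p_ref))


class TestTaxonTrends:
    def test_proportional_taxon_has_r_one(self):
        days = [10, 20, 30, 40]
        table = pd.DataFrame(
            {f"S{i}": [d, 100 - d] for i, d in enumerate(days)}, index=["up", "down"])
        res = taxon_trends(table, days)
        assert res.loc["up", "r"] == pytest.approx(1.0)
        assert res.loc["down", "r"] == pytest.approx(-1.0)

    def test_bh_step_up_hand_case(self):
        # four p-values 0.01..0.04 with m=4 all adjust to 0.04
        from statsmodels.stats.multitest import multipletests

        q = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_constant_taxon_flagged(self):
        table = pd.DataFrame({"S1": [5, 5], "S2": [7, 7], "S3": [3, 3]},
                             index=["flat", "alsoflat"])
        res = taxon_trends(table, [10, 20, 30])
        assert res["constant"].all()
        assert (res["r"] == 0).all() and (res["p"] == 1).all()

    def test_null_data_fdr_control(self, rng):
        # no true trends: BH discoveries at q<0.05 should stay near/below 5%
        discoveries, total = 0, 0
        for _ in range(60):
            table = random_counts(rng, n_taxa=20, n_samples=9, total=2_000)
            res = taxon_trends(table, [10, 10, 10, 20, 20, 20, 30, 30, 30])
            discoveries += int(res["significant"].sum())
            total += len(res)
        assert discoveries / total <= 0.05

    def test_too_few_days_rejected(self, rng):
        with pytest.raises(ValueError):
            taxon_trends(random_counts(rng, n_samples=4), [10, 10, 20, 20])


class TestStageDendrogram:
    def _epoch_distance(self):
        # three well-separated epochs of three timepoints each
        pts = np.concatenate([np.full(3, 0.0), np.full(3, 5.0), np.full(3, 11.0)])
        pts = pts + np.linspace(0, 0.3, 9)
        from scipy.spatial.distance import pdist, squareform

        return DistanceMatrix(squareform(pdist(pts[:, None])),
                              ids=[f"d{k}" for k in range(9)])

    def test_k_equals_n_gives_singletons(self):
        d = self._epoch_distance()
        out = stage_dendrogram(d, k=9)
        assert out.nunique() == 9

    def test_planted_epochs_recovered(self):
        d = self._epoch_distance()
        out = stage_dendrogram(d, k=3)
        assert list(out) == [1, 1, 1, 2, 2, 2, 3, 3, 3]

    def test_upgma_merge_heights_nondecreasing(self, rng):
        t = random_counts(rng, n_taxa=10, n_samples=7)
        link = upgma_linkage(bray_curtis(t))
        heights = link[:, 2]
        assert (np.diff(heights) >= -1e-12).all()

    def test_invalid_k_rejected(self):
        d = self._epoch_distance()
        with pytest.raises(ValueError):
            stage_dendrogram(d, k=0)
        with pytest.raises(ValueError):
            stage_dendrogram(d, k=10)
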