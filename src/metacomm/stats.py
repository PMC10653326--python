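"""Distance-based ordination and permutation statistics.

Bray-Curtis dissimilarity, PCoA, PERMANOVA (with an exhaustive small-sample
mode), Mantel and partial Mantel tests, Kruskal-Wallis / Welch t tests,
FDR-corrected per-taxon temporal trends, and the UPGMA dendrogram used to
split the culture period into stages.

All permutation p-values follow the (1 + more-extreme) / (1 + n_perm)
convention and therefore never reach zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations as _iter_perms
from math import comb

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats as ss
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa
from statsmodels.stats.multitest import multipletests


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n_permutations: int
    method: str


# ---------------------------------------------------------------------------
# distances & ordination


def bray_curtis(table: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples (columns) of a count table."""
    if table.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    mat = table.to_numpy(dtype=float).T
    if np.any(mat.sum(axis=1) <= 0):
        bad = [s for s in table.columns if table[s].sum() <= 0]
        raise ValueError(f"zero-total sample(s): {bad}")
    return DistanceMatrix(squareform(pdist(mat, metric="braycurtis")),
                          ids=[str(c) for c in table.columns])


def pcoa(d: DistanceMatrix):
    """Principal coordinates analysis (Gower-centred eigen-decomposition).

    Returns a scikit-bio ``OrdinationResults`` with sample coordinates,
    eigenvalues and proportion of (positive) variance explained per axis.
    """
    return _skbio_pcoa(d, method="eigh")


# ---------------------------------------------------------------------------
# PERMANOVA


def _permanova_f(d2: np.ndarray, labels: np.ndarray) -> float:
    """Pseudo-F from squared distances and integer group labels."""
    n = len(labels)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    n_groups = 0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        n_groups += 1
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    df_among = n_groups - 1
    df_within = n - n_groups
    return (ss_among / df_among) / (ss_within / df_within)


def permanova(
    d: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int = 0,
    exhaustive: bool = False,
) -> TestResult:
    """Permutational multivariate ANOVA on a distance matrix.

    Pseudo-F is computed directly from among/within sums of squared
    distances; the null shuffles group labels freely.  With
    ``exhaustive=True`` every distinct label arrangement is enumerated and
    the p-value is the exact fraction of arrangements with F >= F_observed
    (the identity arrangement included).
    """
    labels = pd.Series(list(groups)).astype("category").cat.codes.to_numpy()
    _, counts = np.unique(labels, return_counts=True)
    if len(counts) < 2 or counts.min() < 2:
        raise ValueError("permanova needs >=2 groups with >=2 samples each")
    d2 = np.asarray(d.data) ** 2
    f_obs = _permanova_f(d2, labels)
    if exhaustive:
        n = len(labels)
        seen = set()
        hits = total = 0
        for perm in _iter_perms(range(n)):
            key = tuple(labels[list(perm)])
            if key in seen:
                continue
            seen.add(key)
            total += 1
            if _permanova_f(d2, np.array(key)) >= f_obs - 1e-12:
                hits += 1
        return TestResult(f_obs, hits / total, total, "permanova-exhaustive")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        hits += _permanova_f(d2, rng.permutation(labels)) >= f_obs
    return TestResult(f_obs, (1 + hits) / (1 + n_perm), n_perm, "permanova")


def n_distinct_arrangements(group_sizes) -> int:
    """Number of distinct label arrangements (multinomial coefficient)."""
    total, out = sum(group_sizes), 1
    for k in group_sizes:
        out *= comb(total, k)
        total -= k
    return out


# ---------------------------------------------------------------------------
# Mantel


def _upper(m: np.ndarray) -> np.ndarray:
    return m[np.triu_indices(m.shape[0], 1)]


def _check_aligned(*ds: DistanceMatrix) -> list[np.ndarray]:
    ids = ds[0].ids
    for d in ds[1:]:
        if tuple(d.ids) != tuple(ids):
            raise ValueError("distance matrices have mismatched ids/order")
    return [np.asarray(d.data) for d in ds]


def mantel(d1: DistanceMatrix, d2: DistanceMatrix, n_perm: int = 999, seed: int = 0) -> TestResult:
    """Mantel test: Pearson correlation of the two upper triangles.

    Significance from jointly permuting rows/columns of ``d1``.
    """
    m1, m2 = _check_aligned(d1, d2)
    r_obs = float(np.corrcoef(_upper(m1), _upper(m2))[0, 1])
    rng = np.random.default_rng(seed)
    v2 = _upper(m2)
    hits = 0
    n = m1.shape[0]
    for _ in range(n_perm):
        p = rng.permutation(n)
        r = np.corrcoef(_upper(m1[np.ix_(p, p)]), v2)[0, 1]
        hits += abs(r) >= abs(r_obs) - 1e-12
    return TestResult(r_obs, (1 + hits) / (1 + n_perm), n_perm, "mantel")


def partial_correlation(r12: float, r13: float, r23: float) -> float:
    """First-order partial correlation of 1 and 2 controlling for 3."""
    den = np.sqrt((1 - r13**2) * (1 - r23**2))
    return (r12 - r13 * r23) / den


def partial_mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    d_control: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
) -> TestResult:
    """Partial Mantel test of d1 vs d2 controlling for a third matrix."""
    m1, m2, mc = _check_aligned(d1, d2, d_control)
    v2, vc = _upper(m2), _upper(mc)

    def pr(v1):
        r12 = np.corrcoef(v1, v2)[0, 1]
        r13 = np.corrcoef(v1, vc)[0, 1]
        r23 = np.corrcoef(v2, vc)[0, 1]
        return partial_correlation(r12, r13, r23)

    r_obs = float(pr(_upper(m1)))
    rng = np.random.default_rng(seed)
    n = m1.shape[0]
    hits = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        hits += abs(pr(_upper(m1[np.ix_(p, p)]))) >= abs(r_obs) - 1e-12
    return TestResult(r_obs, (1 + hits) / (1 + n_perm), n_perm, "partial-mantel")


# ---------------------------------------------------------------------------
# univariate tests


def kruskal_wallis(*groups) -> TestResult:
    """Kruskal-Wallis H (tie-corrected) with chi-square p-value."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size == 0 for a in arrays):
        raise ValueError("need >=2 non-empty groups")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        import warnings

        warnings.warn("all values identical across groups; H=0, p=1")
        return TestResult(0.0, 1.0, 0, "kruskal-wallis")
    h, p = ss.kruskal(*arrays)
    return TestResult(float(h), float(p), 0, "kruskal-wallis")


def t_test(x, y, equal_var: bool = False) -> TestResult:
    """Two-sided t test; Welch (unequal variances) by default."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("t_test needs >=2 values per group")
    if np.array_equal(x, y):
        return TestResult(0.0, 1.0, 0, "t-test")
    t, p = ss.ttest_ind(x, y, equal_var=equal_var)
    return TestResult(float(t), float(p), 0, "t-test")


# ---------------------------------------------------------------------------
# taxon trends


def taxon_trends(table: pd.DataFrame, days) -> pd.DataFrame:
    """Per-taxon Pearson trend of relative abundance against culture day.

    Returns a frame indexed by taxon with columns r, p, q (Benjamini-
    Hochberg), ``significant`` (q < 0.05) and ``constant`` flags.  A taxon
    with constant relative abundance has an undefined correlation and is
    reported as r=0, p=1 with the ``constant`` flag set.
    """
    day_v = np.asarray(pd.Series(list(days)), dtype=float)
    if len(np.unique(day_v)) < 3:
        raise ValueError("taxon_trends needs >=3 distinct days")
    rel = table.to_numpy(dtype=float)
    rel = rel / rel.sum(axis=0, keepdims=True)
    rows = []
    for i, taxon in enumerate(table.index):
        y = rel[i]
        if np.allclose(y, y[0]):
            rows.append((taxon, 0.0, 1.0, True))
            continue
        r, p = ss.pearsonr(day_v, y)
        rows.append((taxon, float(r), float(p), False))
    out = pd.DataFrame(rows, columns=["taxon", "r", "p", "constant"]).set_index("taxon")
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = out["q"] < 0.05
    return out


# ---------------------------------------------------------------------------
# stage dendrogram


def stage_dendrogram(d: DistanceMatrix, k: int) -> pd.Series:
    """UPGMA clustering of timepoint-mean communities cut into ``k`` stages.

    Returns a timepoint -> cluster-label series (labels 1..k, renumbered in
    order of first appearance).  Temporal contiguity is not enforced.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(d.ids)
    if k > n:
        raise ValueError("k exceeds the number of timepoints")
    link = sch.linkage(squareform(np.asarray(d.data), checks=False), method="average")
    raw = sch.fcluster(link, t=k, criterion="maxclust")
    remap, nxt = {}, 1
    labels = []
    for c in raw:
        if c not in remap:
            remap[c] = nxt
            nxt += 1
        labels.append(remap[c])
    return pd.Series(labels, index=list(d.ids), name="stage")


def upgma_linkage(d: DistanceMatrix) -> np.ndarray:
    """Raw UPGMA linkage matrix (scipy format) for the timepoint communities."""
    return sch.linkage(squareform(np.asarray(d.data), checks=False), method="average")
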