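"""Phylogenetic-bin null models quantifying community assembly processes.

Taxa are partitioned into phylogenetic bins (average-linkage clustering of
patristic distances).  For every within-day pair of samples and every bin,
two null-standardized turnover metrics are computed:

* betaNRI — the standardized effect size of the abundance-weighted
  between-community mean pairwise phylogenetic distance (betaMPD) against a
  null that shuffles taxon identities across the bin's tips;
* RC (Raup-Crick) — Bray-Curtis turnover ranked against null communities
  that preserve each sample's within-bin richness and total abundance while
  drawing taxa by regional occurrence frequency.

Each pair-bin is classified into one of five processes: betaNRI > +1.96 ->
heterogeneous selection (HeS); betaNRI < -1.96 -> homogeneous selection
(HoS); otherwise RC > +0.95 -> dispersal limitation (DL); RC < -0.95 ->
homogenizing dispersal (HD); else drift (DR).  Bin-level labels are
aggregated to community-level process percentages with abundance weights,
and determinism (HeS + HoS) can be regressed on environmental covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats as ss
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

PROCESSES = ("HeS", "HoS", "DL", "HD", "DR")


# ---------------------------------------------------------------------------
# binning


def bin_taxa(
    labels: list[str],
    d_phylo: np.ndarray,
    ds_threshold: float | None = None,
    min_bin_size: int = 12,
) -> dict[int, list[str]]:
    """Partition taxa into phylogenetic bins.

    Average-linkage clustering of the patristic distance matrix is cut at
    ``ds_threshold`` (default: 0.4 x the tree diameter, i.e. the largest
    pairwise distance); bins smaller than ``min_bin_size`` are merged into
    the phylogenetically nearest bin by mean inter-bin distance.  Bins must
    be coarse enough that selection acting on a clade remains a proper
    subset of its bin — within-bin nulls cannot see bin-level filtering —
    which is why the default cut is deliberately deep for trees of a few
    hundred tips.
    """
    n = len(labels)
    if min_bin_size < 3:
        raise ValueError("min_bin_size must be >= 3")
    if min_bin_size > n:
        raise ValueError("min_bin_size exceeds the number of taxa")
    d_phylo = np.asarray(d_phylo, dtype=float)
    if ds_threshold is None:
        ds_threshold = 0.4 * d_phylo.max()
    link = sch.linkage(squareform(d_phylo, checks=False), method="average")
    assign = sch.fcluster(link, t=ds_threshold, criterion="distance")
    bins: dict[int, list[int]] = {}
    for i, c in enumerate(assign):
        bins.setdefault(int(c), []).append(i)
    # merge undersized bins into the nearest (mean patristic distance) bin
    while len(bins) > 1:
        small = [b for b, members in bins.items() if len(members) < min_bin_size]
        if not small:
            break
        b = min(small, key=lambda k: len(bins[k]))
        others = [k for k in bins if k != b]
        dists = {
            k: d_phylo[np.ix_(bins[b], bins[k])].mean() for k in others
        }
        target = min(dists, key=dists.get)
        bins[target] = sorted(bins[target] + bins.pop(b))
    return {
        new_id: [labels[i] for i in members]
        for new_id, (_, members) in enumerate(sorted(bins.items()))
    }


# ---------------------------------------------------------------------------
# betaMPD / betaNRI


def beta_mpd(a: np.ndarray, b: np.ndarray, d_phylo: np.ndarray) -> float:
    """Abundance-weighted between-community mean pairwise phylogenetic distance.

    ``a`` and ``b`` are abundance vectors over the same taxon set;
    betaMPD = f_a' D f_b with f the within-vector relative abundances.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.sum() <= 0 or b.sum() <= 0:
        raise ValueError("both communities must have positive total abundance")
    fa, fb = a / a.sum(), b / b.sum()
    return float(fa @ np.asarray(d_phylo, dtype=float) @ fb)


def bnri(
    a: np.ndarray,
    b: np.ndarray,
    d_phylo: np.ndarray,
    n_null: int = 1000,
    seed: int = 0,
) -> float:
    """betaNRI: (observed betaMPD - null mean) / null sd.

    The null shuffles taxon identities across the bin's tips, i.e. jointly
    permutes rows and columns of the bin's patristic distance matrix.
    Degenerate nulls (sd = 0) return 0.
    """
    rng = np.random.default_rng(seed)
    obs = beta_mpd(a, b, d_phylo)
    fa = np.asarray(a, float) / np.sum(a)
    fb = np.asarray(b, float) / np.sum(b)
    d = np.asarray(d_phylo, dtype=float)
    n = d.shape[0]
    nulls = np.empty(n_null)
    for k in range(n_null):
        perm = rng.permutation(n)
        nulls[k] = fa[perm] @ d @ fb[perm]
    sd = nulls.std(ddof=1)
    if sd <= 1e-12 * max(1.0, abs(nulls.mean())):
        logger.warning("bnri: degenerate null (sd~0); returning 0")
        return 0.0
    return float((obs - nulls.mean()) / sd)


# ---------------------------------------------------------------------------
# Raup-Crick


def _gumbel_topk(rng, log_w: np.ndarray, k: int, n_draws: int) -> np.ndarray:
    """``n_draws`` weighted samples of k distinct indices (Gumbel top-k trick)."""
    noise = rng.gumbel(size=(n_draws, log_w.size))
    keys = log_w[None, :] + noise
    return np.argpartition(-keys, k - 1, axis=1)[:, :k]


def null_bin_communities(
    sample: np.ndarray,
    freq: np.ndarray,
    mean_ab: np.ndarray,
    n_null: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Null within-bin communities preserving richness and total abundance.

    Taxa are drawn without replacement with probability proportional to the
    regional occurrence frequency ``freq``; drawn taxa receive abundance
    proportional to the regional mean abundance ``mean_ab``, rescaled to the
    sample's within-bin total.  Returns an (n_null, n_bin_taxa) array.
    """
    sample = np.asarray(sample, dtype=float)
    b = sample.size
    k = int((sample > 0).sum())
    total = sample.sum()
    candidates = np.flatnonzero(freq > 0)
    k = min(k, candidates.size)
    out = np.zeros((n_null, b))
    if k == 0 or total <= 0:
        return out
    log_w = np.full(b, -np.inf)
    log_w[candidates] = np.log(freq[candidates])
    picks = _gumbel_topk(rng, log_w, k, n_null)
    vals = np.maximum(mean_ab[picks], 1e-12)
    vals = vals / vals.sum(axis=1, keepdims=True) * total
    np.put_along_axis(out, picks, vals, axis=1)
    return out


def _bray_curtis_pairs(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Bray-Curtis between two stacks of abundance vectors."""
    num = np.abs(x - y).sum(axis=-1)
    den = (x + y).sum(axis=-1)
    return np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)


def raup_crick_from_null(bc_obs: float, bc_null: np.ndarray) -> float:
    """RC = ((#{null < obs} + 0.5 #{null = obs}) / n_null) * 2 - 1, in [-1, 1]."""
    bc_null = np.asarray(bc_null, dtype=float)
    less = (bc_null < bc_obs - 1e-12).sum()
    equal = (np.abs(bc_null - bc_obs) <= 1e-12).sum()
    return float((less + 0.5 * equal) / bc_null.size * 2.0 - 1.0)


def rc_bray(
    a: np.ndarray,
    b: np.ndarray,
    freq: np.ndarray,
    mean_ab: np.ndarray,
    n_null: int = 1000,
    seed: int = 0,
) -> float:
    """Raup-Crick metric on Bray-Curtis turnover for one within-bin pair.

    ``freq`` and ``mean_ab`` describe the regional pool over the bin's taxa
    (occurrence frequency across all samples; mean relative abundance).
    Pairs where either sample has within-bin richness < 2 should be skipped
    by the caller; this function raises in that case.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if (a > 0).sum() < 2 or (b > 0).sum() < 2:
        raise ValueError("rc_bray needs within-bin richness >= 2 in both samples")
    rng = np.random.default_rng(seed)
    bc_obs = float(_bray_curtis_pairs(a, b))
    null_a = null_bin_communities(a, freq, mean_ab, n_null, rng)
    null_b = null_bin_communities(b, freq, mean_ab, n_null, rng)
    return raup_crick_from_null(bc_obs, _bray_curtis_pairs(null_a, null_b))


# ---------------------------------------------------------------------------
# classification & aggregation


def classify(bnri_value: float, rc_value: float | None,
             z_cut: float = 1.96, rc_cut: float = 0.95) -> str:
    """Five-process label from the two null-standardized metrics."""
    if not np.isfinite(bnri_value):
        raise ValueError("bnri must be finite")
    if bnri_value > z_cut:
        return "HeS"
    if bnri_value < -z_cut:
        return "HoS"
    if rc_value is None or not np.isfinite(rc_value):
        return "DR"
    if rc_value > rc_cut:
        return "DL"
    if rc_value < -rc_cut:
        return "HD"
    return "DR"


@dataclass
class AssemblyResult:
    """Per-pair-bin metrics plus aggregated per-day process percentages."""

    pair_bins: pd.DataFrame  # pair, day, bin, bnri, rc, label, weight
    percentages: pd.DataFrame = field(default_factory=pd.DataFrame)


def aggregate(pair_bins: pd.DataFrame, grouping: str = "day") -> pd.DataFrame:
    """Bin-weight-aggregated process percentages per group.

    Per pair, each process's fraction is the summed weight of bins carrying
    that label (weights renormalized over the pair's valid bins); per group
    the percentage is the mean over pairs x 100.  Adds determinism (HeS +
    HoS) and stochasticity (DL + HD + DR) columns.
    """
    rows = []
    for (grp, pair), sub in pair_bins.groupby([grouping, "pair"]):
        w = sub["weight"].to_numpy(dtype=float)
        if w.sum() <= 0:
            continue
        w = w / w.sum()
        frac = {p: float(w[(sub["label"] == p).to_numpy()].sum()) for p in PROCESSES}
        rows.append({grouping: grp, "pair": pair, **frac})
    if not rows:
        return pd.DataFrame()
    per_pair = pd.DataFrame(rows)
    out = per_pair.groupby(grouping)[list(PROCESSES)].mean() * 100.0
    out["determinism"] = out["HeS"] + out["HoS"]
    out["stochasticity"] = out["DL"] + out["HD"] + out["DR"]
    return out.reset_index()


def regress_determinism(determinism: pd.Series, env: pd.DataFrame) -> pd.DataFrame:
    """OLS of determinism % on each environmental factor separately.

    ``determinism`` is indexed by group (day); ``env`` rows are aligned on
    the same index.  Constant factors are skipped with a warning.
    """
    if len(determinism) < 3:
        raise ValueError("need >=3 groups for regression")
    common = determinism.index.intersection(env.index)
    y = determinism.loc[common].to_numpy(dtype=float)
    rows = []
    for factor in env.columns:
        x = env.loc[common, factor].to_numpy(dtype=float)
        if np.allclose(x, x[0]):
            logger.warning("factor %s is constant; skipped", factor)
            continue
        res = ss.linregress(x, y)
        rows.append({"factor": factor, "slope": res.slope, "intercept": res.intercept,
                     "r_squared": res.rvalue**2, "p": res.pvalue})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# end-to-end driver


def quantify_assembly(
    counts: pd.DataFrame,
    labels: list[str],
    d_phylo: np.ndarray,
    metadata: pd.DataFrame,
    ds_threshold: float | None = None,
    min_bin_size: int = 12,
    n_null: int = 1000,
    z_cut: float = 1.96,
    rc_cut: float = 0.95,
    seed: int = 0,
) -> AssemblyResult:
    """Full pipeline: bin taxa, score all within-day sample pairs, classify, aggregate.

    ``labels``/``d_phylo`` are the taxon order and patristic distance matrix
    (e.g. from :func:`metacomm.simulate.patristic_matrix`).  The null
    computations are vectorized per bin: one set of ``n_null`` taxon
    shuffles (betaNRI) and one set of null communities per sample (RC) is
    shared by all pairs in a day group.
    """
    rng = np.random.default_rng(seed)
    missing = [t for t in counts.index if t not in set(labels)]
    if missing:
        raise ValueError(f"taxa missing from the tree: {missing[:5]}...")
    counts = counts.loc[labels]
    mat = counts.to_numpy(dtype=float)
    rel = mat / np.maximum(mat.sum(axis=0, keepdims=True), 1e-300)
    sample_ids = list(counts.columns)
    sample_pos = {s: i for i, s in enumerate(sample_ids)}

    bins = bin_taxa(labels, d_phylo, ds_threshold=ds_threshold, min_bin_size=min_bin_size)
    label_pos = {t: i for i, t in enumerate(labels)}
    bin_idx = {b: np.array([label_pos[t] for t in taxa]) for b, taxa in bins.items()}

    # regional pool per bin: occurrence frequency and mean relative abundance
    occ = (mat > 0).mean(axis=1)
    mean_rel = rel.mean(axis=1)

    days = metadata.loc[[s for s in sample_ids], "day"]
    records = []
    for day, meta_sub in metadata.loc[sample_ids].groupby("day"):
        members = [s for s in meta_sub.index]
        if len(members) < 2:
            continue
        pairs = list(combinations(members, 2))
        pos = np.array([sample_pos[s] for s in members])
        pair_a = np.array([members.index(a) for a, _ in pairs])
        pair_b = np.array([members.index(b) for _, b in pairs])
        day_rel = rel[:, pos]  # taxa x members

        # per-pair bin weights: mean share of total abundance in each bin
        bin_share = {b: day_rel[idx].sum(axis=0) for b, idx in bin_idx.items()}

        for b, idx in bin_idx.items():
            d_bin = d_phylo[np.ix_(idx, idx)]
            sub = day_rel[idx]  # bin taxa x members
            totals = sub.sum(axis=0)
            valid = totals > 0
            f = np.zeros_like(sub)
            f[:, valid] = sub[:, valid] / totals[valid]
            f = f.T  # members x bin taxa

            # observed betaMPD for all pairs at once
            m_obs = f @ d_bin @ f.T
            obs = m_obs[pair_a, pair_b]

            # null: shared taxon shuffles
            nulls = np.empty((n_null, len(pairs)))
            for k in range(n_null):
                perm = rng.permutation(len(idx))
                g = f[:, np.argsort(perm)]  # equivalent to permuting D
                m = g @ d_bin @ g.T
                nulls[k] = m[pair_a, pair_b]
            mu, sd = nulls.mean(axis=0), nulls.std(axis=0, ddof=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                z = np.where(sd > 1e-12 * np.maximum(1.0, np.abs(mu)),
                             (obs - mu) / sd, 0.0)

            # RC nulls per member sample
            freq_b = occ[idx]
            mean_b = mean_rel[idx]
            nulls_rc = [
                null_bin_communities(sub[:, m_i], freq_b, mean_b, n_null, rng)
                for m_i in range(len(members))
            ]
            richness_b = (sub > 0).sum(axis=0)

            for p_i, (sa, sb) in enumerate(pairs):
                ia, ib = pair_a[p_i], pair_b[p_i]
                if not (valid[ia] and valid[ib]):
                    continue  # bin absent from one community
                weight = 0.5 * (bin_share[b][ia] + bin_share[b][ib])
                if richness_b[ia] >= 2 and richness_b[ib] >= 2:
                    bc_obs = float(_bray_curtis_pairs(sub[:, ia], sub[:, ib]))
                    bc_null = _bray_curtis_pairs(nulls_rc[ia], nulls_rc[ib])
                    rc_val = raup_crick_from_null(bc_obs, bc_null)
                else:
                    rc_val = np.nan
                lab = classify(float(z[p_i]), None if np.isnan(rc_val) else rc_val,
                               z_cut=z_cut, rc_cut=rc_cut)
                records.append({
                    "pair": f"{sa}|{sb}", "day": day, "bin": b,
                    "beta_mpd_obs": float(obs[p_i]), "bnri": float(z[p_i]),
                    "rc": rc_val, "label": lab, "weight": float(weight),
                })

    pair_bins = pd.DataFrame(records)
    percentages = aggregate(pair_bins) if not pair_bins.empty else pd.DataFrame()
    return AssemblyResult(pair_bins=pair_bins, percentages=percentages)
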