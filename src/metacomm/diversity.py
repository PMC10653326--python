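"""Alpha diversity, rarefaction, and multiscale Rao-entropy partitioning.

The centrepiece is the additive hierarchical decomposition of metacommunity
diversity within a culture stage,

    gamma_ecosystem = alpha_local + beta_intertemporal + beta_intratemporal,

where diversity is Rao's quadratic entropy Q = sum_ij d_ij p_i p_j.  With the
default taxonomic distance (d_ij = 1 for i != j) Q reduces to the
Gini-Simpson index; a phylogenetic patristic distance matrix (rescaled to a
maximum of 1) may be supplied instead.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def rarefy(table: pd.DataFrame, depth: int, seed: int) -> pd.DataFrame:
    """Subsample every sample (column) to exactly ``depth`` reads without replacement.

    Columns whose total is below ``depth`` are dropped with a logged warning.
    The draw is multivariate hypergeometric per sample, so a sample already
    at ``depth`` is returned unchanged.
    """
    if depth <= 0:
        raise ValueError("depth must be a positive integer")
    rng = np.random.default_rng(seed)
    kept = {}
    dropped = []
    for sid in table.columns:
        col = table[sid].to_numpy(dtype=np.int64)
        total = int(col.sum())
        if total < depth:
            dropped.append(sid)
            continue
        kept[sid] = rng.multivariate_hypergeometric(col, depth)
    if dropped:
        logger.warning(
            "rarefy: dropped %d sample(s) below depth %d: %s",
            len(dropped), depth, ", ".join(map(str, dropped)),
        )
    return pd.DataFrame(kept, index=table.index, dtype=np.int64)


def richness(sample: np.ndarray | pd.Series) -> int:
    """Number of taxa with count > 0."""
    v = np.asarray(sample)
    return int((v > 0).sum())


def chao1(sample: np.ndarray | pd.Series) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1-1) / (2(F2+1)).

    F1 and F2 are the singleton and doubleton counts; the bias-corrected
    form stays finite when there are no doubletons.
    """
    v = np.asarray(sample)
    s_obs = float((v > 0).sum())
    f1 = float((v == 1).sum())
    f2 = float((v == 2).sum())
    return s_obs + f1 * (f1 - 1.0) / (2.0 * (f2 + 1.0))


def shannon(sample: np.ndarray | pd.Series) -> float:
    """Shannon entropy H = -sum p_i ln p_i over positive-abundance taxa (nats)."""
    v = np.asarray(sample, dtype=float)
    v = v[v > 0]
    if v.size == 0:
        raise ValueError("shannon requires at least one positive count")
    p = v / v.sum()
    return float(-(p * np.log(p)).sum())


def rao_q(p: np.ndarray, d: np.ndarray | None = None) -> float:
    """Rao quadratic entropy Q = sum_ij d_ij p_i p_j.

    ``p`` is a relative-abundance vector (renormalized internally, with a
    warning if it is off unity by more than 1e-6).  ``d`` defaults to the
    taxonomic distance d_ij = 1 - delta_ij, for which Q equals Gini-Simpson.
    """
    p = np.asarray(p, dtype=float)
    total = p.sum()
    if total <= 0:
        raise ValueError("relative-abundance vector must have positive total")
    if abs(total - 1.0) > 1e-6:
        warnings.warn(f"rao_q: renormalizing abundance vector (sum={total:.6g})")
    p = p / total
    if d is None:
        return float(1.0 - (p**2).sum())
    d = np.asarray(d, dtype=float)
    if d.shape != (p.size, p.size):
        raise ValueError(f"distance matrix shape {d.shape} does not match {p.size} taxa")
    return float(p @ d @ p)


def scale_distance(d: np.ndarray) -> np.ndarray:
    """Rescale a distance matrix so the maximum off-diagonal entry is 1."""
    d = np.asarray(d, dtype=float)
    m = d.max()
    return d / m if m > 0 else d


@dataclass
class PartitionResult:
    """Additive Rao partition of one stage's metacommunity diversity.

    ``gamma`` is Q of the stage-pooled community; components satisfy
    ``alpha_local + beta_inter + beta_intra == gamma`` exactly (up to float
    round-off) and ``percentages`` expresses each component relative to
    gamma, summing to 100.
    """

    gamma: float
    alpha_local: float
    beta_inter: float
    beta_intra: float

    @property
    def percentages(self) -> dict[str, float]:
        if self.gamma == 0:
            return {"AlphaLoc%": 0.0, "BetaInter%": 0.0, "BetaIntra%": 0.0, "GammaReg%": 0.0}
        return {
            "GammaReg%": 100.0,
            "AlphaLoc%": 100.0 * self.alpha_local / self.gamma,
            "BetaInter%": 100.0 * self.beta_inter / self.gamma,
            "BetaIntra%": 100.0 * self.beta_intra / self.gamma,
        }


def partition_stage(
    table: pd.DataFrame,
    days: pd.Series | dict,
    d: np.ndarray | None = None,
    weights: str = "equal",
) -> PartitionResult:
    """Partition one stage's Rao diversity over timepoints and local communities.

    ``table`` holds the stage's local communities as columns (taxa as rows);
    ``days`` maps each sample to its timepoint.  Per timepoint t the pooled
    community is the mean of its local relative-abundance vectors, giving
    gamma_t and the local mean alpha_t; pooling timepoint means (equal
    timepoint weights by default, replicate-count weights with
    ``weights="abundance"``) gives the stage gamma.  Then

        alpha_local = weighted mean of alpha_t
        beta_intra  = weighted mean of (gamma_t - alpha_t)
        beta_inter  = gamma - weighted mean of gamma_t

    which sums to gamma by construction.
    """
    if weights not in ("equal", "abundance"):
        raise ValueError("weights must be 'equal' or 'abundance'")
    days = pd.Series(days)
    groups: dict[int, list[np.ndarray]] = {}
    for sid in table.columns:
        if sid not in days.index:
            raise ValueError(f"sample {sid!r} missing from day labels")
        col = table[sid].to_numpy(dtype=float)
        if col.sum() <= 0:
            raise ValueError(f"sample {sid!r} has zero total")
        groups.setdefault(int(days[sid]), []).append(col / col.sum())
    if len(groups) < 2:
        raise ValueError("partition_stage needs at least 2 timepoints")

    tps = sorted(groups)
    n_t = np.array([len(groups[t]) for t in tps], dtype=float)
    w = n_t / n_t.sum() if weights == "abundance" else np.full(len(tps), 1.0 / len(tps))

    gamma_t = np.empty(len(tps))
    alpha_t = np.empty(len(tps))
    pooled_t = []
    for k, t in enumerate(tps):
        locs = np.vstack(groups[t])
        p_t = locs.mean(axis=0)
        pooled_t.append(p_t)
        gamma_t[k] = rao_q(p_t, d)
        alpha_t[k] = float(np.mean([rao_q(p, d) for p in locs]))

    p_stage = np.tensordot(w, np.vstack(pooled_t), axes=1)
    gamma = rao_q(p_stage, d)
    alpha_local = float(w @ alpha_t)
    beta_intra = float(w @ (gamma_t - alpha_t))
    beta_inter = float(gamma - w @ gamma_t)
    return PartitionResult(gamma=gamma, alpha_local=alpha_local,
                           beta_inter=beta_inter, beta_intra=beta_intra)


def partition_by_stage(
    table: pd.DataFrame,
    metadata: pd.DataFrame,
    d: np.ndarray | None = None,
    weights: str = "equal",
) -> pd.DataFrame:
    """Run the Rao partition per (marker group, stage), Table-style output.

    Returns a tidy frame with one row per group x stage and the component
    percentages GammaReg%, AlphaLoc%, BetaInter%, BetaIntra%.
    """
    rows = []
    for (group, stage), meta_sub in metadata.groupby(["group", "stage"]):
        samples = [s for s in meta_sub.index if s in table.columns]
        if not samples:
            continue
        sub = table[samples]
        res = partition_stage(sub, metadata.loc[samples, "day"], d=d, weights=weights)
        rows.append({"group": group, "stage": stage, "gamma": res.gamma, **res.percentages})
    return pd.DataFrame(rows)
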