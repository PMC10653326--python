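"""Synthetic metacommunity generation under known assembly regimes.

Generates everything a downstream analysis needs — a zOTU-by-sample count
table, a rooted phylogeny, sample metadata (pond / day / stage), and
environmental covariate trajectories — for a multi-pond aquaculture-style
time series in which the true community assembly process is controlled.

The assembly model is a mainland–island metacommunity: each pond carries a
relative-abundance state vector that is updated at every timepoint by

1. migration from a regional pool (abundance-weighted mean of all ponds at
   the previous timepoint) at rate ``migration_rate``,
2. an optional Gaussian selection filter ``exp(-(trait - optimum)^2 / 2σ²)``
   acting on a trait evolved along the phylogeny by Brownian motion (so
   selection is phylogenetically structured), and
3. neutral demographic resampling of ``community_size`` individuals.

Sequencing is a multinomial draw per replicate sample at a lognormally
varying depth, so library sizes differ and rarefaction is meaningful.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REGIMES = (
    "homogeneous_selection",
    "heterogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "drift",
    "mixture",
)

#: day -> stage mapping used by the default 100-day design
DEFAULT_TIMEPOINTS = (10, 20, 30, 40, 50, 60, 70, 80, 100)


def stage_of_day(day: int) -> int:
    """Stage label for a culture day: 1 for days 10-30, 2 for 40-60, 3 for 70-100."""
    if day <= 30:
        return 1
    if day <= 60:
        return 2
    return 3


@dataclass
class SimulationConfig:
    """Parameters of one synthetic metacommunity run.

    ``regime_strength`` in [0, 1] controls the width of the Gaussian
    selection kernel (0 = no selection, i.e. pure drift; 1 = knife-edge
    filtering).  ``migration_rate`` in [0, 1] is the per-generation fraction
    of each pond replaced by the regional pool.
    """

    n_taxa: int = 150
    n_ponds: int = 4
    timepoints: Sequence[int] = DEFAULT_TIMEPOINTS
    replicates_per_pond: int = 3
    depth_mean: float = 45_000.0
    depth_cv: float = 0.03
    regime: str = "drift"
    regime_strength: float = 0.5
    migration_rate: float = 0.3
    community_size: int = 100_000
    marker: str = "16S"
    seed: int = 0

    def validate(self) -> None:
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        for name in ("n_ponds", "replicates_per_pond", "community_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        tps = list(self.timepoints)
        if not tps or any(b <= a for a, b in zip(tps, tps[1:])):
            raise ValueError("timepoints must be non-empty and strictly increasing")
        for name in ("regime_strength", "migration_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be within [0, 1]")
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}; choose from {REGIMES}")


@dataclass
class SyntheticDataset:
    """Bundle of generated data plus the ground truth used to create it."""

    counts: pd.DataFrame  # taxa x samples, integer counts
    tree: dendropy.Tree
    metadata: pd.DataFrame  # indexed by sample id: pond, day, stage, group
    env: pd.DataFrame  # indexed by day
    truth: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# phylogeny


def simulate_tree(n_taxa: int, seed: int) -> dendropy.Tree:
    """Random rooted binary tree with ``n_taxa`` uniquely labelled tips.

    Built by successive random coalescence of lineages; every branch gets a
    strictly positive exponential length.  Fully deterministic for a fixed
    ``(n_taxa, seed)`` pair, down to the newick string.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = np.random.default_rng(seed)
    width = len(str(n_taxa))
    subtrees = [f"t{i + 1:0{width}d}" for i in range(n_taxa)]
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        bl_i, bl_j = rng.exponential(0.1, size=2) + 1e-3
        merged = f"({subtrees[i]}:{bl_i:.6f},{subtrees[j]}:{bl_j:.6f})"
        subtrees[i] = merged
        del subtrees[j]
    newick = subtrees[0] + ";"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = True
    return tree


def patristic_matrix(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Tip labels (sorted) and the dense matrix of tip-to-tip path lengths."""
    labels = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    idx = {lab: k for k, lab in enumerate(labels)}
    n = len(labels)
    d = np.zeros((n, n))
    pdm = tree.phylogenetic_distance_matrix()
    for t1, t2 in pdm.distinct_taxon_pair_iter():
        i, j = idx[t1.label], idx[t2.label]
        d[i, j] = d[j, i] = pdm.patristic_distance(t1, t2)
    return labels, d


def evolve_traits(tree: dendropy.Tree, seed: int, n_traits: int = 25) -> pd.DataFrame:
    """Brownian-motion niche traits on the tree.

    Each of ``n_traits`` independent trait dimensions accumulates
    N(0, branch length) perturbations along every edge, so expected squared
    trait distance between two tips is proportional to their patristic
    distance.  Several dimensions are used because a single Brownian trait
    is noisy — unrelated tips often converge on similar values — whereas in
    a few dimensions trait proximity reliably implies phylogenetic
    proximity.  Rows are tip labels (sorted), columns trait dimensions.
    """
    rng = np.random.default_rng(seed)
    values: dict[int, np.ndarray] = {id(tree.seed_node): np.zeros(n_traits)}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        bl = node.edge.length or 0.0
        step = rng.normal(0.0, np.sqrt(max(bl, 1e-9)), size=n_traits)
        values[id(node)] = values[id(node.parent_node)] + step
    tips = {leaf.taxon.label: values[id(leaf)] for leaf in tree.leaf_node_iter()}
    return pd.DataFrame(tips).T.sort_index()


def evolve_trait(tree: dendropy.Tree, seed: int) -> pd.Series:
    """Single Brownian trait (first dimension of :func:`evolve_traits`)."""
    return evolve_traits(tree, seed, n_traits=1).iloc[:, 0]


# ---------------------------------------------------------------------------
# environment


ENV_TRENDS = {
    # covariate: (start, end, unit) over the culture period; negative slope = falling
    "TN": (0.5, 3.0, "mg/L"),
    "TP": (0.05, 0.35, "mg/L"),
    "ammonium": (0.05, 0.6, "mg/L"),
    "nitrite": (0.01, 0.25, "mg/L"),
    "nitrate": (0.05, 0.5, "mg/L"),
    "phosphate": (0.02, 0.25, "mg/L"),
    "silicate": (2.0, 0.4, "mg/L"),
    "salinity": (30.0, 31.0, "permille"),
    "pH": (8.4, 7.9, "pH"),
    "temperature": (22.0, 29.0, "degC"),
    "DO": (8.0, 6.0, "mg/L"),
    "chlorophyll": (2.0, 18.0, "ug/L"),
}


def simulate_env(timepoints: Sequence[int], seed: int, noise_scale: float = 0.05) -> pd.DataFrame:
    """Environmental covariate table over the culture days.

    Nutrient loads (TN, TP, phosphate, ammonium, nitrite, nitrate) rise
    linearly in expectation over the period while silicate falls, emulating
    intensive-aquaculture eutrophication; ``noise_scale`` is the additive
    Gaussian noise sd as a fraction of each covariate's total range.
    """
    tps = list(timepoints)
    if not tps:
        raise ValueError("timepoints must be non-empty")
    rng = np.random.default_rng(seed)
    span = max(tps) - min(tps) or 1
    frac = (np.asarray(tps, dtype=float) - min(tps)) / span
    cols = {}
    for name, (start, end, _unit) in ENV_TRENDS.items():
        base = start + (end - start) * frac
        noise = rng.normal(0.0, noise_scale * abs(end - start), size=len(tps))
        cols[name] = base + noise
    env = pd.DataFrame(cols, index=pd.Index(tps, name="day"))
    return env


# ---------------------------------------------------------------------------
# metacommunity assembly


def _selection_sigma2(strength: float, n_traits: int, patristic_diameter: float) -> float:
    """Squared trait-space kernel width for a regime strength in (0, 1].

    Because expected squared trait distance between tips equals n_traits x
    patristic distance under the Brownian model, a Gaussian kernel of
    squared width sigma2 acts (in expectation) like an exponential filter
    exp(-patristic / tau) with tau = 2 sigma2 / n_traits.  The width is set
    so that tau = 0.25 x tree diameter x ((1 - s) / s)^0.6: strength 0.9
    confines the favoured community to a small clade neighbourhood around
    the optimum, strength 0.5 to a broad clade, and strength -> 0 removes
    selection entirely (infinite width).
    """
    if strength <= 0.0:
        return np.inf
    tau = 0.25 * patristic_diameter * ((1.0 - strength) / strength) ** 0.6
    return 0.5 * n_traits * tau + 1e-12


def _regime_knobs(cfg: SimulationConfig) -> tuple[str, float]:
    """Map a named regime onto (selection mode, effective migration rate)."""
    if cfg.regime == "homogeneous_selection":
        return "shared", cfg.migration_rate
    if cfg.regime == "heterogeneous_selection":
        return "per_pond", cfg.migration_rate
    if cfg.regime == "dispersal_limitation":
        return "none", 1e-4
    if cfg.regime == "homogenizing_dispersal":
        return "none", 0.95
    if cfg.regime == "drift":
        return "none", cfg.migration_rate
    return "shared", cfg.migration_rate  # mixture: selection + free migration knob


def assemble_metacommunity(config: SimulationConfig) -> SyntheticDataset:
    """Simulate a full multi-pond time series under the configured regime.

    Returns counts (taxa x samples), the phylogeny the trait evolved on,
    per-sample metadata, the environment table, and a ``truth`` record with
    the regime, the trait values and the selection optima actually used.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    tree = simulate_tree(config.n_taxa, seed=config.seed)
    labels, d_phylo = patristic_matrix(tree)
    traits = evolve_traits(tree, seed=config.seed + 1).loc[labels].to_numpy()
    n_traits = traits.shape[1]

    env = simulate_env(config.timepoints, seed=config.seed + 2)
    sel_mode, migration = _regime_knobs(config)
    sigma2 = _selection_sigma2(config.regime_strength, n_traits, float(d_phylo.max()))

    # regional source pool: lognormal rank-abundance curve
    pool = rng.lognormal(0.0, 1.0, size=config.n_taxa)
    pool /= pool.sum()

    # Selection optima are anchored at real tips' trait vectors so that the
    # optimum always sits in a populated region of niche space.  The shared
    # optimum glides partway toward a distant anchor as the nutrient load
    # rises; per-pond optima (heterogeneous selection) are maximin-separated
    # tips so that ponds favour well-separated lineages.
    anchor0 = int(rng.integers(config.n_taxa))
    anchors = [anchor0]
    for _ in range(config.n_ponds):
        anchors.append(int(np.argmax(d_phylo[:, anchors].min(axis=1))))
    pond_anchor_ids = anchors[1:]
    tn = env["TN"].to_numpy()
    tn_frac = (tn - tn.min()) / (tn.max() - tn.min() + 1e-12)
    opt_start, opt_end = traits[anchor0], traits[anchors[1]]
    shared_optima = opt_start[None, :] + 0.3 * tn_frac[:, None] * (opt_end - opt_start)[None, :]
    pond_optima = traits[pond_anchor_ids]

    def _kernel(opt: np.ndarray) -> np.ndarray:
        if not np.isfinite(sigma2):
            return np.ones(config.n_taxa)
        dist2 = ((traits - opt[None, :]) ** 2).sum(axis=1)
        return np.exp(-dist2 / (2.0 * sigma2))

    state = np.tile(pool, (config.n_ponds, 1))
    counts_cols: dict[str, np.ndarray] = {}
    meta_rows = []
    for t_idx, day in enumerate(config.timepoints):
        regional = (state * state.sum(axis=1, keepdims=True)).sum(axis=0)
        regional /= regional.sum()
        new_state = np.empty_like(state)
        for pond in range(config.n_ponds):
            p = (1.0 - migration) * state[pond] + migration * regional
            if sel_mode != "none" and config.regime_strength > 0:
                # memoryless selection target: the kernel filters the baseline
                # pool (not the drifted state, which would compound the filter
                # across timepoints); regime_strength is both the kernel
                # tightness and the fraction of the community tracking it
                opt = shared_optima[t_idx] if sel_mode == "shared" else pond_optima[pond]
                target = pool * np.maximum(_kernel(opt), 1e-300)
                target = target / target.sum()
                s = config.regime_strength
                p = (1.0 - s) * p + s * target
            if p.sum() <= 0:
                p = np.full_like(p, 1.0 / len(p))
            p = p / p.sum()
            drawn = rng.multinomial(config.community_size, p)
            new_state[pond] = drawn / config.community_size
            for rep in range(config.replicates_per_pond):
                depth = int(
                    np.round(
                        np.exp(
                            rng.normal(
                                np.log(config.depth_mean)
                                - 0.5 * np.log1p(config.depth_cv**2),
                                np.sqrt(np.log1p(config.depth_cv**2)),
                            )
                        )
                    )
                )
                sample_p = new_state[pond]
                if sample_p.sum() <= 0:
                    sample_p = np.full_like(sample_p, 1.0 / len(sample_p))
                sid = f"P{pond + 1}D{day:03d}R{rep + 1}"
                counts_cols[sid] = rng.multinomial(depth, sample_p / sample_p.sum())
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "pond": f"P{pond + 1}",
                        "day": day,
                        "stage": stage_of_day(day),
                        "group": config.marker,
                    }
                )
        state = new_state

    counts = pd.DataFrame(counts_cols, index=pd.Index(labels, name="taxon_id"))
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    truth = {
        "regime": config.regime,
        "regime_strength": config.regime_strength,
        "migration_rate": migration,
        "selection_mode": sel_mode,
        "trait": {lab: [float(x) for x in traits[i]] for i, lab in enumerate(labels)},
        "shared_optima": shared_optima.tolist(),
        "pond_optima": pond_optima.tolist(),
        "planted_pairs": [],
        "seed": config.seed,
    }
    return SyntheticDataset(counts=counts, tree=tree, metadata=metadata, env=env, truth=truth)


# ---------------------------------------------------------------------------
# planted correlation structure


def plant_correlations(
    counts: pd.DataFrame,
    pairs: Sequence[tuple[str, str, float]],
    seed: int,
) -> pd.DataFrame:
    """Rewrite the second taxon of each pair so its log-abundance tracks the first.

    For a pair ``(a, b, strength)`` with |strength| <= 1, taxon b's
    log-counts across samples are replaced by ``strength``-weighted copies of
    taxon a's standardized log-counts plus independent Gaussian noise, then
    mapped back onto b's original log-scale mean and sd and rounded to
    counts.  All other taxa are untouched.
    """
    out = counts.copy()
    rng = np.random.default_rng(seed)
    for a, b, strength in pairs:
        for name in (a, b):
            if name not in out.index:
                raise KeyError(f"taxon {name!r} not in table")
        if abs(strength) > 1:
            raise ValueError("correlation strength must satisfy |strength| <= 1")
        log_a = np.log(out.loc[a].to_numpy(dtype=float) + 1.0)
        log_b = np.log(out.loc[b].to_numpy(dtype=float) + 1.0)
        z = (log_a - log_a.mean()) / (log_a.std() or 1.0)
        eps = rng.normal(size=len(z))
        eps = (eps - eps.mean()) / (eps.std() or 1.0)
        mixed = strength * z + np.sqrt(1.0 - strength**2) * eps
        mu, sd = log_b.mean(), max(log_b.std(), 0.5)
        new_b = np.exp(mu + sd * mixed) - 1.0
        out.loc[b] = np.maximum(np.round(new_b), 0).astype(counts.dtypes.iloc[0])
    return out


def to_newick(tree: dendropy.Tree) -> str:
    """Newick string with branch lengths, stable across round trips."""
    buf = io.StringIO()
    tree.write(file=buf, schema="newick", suppress_rooting=True)
    return buf.getvalue().strip()
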