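"""Compositional co-occurrence networks: SparCC, filtering, topology, robustness.

Count tables from amplicon sequencing are compositional — taxon fractions
sum to one — so naive Pearson correlations between fractions are biased
negative.  SparCC instead works from the variances of pairwise log-ratios
T_ij = Var(ln x_i / x_j), which are invariant to the closure, solves the
linear "basis variance" system under a sparsity assumption, and converts
back to correlations.  Networks keep only edges with |r| >= 0.6 at p < 0.05
(permutation bootstrap), and stability is summarized by the proportion of
taxa remaining connected after random node removal.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class TopologyMetrics:
    n_nodes: int = 0
    n_links: int = 0
    average_degree: float = 0.0
    clustering_coefficient: float = 0.0
    average_path_distance: float = 0.0
    modularity: float = 0.0
    max_betweenness: float = 0.0
    betweenness_centralization: float = 0.0
    mean_eigenvector_centrality: float = 0.0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class CorrelationNetwork:
    """Undirected filtered-correlation graph with optional group tags."""

    graph: nx.Graph
    modules: dict = field(default_factory=dict)

    @property
    def nodes(self):
        return list(self.graph.nodes)

    @property
    def edges(self):
        return [(u, v, d["r"], d["p"], d["sign"]) for u, v, d in self.graph.edges(data=True)]


# ---------------------------------------------------------------------------
# filtering


def prevalence_filter(table: pd.DataFrame, min_fraction: float = 0.5) -> pd.DataFrame:
    """Keep taxa present in strictly more than ``min_fraction`` of samples.

    The strict inequality implements "observed in more than half of the
    samples" for the default 0.5.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    prev = (table > 0).mean(axis=1)
    kept = table.loc[prev > min_fraction]
    if kept.empty:
        warnings.warn("prevalence_filter removed every taxon")
    return kept


# ---------------------------------------------------------------------------
# SparCC


def log_ratio_variances(fracs: np.ndarray) -> np.ndarray:
    """T_ij = Var over samples of ln(x_i / x_j) for fraction matrix (taxa x samples)."""
    logf = np.log(fracs)
    v = logf.var(axis=1, ddof=1)
    cov = np.cov(logf, ddof=1)
    return v[:, None] + v[None, :] - 2.0 * cov


def _basis_variances(t_mat: np.ndarray, include: np.ndarray) -> np.ndarray:
    """Solve the SparCC basis-variance system restricted to included pairs.

    With M the inclusion indicator (off-diagonal), the sparsity assumption
    gives  diag(M 1) w + M w = t  where t_i = sum_j M_ij T_ij.
    """
    m = include.astype(float)
    np.fill_diagonal(m, 0.0)
    t = (m * t_mat).sum(axis=1)
    a = np.diag(m.sum(axis=1)) + m
    w, *_ = np.linalg.lstsq(a, t, rcond=None)
    return np.maximum(w, 1e-12)


def _corr_from_basis(t_mat: np.ndarray, w: np.ndarray) -> np.ndarray:
    denom = 2.0 * np.sqrt(np.outer(w, w))
    r = (w[:, None] + w[None, :] - t_mat) / denom
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def sparcc(
    table: pd.DataFrame,
    n_inner_iter: int = 20,
    exclusion_threshold: float = 0.1,
    exclusion_rounds: int = 10,
    seed: int = 0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """SparCC correlation matrix for a taxa-by-samples count table.

    Per inner iteration, per-sample fractions are drawn from a
    Dirichlet(counts + pseudocount) posterior; the log-ratio variance matrix
    T is solved for basis variances, the strongest-correlated pair above
    ``exclusion_threshold`` is iteratively excluded from the system (up to
    ``exclusion_rounds`` times), and the resulting correlation matrices are
    averaged across iterations.
    """
    n_taxa, n_samples = table.shape
    if n_taxa < 4:
        raise ValueError("sparcc needs at least 4 taxa")
    rng = np.random.default_rng(seed)
    counts = table.to_numpy(dtype=float)
    acc = np.zeros((n_taxa, n_taxa))
    for _ in range(n_inner_iter):
        fracs = np.empty_like(counts)
        for s in range(n_samples):
            fracs[:, s] = rng.dirichlet(counts[:, s] + pseudocount)
        t_mat = log_ratio_variances(fracs)
        include = np.ones((n_taxa, n_taxa), dtype=bool)
        w = _basis_variances(t_mat, include)
        r = _corr_from_basis(t_mat, w)
        for _round in range(exclusion_rounds):
            r_off = np.abs(r.copy())
            np.fill_diagonal(r_off, 0.0)
            r_off[~include] = 0.0
            i, j = np.unravel_index(np.argmax(r_off), r_off.shape)
            if r_off[i, j] <= exclusion_threshold:
                break
            include[i, j] = include[j, i] = False
            w = _basis_variances(t_mat, include)
            r = _corr_from_basis(t_mat, w)
        acc += r
    out = np.clip(acc / n_inner_iter, -1.0, 1.0)
    np.fill_diagonal(out, 1.0)
    ids = list(table.index)
    return pd.DataFrame(out, index=ids, columns=ids)


def sparcc_pvalues(
    table: pd.DataFrame,
    corr: pd.DataFrame,
    n_boot: int = 100,
    seed: int = 0,
    n_inner_iter: int = 5,
) -> pd.DataFrame:
    """Two-sided permutation-bootstrap p-values for SparCC correlations.

    Each bootstrap replicate permutes every taxon's counts independently
    across samples (destroying all between-taxon association while keeping
    marginals), re-runs SparCC, and counts entries with |r_null| >= |r_obs|:
    p = (1 + hits) / (1 + n_boot).  Diagonal p is 0 by convention.
    """
    if n_boot < 20:
        warnings.warn("n_boot < 20 gives very coarse p-value resolution")
    rng = np.random.default_rng(seed)
    counts = table.to_numpy(dtype=np.int64)
    obs = np.abs(corr.to_numpy())
    hits = np.zeros_like(obs)
    for b in range(n_boot):
        perm = np.empty_like(counts)
        for i in range(counts.shape[0]):
            perm[i] = rng.permutation(counts[i])
        null_tab = pd.DataFrame(perm, index=table.index, columns=table.columns)
        r_null = sparcc(null_tab, n_inner_iter=n_inner_iter, seed=int(rng.integers(2**31))).to_numpy()
        hits += np.abs(r_null) >= obs - 1e-12
    p = (1.0 + hits) / (1.0 + n_boot)
    np.fill_diagonal(p, 0.0)
    return pd.DataFrame(p, index=corr.index, columns=corr.columns)


# ---------------------------------------------------------------------------
# network construction


def build_network(
    corr: pd.DataFrame,
    pvals: pd.DataFrame,
    r_min: float = 0.6,
    alpha: float = 0.05,
    groups: dict | None = None,
) -> CorrelationNetwork:
    """Filter correlations into an undirected network.

    An edge is kept iff |r| >= r_min and p < alpha; isolated nodes are
    dropped.  If ``groups`` tags nodes with exactly two distinct labels the
    network is bipartite: within-group edges are discarded.
    """
    if list(corr.index) != list(pvals.index) or list(corr.columns) != list(pvals.columns):
        raise ValueError("correlation and p-value matrices are not aligned")
    bipartite = groups is not None and len(set(groups.values())) == 2
    g = nx.Graph()
    ids = list(corr.index)
    r = corr.to_numpy()
    p = pvals.to_numpy()
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if abs(r[i, j]) < r_min or p[i, j] >= alpha:
                continue
            if bipartite and groups[ids[i]] == groups[ids[j]]:
                continue
            g.add_edge(ids[i], ids[j], r=float(r[i, j]), p=float(p[i, j]),
                       sign="+" if r[i, j] > 0 else "-")
    if groups:
        nx.set_node_attributes(g, {n: groups.get(n, "") for n in g.nodes}, "group")
    return CorrelationNetwork(graph=g)


def detect_modules(net: CorrelationNetwork, seed: int = 0) -> dict:
    """Greedy Louvain community detection (seeded); labels stored on the network."""
    if net.graph.number_of_nodes() == 0:
        net.modules = {}
        return {}
    comms = nx.community.louvain_communities(net.graph, weight=None, seed=seed)
    modules = {}
    for k, comm in enumerate(sorted(comms, key=lambda c: (-len(c), sorted(c)[0]))):
        for node in comm:
            modules[node] = k
    net.modules = modules
    nx.set_node_attributes(net.graph, modules, "module")
    return modules


# ---------------------------------------------------------------------------
# topology & robustness


def topology(net: CorrelationNetwork, seed: int = 0) -> TopologyMetrics:
    """Global topology metrics of a co-occurrence network.

    Average path distance and eigenvector centrality are computed on the
    largest connected component; betweenness centralization is the sum of
    (max - b_i) of normalized betweenness scaled by its star-graph maximum
    (n - 1), so a star scores exactly 1.
    """
    g = net.graph
    n = g.number_of_nodes()
    if n == 0:
        return TopologyMetrics()
    largest_cc = g.subgraph(max(nx.connected_components(g), key=len))
    bet = nx.betweenness_centrality(g, normalized=True)
    b_max = max(bet.values())
    centralization = sum(b_max - b for b in bet.values()) / (n - 1) if n > 1 else 0.0
    if not net.modules:
        detect_modules(net, seed=seed)
    comms: dict[int, set] = {}
    for node, m in net.modules.items():
        comms.setdefault(m, set()).add(node)
    modularity = nx.community.modularity(g, comms.values()) if g.number_of_edges() else 0.0
    try:
        eig = nx.eigenvector_centrality_numpy(largest_cc)
    except Exception:  # tiny/degenerate components
        eig = {node: 1.0 / largest_cc.number_of_nodes() for node in largest_cc}
    return TopologyMetrics(
        n_nodes=n,
        n_links=g.number_of_edges(),
        average_degree=2.0 * g.number_of_edges() / n,
        clustering_coefficient=nx.average_clustering(g),
        average_path_distance=(
            nx.average_shortest_path_length(largest_cc)
            if largest_cc.number_of_nodes() > 1 else 0.0
        ),
        modularity=modularity,
        max_betweenness=b_max,
        betweenness_centralization=centralization,
        mean_eigenvector_centrality=float(np.mean(list(eig.values()))),
    )


def robustness(
    net: CorrelationNetwork,
    removal_fraction: float = 0.5,
    n_reps: int = 100,
    seed: int = 0,
) -> tuple[float, float]:
    """Mean +/- sd proportion of species remaining after random node removal.

    Per repetition, floor(f * N) nodes are removed uniformly at random, then
    any node left without edges is also discarded; the remaining proportion
    is survivors / N.
    """
    if not 0 <= removal_fraction < 1:
        raise ValueError("removal_fraction must be in [0, 1)")
    g = net.graph
    n = g.number_of_nodes()
    if n == 0:
        return 0.0, 0.0
    nodes = list(g.nodes)
    k = int(np.floor(removal_fraction * n))
    rng = np.random.default_rng(seed)
    props = np.empty(n_reps)
    for rep in range(n_reps):
        removed = set(rng.choice(n, size=k, replace=False))
        sub = g.subgraph([nodes[i] for i in range(n) if i not in removed])
        survivors = sum(1 for node in sub.nodes if sub.degree(node) > 0)
        props[rep] = survivors / n
    return float(props.mean()), float(props.std(ddof=0))


def robustness_curve(
    net: CorrelationNetwork,
    fractions=np.linspace(0.0, 0.9, 10),
    n_reps: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Robustness at a grid of removal fractions (mean and sd per fraction)."""
    rows = []
    for i, f in enumerate(fractions):
        m, s = robustness(net, float(f), n_reps=n_reps, seed=seed + i)
        rows.append({"removal_fraction": float(f), "mean_remaining": m, "sd_remaining": s})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# module trends


def module_trends(net: CorrelationNetwork, table: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-module mean relative abundance per day with a Pearson time trend."""
    import scipy.stats as ss

    if not net.modules:
        raise ValueError("run detect_modules first")
    rel = table.div(table.sum(axis=0), axis=1)
    days = metadata.loc[table.columns, "day"]
    rows = []
    for m in sorted(set(net.modules.values())):
        members = [t for t, mm in net.modules.items() if mm == m and t in rel.index]
        if not members:
            warnings.warn(f"module {m} has no taxa in the table; skipped")
            continue
        mod_ab = rel.loc[members].sum(axis=0)
        per_day = mod_ab.groupby(days).mean()
        if len(per_day) >= 3 and per_day.std() > 0:
            r, p = ss.pearsonr(per_day.index.to_numpy(dtype=float), per_day.to_numpy())
        else:
            r, p = 0.0, 1.0
        rows.append({"module": m, "n_taxa": len(members),
                     "mean_abundance": float(mod_ab.mean()), "r": float(r), "p": float(p)})
    return pd.DataFrame(rows)
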