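"""End-to-end reproducible runs: simulate -> rarefy -> partition -> stats ->
network -> assembly, with a manifest of inputs, seeds and output checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import assembly as asm
from . import diversity, io, network, simulate, stats

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one full pipeline run (YAML-loadable)."""

    outdir: str = "metacomm_run"
    seed: int = 0
    simulation: dict = field(default_factory=dict)
    rarefaction_depth: int = 37_827
    network_r_min: float = 0.6
    network_alpha: float = 0.05
    network_min_fraction: float = 0.5
    network_n_boot: int = 50
    assembly_min_bin_size: int = 12
    assembly_n_null: int = 100
    assembly_z_cut: float = 1.96
    assembly_rc_cut: float = 0.95
    counts_path: str | None = None
    metadata_path: str | None = None
    tree_path: str | None = None
    env_path: str | None = None
    run_network: bool = True
    run_assembly: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**known)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.rarefaction_depth <= 0:
            raise ValueError("rarefaction_depth must be positive")
        if not 0 < self.network_r_min <= 1 or not 0 < self.network_alpha <= 1:
            raise ValueError("network thresholds out of range")
        if self.counts_path and self.run_assembly and not self.tree_path:
            raise ValueError("assembly stage enabled but no tree_path given")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline and return the manifest dict.

    All outputs land under ``config.outdir``; the manifest records
    parameters, seeds, and a sha256 per output file so a rerun with the same
    config can be verified byte-for-byte.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stage_done = []
    try:
        # --- inputs ------------------------------------------------------
        if config.counts_path:
            counts = io.read_counts(config.counts_path)
            metadata = io.read_metadata(config.metadata_path)
            tree = io.read_tree(config.tree_path, taxa=list(counts.index)) if config.tree_path else None
            env = io.read_env(config.env_path) if config.env_path else None
        else:
            sim_cfg = simulate.SimulationConfig(**config.simulation)
            sim_cfg.seed = config.simulation.get("seed", config.seed)
            ds = simulate.assemble_metacommunity(sim_cfg)
            counts, metadata, tree, env = ds.counts, ds.metadata, ds.tree, ds.env
            io.write_counts(counts, out / "counts.tsv")
            io.write_metadata(metadata, out / "metadata.tsv")
            io.write_env(env, out / "env.tsv")
            io.write_tree(tree, out / "tree.nwk")
            io.write_json(ds.truth, out / "truth.json")
        stage_done.append("inputs")

        # --- rarefaction --------------------------------------------------
        rarefied = diversity.rarefy(counts, config.rarefaction_depth, seed=config.seed + 1)
        io.write_counts(rarefied, out / "counts_rarefied.tsv")
        metadata = metadata.loc[[s for s in rarefied.columns]]
        stage_done.append("rarefy")

        # --- diversity partition -----------------------------------------
        part = diversity.partition_by_stage(rarefied, metadata)
        part.to_csv(out / "partition.tsv", sep="\t", index=False)
        stage_done.append("partition")

        # --- ordination + permutation stats ------------------------------
        bc = stats.bray_curtis(rarefied)
        ord_res = stats.pcoa(bc)
        coords = ord_res.samples.iloc[:, :3]
        coords.insert(0, "sample_id", list(bc.ids))
        coords.to_csv(out / "pcoa.tsv", sep="\t", index=False)
        days = metadata.loc[list(bc.ids), "day"]
        perm = stats.permanova(bc, days, n_perm=999, seed=config.seed + 2)
        trends = stats.taxon_trends(rarefied, metadata.loc[rarefied.columns, "day"])
        trends.to_csv(out / "taxon_trends.tsv", sep="\t")
        io.write_json(
            {"permanova": {"pseudo_F": perm.statistic, "p": perm.p_value,
                           "n_perm": perm.n_permutations}},
            out / "stats.json",
        )
        stage_done.append("stats")

        # --- network ------------------------------------------------------
        if config.run_network:
            filt = network.prevalence_filter(rarefied, config.network_min_fraction)
            if filt.shape[0] >= 4:
                corr = network.sparcc(filt, seed=config.seed + 3)
                pvals = network.sparcc_pvalues(filt, corr, n_boot=config.network_n_boot,
                                               seed=config.seed + 4)
                net = network.build_network(corr, pvals, r_min=config.network_r_min,
                                            alpha=config.network_alpha)
                network.detect_modules(net, seed=config.seed + 5)
                metrics = network.topology(net, seed=config.seed + 5)
                io.write_json(metrics.as_dict(), out / "network_metrics.json")
                edges = [
                    {"source": u, "target": v, "r": r, "p": p, "sign": s,
                     "module": net.modules.get(u, -1)}
                    for u, v, r, p, s in net.edges
                ]
                with open(out / "edges.tsv", "w") as fh:
                    fh.write("source\ttarget\tr\tp\tsign\tmodule\n")
                    for e in edges:
                        fh.write("{source}\t{target}\t{r:.6f}\t{p:.6g}\t{sign}\t{module}\n".format(**e))
                import networkx as nx

                nx.write_graphml(net.graph, out / "network.graphml")
                curve = network.robustness_curve(net, n_reps=100, seed=config.seed + 6)
                curve.to_csv(out / "robustness.tsv", sep="\t", index=False)
            else:
                logger.warning("too few prevalent taxa for a network; stage skipped")
            stage_done.append("network")

        # --- assembly -----------------------------------------------------
        if config.run_assembly and tree is not None:
            labels, d_phylo = simulate.patristic_matrix(tree)
            result = asm.quantify_assembly(
                rarefied, labels, d_phylo, metadata,
                min_bin_size=min(config.assembly_min_bin_size, max(3, rarefied.shape[0] // 2)),
                n_null=config.assembly_n_null,
                z_cut=config.assembly_z_cut, rc_cut=config.assembly_rc_cut,
                seed=config.seed + 7,
            )
            result.pair_bins.to_csv(out / "assembly_pair_bins.tsv", sep="\t", index=False)
            result.percentages.to_csv(out / "assembly_percentages.tsv", sep="\t", index=False)
            if env is not None and len(result.percentages) >= 3:
                det = result.percentages.set_index("day")["determinism"]
                reg = asm.regress_determinism(det, env)
                reg.to_csv(out / "determinism_regression.tsv", sep="\t", index=False)
            stage_done.append("assembly")
    except Exception as exc:
        raise RuntimeError(
            f"pipeline failed after stage(s) {stage_done}: {exc}"
        ) from exc

    manifest = {
        "config": asdict(config),
        "stages": stage_done,
        "runtime_s": round(time.time() - t0, 2),
        "outputs": {p.name: _sha256(p) for p in sorted(out.iterdir())
                    if p.is_file() and p.name != "manifest.json"},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
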