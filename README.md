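# metacomm

Tools for analysing microbial community time series from replicated
mesocosm / pond systems: multiscale diversity partitioning with Rao's
quadratic entropy, compositional (SparCC-style) co-occurrence networks with
robustness analysis, and phylogenetic-bin null models that apportion
community assembly among five ecological processes.  A built-in
metacommunity simulator generates data under *known* assembly regimes, so
every stage of the pipeline can be validated against ground truth.

## Who this is for

Microbial ecologists working with zOTU/ASV count tables sampled repeatedly
across sites (ponds) and time (culture days), who want to answer three
questions: how is metacommunity diversity distributed across time and
space, which taxa co-occur beyond compositional artefacts, and how much of
community turnover is driven by selection versus dispersal and drift.

## The methods

**Diversity partition.**  Diversity is Rao's quadratic entropy
Q = Σᵢⱼ dᵢⱼ pᵢ pⱼ (with dᵢⱼ = 1 for i ≠ j this is Gini–Simpson; patristic
distances may be used instead).  Within a culture stage, the stage-pooled
diversity decomposes additively:

    γ_ecosystem = ᾱ_local + β_intertemporal + β̄_intratemporal

where ᾱ_local is the mean within-sample diversity, β̄_intratemporal the mean
excess of each timepoint's pooled diversity over its local mean, and
β_intertemporal the excess of the stage-pooled diversity over the mean
timepoint diversity.  The identity is exact by construction, so the three
component percentages always sum to 100% of γ.

**Co-occurrence networks.**  Count tables are compositional, which biases
naive correlations.  SparCC works from log-ratio variances
Tᵢⱼ = Var ln(xᵢ/xⱼ), solves the basis-variance system
ωᵢ under a sparsity assumption, and recovers correlations
rᵢⱼ = (ωᵢ + ωⱼ − Tᵢⱼ) / 2√(ωᵢωⱼ).  Edges are kept at |r| ≥ 0.6 and
permutation-bootstrap p < 0.05 after a >50 % prevalence filter; topology
(degree, clustering, path distance, modularity, betweenness
centralization) and robustness (proportion of taxa still connected after
random node removal) summarize each network.

**Assembly processes.**  Taxa are clustered into phylogenetic bins; for
every within-day sample pair and bin the pipeline computes βNRI (the
standardized effect size of abundance-weighted between-community mean
pairwise phylogenetic distance against a within-bin taxon shuffle) and the
Raup–Crick metric RC (Bray–Curtis turnover ranked against richness- and
abundance-preserving null communities).  βNRI < −1.96 → homogeneous
selection, βNRI > +1.96 → heterogeneous selection; otherwise RC > 0.95 →
dispersal limitation, RC < −0.95 → homogenizing dispersal, else drift.
Bin labels are abundance-weight-aggregated to per-day process percentages,
and the deterministic fraction (HeS + HoS) can be regressed on
environmental covariates.

## Worked example

Simulate a 4-pond, 3-timepoint metacommunity under strong shared
environmental selection, rarefy to a common depth, partition diversity,
and quantify assembly processes:

```python
from metacomm.simulate import SimulationConfig, assemble_metacommunity, patristic_matrix
from metacomm.diversity import rarefy, partition_by_stage
from metacomm.assembly import quantify_assembly

cfg = SimulationConfig(
    n_taxa=150, n_ponds=4, timepoints=[10, 20, 30], replicates_per_pond=3,
    regime="homogeneous_selection", regime_strength=0.9, migration_rate=0.3, seed=1,
)
ds = assemble_metacommunity(cfg)
counts = rarefy(ds.counts, 37_827, seed=0)

print(partition_by_stage(counts, ds.metadata).round(2).to_string(index=False))
labels, d = patristic_matrix(ds.tree)
res = quantify_assembly(counts, labels, d, ds.metadata, n_null=100, seed=7)
print(res.percentages.round(1).to_string(index=False))
```

Output:

```
group  stage  gamma  GammaReg%  AlphaLoc%  BetaInter%  BetaIntra%
  16S      1   0.85      100.0      97.72        2.28         0.0

 day  HeS  HoS  DL  HD  DR  determinism  stochasticity
  10  0.0 92.1 7.9 0.0 0.0         92.1            7.9
  20  0.0 96.8 2.2 0.0 1.1         96.8            3.2
  30  0.0 97.3 2.7 0.0 0.0         97.3            2.7
```

The partition row says almost all stage diversity sits within local
communities (AlphaLoc% ≈ 98) — ponds filtered through one shared optimum
converge on the same community, leaving little turnover between ponds or
days.  The assembly table recovers the planted regime: homogeneous
selection (HoS) is the dominant process on every sampling day, and the
deterministic fraction exceeds 90 %.  Rerunning with `regime="drift"`
flips the table to the stochastic processes (DL + HD + DR > 50 %).

The same steps are available from the shell:

```bash
metacomm simulate --seed 1 --outdir run/
metacomm rarefy   --counts run/counts.tsv --depth 37827 --seed 0 --out run/rare.tsv
metacomm partition --counts run/rare.tsv --meta run/metadata.tsv --out run/partition.tsv
metacomm network  --counts run/rare.tsv --outdir run/net
metacomm assembly --counts run/rare.tsv --meta run/metadata.tsv \
                  --tree run/tree.nwk --env run/env.tsv --outdir run/assembly
metacomm all      --seed 1 --outdir run/full   # whole pipeline + manifest
```

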