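# Methods notes

This document records the models, defaults and numerical choices behind
`metacomm`, including where the design was genuinely open and what the
synthetic benchmark does and does not demonstrate.

## Synthetic metacommunity model

The generator (`metacomm.simulate`) emulates a replicated pond time series:
`n_ponds` ponds sampled at the configured culture days with 3–5 replicate
samples each, rising nutrient loads (TN, TP, phosphate, ammonium, nitrite,
nitrate) and falling silicate, and communities assembled under a chosen
regime.  Defaults follow the emulated study design: 9 timepoints over 100
days (stages 1–3 at days 10–30, 40–60, 70–100), 4 ponds, 3 replicates, and
a mean sequencing depth of 45,000 reads (CV 3 %) so that rarefaction to
37,827 reads — the depth used throughout the package's examples — retains
every sample.

**Dynamics.**  Each pond carries a relative-abundance state over `n_taxa`
taxa, initialized from a lognormal(0, 1) regional pool.  Per timepoint:

1. *Migration*: the state is mixed with the regional pool (abundance-
   weighted mean of all ponds at the previous timepoint) at rate *m*.
2. *Selection* (selection regimes only): a Gaussian kernel
   exp(−‖trait − optimum‖²/2σ²) filters the *baseline* pool, and the
   community becomes a blend `(1−s)·drift_state + s·filtered_pool`, with
   *s* the regime strength.  Applying the kernel to the baseline pool
   rather than to the running state keeps the filter from compounding
   across timepoints; compounding collapses communities onto a handful of
   taxa, which both destroys within-bin diversity and (by concentrating
   abundance) inflates the variance of the βNRI null.
3. *Demography*: multinomial resampling of 100,000 individuals.
4. *Sequencing*: per replicate, a multinomial read draw at a lognormal
   per-sample depth.

**Traits.**  Niche traits evolve along a random coalescent tree by Brownian
motion in **25 independent dimensions** (each edge adds N(0, branch length)
per dimension).  One Brownian dimension carries so much homoplasy that
communities perfectly confined to a trait window are phylogenetically
clustered only by luck; with K dimensions the squared trait distance
concentrates around K × patristic distance (relative sd √(2/K) ≈ 0.28 at
K = 25), so the Gaussian fitness kernel behaves like an exponential
patristic filter exp(−patristic/τ) with τ = 2σ²/K, and "favoured by the
optimum" reliably means "a clade".  Selection then produces the
phylogenetic signal that βNRI is designed to detect, for the same reason it
does in nature: niches are conserved.

**Kernel width.**  τ = 0.25 × tree diameter × ((1−s)/s)^0.6.  At s = 0.9
the favoured neighbourhood is a small clade (τ ≈ 0.07 diameters); at
s = 0.5 a broad clade; s → 0 removes selection (the homogeneous-selection
regime with s = 0 is bitwise identical to drift).  The exponent 0.6 was
chosen once so that the three-point strength grid (0.2, 0.5, 0.9) spans
negligible → moderate → dominant determinism.

**Optima.**  Optima are anchored at real tips' trait vectors so they always
sit in occupied niche space.  The shared optimum (homogeneous selection)
glides 30 % of the way toward a distant anchor as TN rises, coupling
selection to the environment; per-pond optima (heterogeneous selection)
are maximin-separated tips so ponds favour well-separated lineages.
Dispersal limitation forces m ≈ 10⁻⁴ with independent pond drift;
homogenizing dispersal sets m = 0.95.

**What the generator does not emulate.**  Sequencing error, chimeras and
primer bias (taxa are abstract); seasonal environmental cycles; species
interactions (taxa are coupled only through the shared multinomial
constraint and, via `plant_correlations`, through explicitly planted
log-linear couplings).  Passing the recovery benchmarks therefore shows
the estimators are correct and well calibrated under their own model
assumptions — not that real pond data satisfy those assumptions.

## Rao partition

Pooling is the mean of relative-abundance vectors; timepoints get equal
weight by default (replicate-count weights via `weights="abundance"`),
and the same weights are used for γ, ᾱ and both β components, which makes
the additive identity exact rather than approximate.  With unequal
replicate counts "mean local diversity" is ambiguous (mean over
communities vs. over timepoint means); the default is the timepoint-mean-
of-means, the alternative is one flag away, and both obey the identity.
The taxon distance defaults to dᵢⱼ = 1 − δᵢⱼ (Rao = Gini–Simpson);
patristic distances rescaled to max 1 are accepted wherever a distance
matrix is.  No equivalent-number (Q/(1−Q)) transformation is applied by
default since the additive form is the object of interest.  Chao1 uses the
bias-corrected form (finite when F₂ = 0); Shannon uses natural log.

## Permutation statistics

All permutation p-values use (1 + #more-extreme)/(1 + n_perm) and cannot
be zero.  PERMANOVA permutes labels freely (no strata), default
n_perm = 999, with an exhaustive mode that enumerates all distinct label
arrangements for small designs (used to verify the permutation machinery
exactly).  The t test defaults to the Welch form because replicate
variances differ between ponds; the pooled form is a flag.  Per-taxon
temporal trends are Pearson correlations of relative abundance against
day with Benjamini–Hochberg correction across taxa; constant taxa are
reported as r = 0, p = 1 with a flag rather than NaN.  The stage split
uses UPGMA on Bray–Curtis distances between day-mean communities; temporal
contiguity of the resulting clusters is reported, not enforced.

## SparCC

Pseudocount 1, 20 Dirichlet resamples averaged, exclusion threshold 0.1
with up to 10 exclusion rounds — the conventional inner settings, all
config-exposed; only the |r| ≥ 0.6, p < 0.05 edge filter and the >50 %
prevalence filter (strict inequality) are fixed contract values.  The
p-value null permutes each taxon's counts independently across samples and
re-runs the full estimator.  Log-ratio variances are computed from the
covariance of log-fractions (T = v1ᵀ + 1vᵀ − 2C), and basis variances
solve (diag(M1) + M)ω = t by least squares so the pair-exclusion system
stays well-posed.  Average path distance is computed on the largest
connected component (undefined otherwise); modularity uses seeded Louvain
so runs are reproducible; betweenness centralization is Σ(max b − bᵢ)
normalized by the star-graph maximum (n − 1), anchoring a star at exactly 1.
Robustness removes ⌊f·N⌋ nodes uniformly at random, discards nodes left
edgeless, and reports the surviving fraction (mean ± sd over repetitions;
defaults f = 0.5, 100 repetitions).

## Assembly null models

Bins come from average-linkage clustering of patristic distances cut at
**0.4 × tree diameter** (minimum bin size 12; undersized bins merge into
the nearest bin by mean inter-bin distance).  The deep cut is deliberate:
within-bin null models are blind to selection acting at or above the grain
of a bin, so bins must be coarse relative to the clades selection favours.
At the few-hundred-taxon scale this package targets, a 0.2-diameter cut
(the convention for trees with thousands of tips, where bins are
relatively much finer) produces bins commensurate with a selected clade
and washes out the βNRI signal; 0.4 restores the separation of scales.
Both the threshold and the minimum size are parameters.

βMPD is abundance-weighted (fᴬᵀ D fᴮ on within-bin relative abundances),
matching the abundance-based analyses the package performs throughout.
The βNRI null shuffles taxon identities **within the bin** (joint row/
column permutation of the bin's distance matrix), 1000 draws by default
(100 in the fast recovery benchmarks); a null sd below 10⁻¹² of the null
mean is reported as βNRI = 0 with a warning.  RC nulls preserve each
sample's within-bin richness and total abundance, draw taxa without
replacement with probability proportional to regional occurrence frequency
(Gumbel top-k sampling), assign abundances proportional to regional mean
abundance, and rank observed Bray–Curtis against the null:
RC = 2·(#{null < obs} + ½#{null = obs})/n − 1.  Pairs whose within-bin
richness is below 2 in either sample skip RC for that bin; bins absent
from a community skip the pair entirely, and the pair's bin weights
(mean relative-abundance share of the two samples) are renormalized over
the bins that remain.  Classification thresholds are ±1.96 (βNRI) and
±0.95 (RC), the framework convention, both config-exposed.  Sample pairs
are all within-day pairs; consecutive-day pairing is not implemented.

The per-bin computation is vectorized: one set of taxon shuffles and one
set of null communities per sample is shared by all pairs in a day group,
which is what keeps 1000-null runs on ~200 pairs × ~5 bins in seconds.

## Benchmark problem sizes

The regime-recovery benchmarks use 150 taxa, 4 ponds × 3 timepoints × 3
replicates and 100 null draws per pair-bin; the calibration checks use 200
self-null replicates with 500 draws each on bins of 5–30 taxa; SparCC
checks use 50 taxa × 200 samples.  These sizes give stable verdicts
(selection recovered as HoS in ≥ 8/10 seeds, drift as majority-stochastic
in 10/10) while keeping the full suite inexpensive to run.

## Known limitations

- βNRI-based detection needs the selected clade to be finer than its bin;
  selection aligned exactly with bin boundaries reads as drift.  This is a
  property of bin-based null models generally, not of this implementation.
- Heterogeneous selection with few ponds mixes HeS (cross-pond pairs) with
  HoS (within-pond replicate pairs) by construction; the deterministic
  fraction is the robust readout for that regime.
- The phylogenetic-signal pre-test of the full bin-based framework is
  reduced to the binning itself (plus the trait–phylogeny Mantel check in
  the test suite); per-bin signal optimization is out of scope.
- RC nulls assign abundances deterministically given the drawn taxon set,
  which makes the null tighter than resampling-based variants; RC values
  near ±1 are therefore common and the ±0.95 cut should not be narrowed
  without recalibration.
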