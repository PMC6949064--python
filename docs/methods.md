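# Methods

This note documents the models, estimators and design choices behind
`mrnet`, what the synthetic-data generator does and does not emulate, and
the numerical conventions that make results deterministic.

## Synthetic cohorts

The generator emulates the statistical shape of a multi-study tumor/normal
microarray compendium on the log2 scale with a linear-Gaussian model:

* Baseline per-gene intensity ~ N(7, 1); i.i.d. noise ε ~ N(0, noise_sd)
  per gene and sample (default noise_sd = 0.7).
* Each of `n_tf` TFs (default 20) drives a signed regulon of
  `targets_per_tf` targets (default 50) drawn from the non-TF genes;
  regulons may overlap. Edge modes are −1 with probability
  `frac_negative_mode` (default 0.3) and coupling strengths are drawn from
  U(0.6, 1.0) — direct regulation strong enough to be detectable at
  microarray-like noise, while still spanning a factor of attenuation.
* `n_active_tfs` TFs (default 10) carry a tumor-specific shift δ
  (default 2 log2 units) in PT samples. A target's expression is
  baseline + mode·strength·(TF deviation) + batch + noise, where the TF
  deviation is the TF's realized departure from its baseline (activity
  shift plus biological noise). TF activity is identified with TF
  expression; there is no hidden protein-activity layer.
* Batch effects are additive per gene (offsets ~ N(0, 0.5), constrained to
  sum to zero across batches); a multiplicative noise scale per batch is
  supported but defaults to 1, matching the additive generative equations.
  Samples are assigned to batches round-robin after shuffling so tissue
  class and batch are never confounded.
* Survival (PT only): event times are exponential with hazard
  baseline_hazard·exp(Σ β_tf·z(TF)), z standardizing TF expression across
  the tumors; censoring is exponential with `censor_rate`. Defaults
  (0.02/month, 0.01/month) give a median survival of roughly three years
  and about one-third censoring — an unexceptional oncology cohort shape.

Default cohort scale — 2,000 genes, 150 PT + 100 NT, 3 batches — keeps a
full pipeline run in the tens of seconds on one CPU while leaving every
stage statistically non-trivial.

What the generator does **not** emulate: probe-level microarray noise,
heavy-tailed or intensity-dependent variance, paired-sample correlation,
copy-number or mutational drivers, and hidden TF activity decoupled from TF
expression. Passing the planted-recovery suite therefore demonstrates
correctness and calibration of the pipeline under its own model class, not
performance guarantees on real tumor compendia.

## Preprocessing

**Duplicate collapse.** Default rule: keep the duplicate row with maximal
mean across samples (preserves within-row covariance); row averaging is
available via `method="mean"`.

**Batch adjustment** is the parametric empirical-Bayes location/scale
model, no covariates. Per gene the data are standardized against the
batch-size-weighted grand mean and the pooled variance of residuals around
per-batch means; per-batch additive effects γ and variance ratios δ² are
shrunk toward a normal and an inverse-gamma prior fitted across genes by
moments (iterated posterior means, relative tolerance 1e-8). Degenerate
priors are handled explicitly: zero between-gene spread of γ̂ collapses to
the common batch effect (which makes removal of a gene-homogeneous planted
shift exact); zero spread of δ̂² leaves scales unshrunk. After adjustment
every gene is re-centered to its pre-adjustment grand mean, so the
operation never moves a gene's overall level. Exact (≤1e-6) equalization of
batch means holds only for shifts homogeneous across genes in standardized
units; heterogeneous shifts are removed up to the shrinkage residual, which
is the intended empirical-Bayes behavior.

**Moderated t.** Pooled two-class variance with df = n−2; prior (d₀, s₀²)
fitted by the closed-form moment equations on log residual variances
(digamma/trigamma inversion by bisection). If the observed spread of
log-variances does not exceed the sampling spread the prior df is infinite
(complete shrinkage); a failed fit falls back to d₀ = 0, the classical
pooled t, with a warning. P-values are two-sided on d₀ + df degrees of
freedom. With d₀ forced to 0 the statistic reproduces `scipy`'s pooled
t-test to 1e-12, and the full fit matches R limma's eBayes on shared data
(cross-checked in the test suite).

**Signature.** FDR < 0.05 (Benjamini–Hochberg) and fold change > 1.5. The
fold-change threshold is interpreted on the linear scale (2^|log2FC| > 1.5)
by default; `fc_scale="log2"` applies it to |log2FC| directly.

## Network inference

**MI estimator.** Profiles are reduced to ordinal ranks (stable tie-break
by sample position) and cut into B = ⌊√(n/5)⌋ ≥ 2 equal-frequency bins;
MI is the plug-in estimate on the joint histogram minus a Miller–Madow
bias term computed from occupied cell counts, clipped at zero, in nats.
The correction matters: the raw plug-in bias (≈(B−1)²/2n) would exceed the
estimator's target accuracy against the bivariate-normal closed form at
n = 10,000. Rank binning makes the estimate invariant under strictly
increasing transforms of either input; a decreasing transform can shift it
minutely when n is not a multiple of B (the unequal bin sizes reverse).
Constant inputs return 0 with a degenerate flag.

**Thresholding and bootstrap.** The null pool is the MI of `n_perm`
(default 1000) random gene pairings, each profile permuted independently;
the threshold is the empirical (1−α) quantile, α = 10⁻³ by default. An
edge is kept if it passes the full-data threshold **and** exceeds the
threshold in ≥ `consensus`·`n_boot` bootstrap resamples (defaults
0.95, 100). Within each resample the threshold is recomputed from that
resample's own permutation null, because sampling with replacement creates
joint duplicates that inflate null MI; a fixed full-data threshold would
mis-calibrate the per-resample decisions. Edge weights are always the
full-data MI.

**DPI.** For every triangle (TF₁, TF₂, target) with TF–TF MI available,
the strictly weakest of the three MI values is marked for removal if it is
a TF–target edge and lies below both others by more than the absolute
`tolerance` (default 0.0; 0.01 reproduces a lenient profile). Marks are
collected first and swept once, so the result is independent of scan
order. TF–TF pairs only condition and are never removed — the output is a
TF→target regulon network.

**Modes.** Sign of the full-data Pearson correlation; zero or undefined
correlation leaves the mode unset and the edge flagged. Note that a target
planted in two regulons has no well-defined per-edge marginal sign when
the regulators share a common driver (e.g. the tumor state), so mode
agreement against planted truth is only meaningful on single-parent
targets.

## Master regulator analysis

One-sided hypergeometric tail P(X ≥ overlap) of regulon–signature overlap
against the universe (all genes in the preprocessed matrix by default,
configurable); odds ratios from the 2×2 table with a Haldane 0.5 correction
when any cell is zero; BH FDR across tested TFs. Regulons with fewer than
`min_regulon_size` (default 15) targets in the universe are flagged and
skipped. Ranks order tested TFs by ascending p with deterministic TF-id
tie-break. Cross-cohort agreement is the Pearson correlation of −log₁₀ p
over shared TFs (p floored at 1e-300; Spearman available); consensus MRs
are those with FDR < α in every cohort; rankings are scored against binary
labels by the Mann–Whitney AUC with half-credit ties.

## Regulon activity (two-tailed GSEA)

A moded regulon splits into A (mode +1) and B (mode −1); both tails are
scored on the same ranked list by the weighted Kolmogorov–Smirnov running
sum (hit steps ∝ |score|^exponent, default exponent 1; miss steps
1/(N−N_hits)); ES is the signed maximum deviation, and dES = ES_A − ES_B
(so dES ∈ [−2, 2], positive = induced). Regulons need ≥ `min_tail`
(default 5) targets per tail to be testable. Conventions that make results
deterministic: ranking ties are broken by gene-id lexicographic order; when
the positive and negative running-sum extremes tie in magnitude (within
relative 1e-12) the positive one is returned; an all-tied ranking (e.g. a
sample exactly at the cohort mean) falls back to uniform hit weights and is
flagged degenerate.

Phenotype-level activity ranks genes by a differential statistic (the
moderated t, in the pipeline); per-sample activity ranks genes by the
sample's z-score against per-gene cohort mean and SD (median/MAD optional).
The z-score basis is a reconstruction choice — the ranking transform behind
published per-sample dES heatmaps in this method family is typically not
printed. For survival analyses the z-scores are computed on the tumor
submatrix, since the stratification concerns variation among tumors.
Permutation p-values (add-one smoothed, |dES| two-sided, default 1000
permutations) are computed for phenotype-level activity; for per-sample
matrices they default off for cost reasons.

## Survival

Kaplan–Meier product-limit curves and the standard log-rank chi-square
(hypergeometric variance per event time, censored-after-events ties, no
continuity correction) are delegated to `lifelines`; the test suite pins
both against hand product-limit and O−E summation oracles. Stratification:
active (dES>0 ∧ ES_A>0 ∧ ES_B<0), repressed (dES<0 ∧ ES_A<0 ∧ ES_B>0),
otherwise inconclusive; active and repressed groups are each split at
their median dES with ties to the low half. The joint log-rank can compare
all strata or user-selected (possibly pooled) groups — both usages are
exposed since either reading is defensible.

## Interactions and subtyping

Pairwise regulon profiles: Jaccard coefficient of target sets; shared
targets with both modes set classified co-activated/co-repressed/opposing;
Pearson correlation of per-sample dES vectors. Joint two-MR stratification
cross-classifies the two three-way states into 9 cells, merging cells below
`min_group` (default 10) into "other". Subtyping is consensus hierarchical
clustering only (average linkage, 1−Pearson distance; `n_resample` = 100
subsamples of 80% of samples without replacement): the consensus matrix is
co-cluster frequency among co-sampled pairs and the final assignment cuts
the 1−consensus dendrogram at k. The number of subtypes k stays a user
decision; `consensus_k_sweep` reports consensus-CDF areas and their deltas
for k = 2…6 as the usual elbow diagnostic.

## Reproducibility

Every stochastic stage draws from `numpy` Generator streams derived from
the single run seed plus a stable stage label (CRC of the name), so
identical configuration and seed reproduce identical outputs, including
across partial re-runs. Readers and writers round-trip losslessly (floats
are written as full reprs and parsed with correctly-rounded conversion).

## Validation experiments and problem sizes

The acceptance script and the end-to-end tests run, at fixed seeds: the
default cohort (2,000 genes × 250 samples) through the full pipeline;
10,000-gene null matrices for moderated-t calibration; 500–2,000 null
log-rank replicates (n = 100 + 100); 200–400 dES permutation-null
replicates (200-gene rankings, 10 + 10 tails, 1000 permutations); and 100
survival-linkage replicates (n_pt = 300, β = −1 on one active TF). These
sizes keep the whole validation in a few minutes on a single CPU while
holding Monte Carlo error well inside the asserted bands.

## Known limitations

* The MI permutation null is pooled across pairs (one global threshold),
  not per-pair — appropriate at regulome scale, conservative for genes
  with unusual marginal structure.
* DPI with many strong co-regulators can remove true edges whose MI is
  attenuated; precision/recall trade off through `alpha`, `consensus` and
  `dpi_tolerance`.
* Per-sample dES depends on the chosen ranking transform; alternatives
  (median/MAD) are provided but not exhaustively characterized.
* The linear-Gaussian generator cannot certify behavior under count-based
  (RNA-seq) noise; applying the pipeline to RNA-seq requires upstream
  variance stabilization.
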