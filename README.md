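# mrnet — master-regulator discovery from expression compendia

`mrnet` implements a complete master-regulator (MR) discovery pipeline for
tumor expression studies: from gene-by-sample log2 expression matrices with
tumor (PT) / adjacent non-tumor (NT) annotation, through a TF-centered
mutual-information network, to regulon enrichment, per-sample regulon
activity and survival stratification. It is aimed at computational
biologists who want the full chain — and a synthetic-cohort generator with
planted ground truth to validate every stage end to end.

## The method

1. **Preprocessing.** Duplicate gene rows are collapsed (max-mean row, or
   averaging); multi-batch data are adjusted by a parametric empirical-Bayes
   location/scale model (per-gene standardization, per-batch effects shrunk
   toward priors fitted across genes by moments).
2. **Signature.** PT-vs-NT differential expression by a moderated t-statistic:
   the pooled per-gene variance s² (df = n−2) is shrunk toward a prior
   (d₀, s₀²) fitted on the log residual variances,
   s̃² = (d₀s₀² + df·s²)/(d₀ + df), with p-values on d₀ + df degrees of
   freedom, BH-adjusted. The signature keeps genes with FDR < 0.05 and
   linear fold change > 1.5.
3. **Network.** For each TF and candidate target, mutual information of the
   rank-transformed profiles on an equal-frequency B×B grid
   (B = ⌊√(n/5)⌋), bias-corrected and clipped at 0, in nats. Edges must
   exceed a pooled permutation-null threshold (empirical 1−α quantile,
   α = 10⁻³) in ≥ 95% of 100 bootstrap resamples; triangles
   (TF₁, TF₂, target) are pruned by the data processing inequality (the
   strictly weakest TF–target edge is removed, with an absolute tolerance
   margin); each surviving edge's mode is the sign of the TF–target Pearson
   correlation.
4. **MRA.** Each regulon is tested for overlap with the signature by the
   one-sided hypergeometric tail against the expression universe, with odds
   ratios and BH FDR; TFs are ranked by p. Helpers compute cross-cohort rank
   agreement (Pearson on −log₁₀ p), consensus MR sets, and ROC AUC against
   external labels.
5. **Regulon activity.** A regulon with modes splits into positive (A) and
   negative (B) targets; each tail gets a weighted Kolmogorov–Smirnov GSEA
   enrichment score on a ranked gene list, and activity is
   dES = ES_A − ES_B (per phenotype ranking, or per sample using gene-wise
   z-scores against the cohort). A highly positive dES means the regulon is
   induced.
6. **Survival.** Samples are stratified as active (dES>0, ES_A>0, ES_B<0),
   repressed (dES<0, ES_A<0, ES_B>0) or inconclusive; the two large groups
   split in half at their median dES. Kaplan–Meier curves and log-rank tests
   compare the strata.
7. **Interactions & subtypes.** Regulon pairs are profiled by Jaccard
   overlap, shared-target mode agreement (co-activated / co-repressed /
   opposing) and dES correlation; samples are subtyped by consensus
   hierarchical clustering (average linkage, 1−Pearson distance) over
   subsampled clusterings.

The synthetic generator plants all of this: a signed TF→target network with
known coupling strengths, tumor-active TFs, batch effects, and exponential
survival whose hazard follows planted TF activity — so precision, recall,
calibration and power are measurable exactly.

## Worked example

`examples/` contains one narrative script per capability. For instance
network inference plus MRA (`python examples/02_network_and_mra.py`):

```
permutation MI threshold: 0.0700 nats
edges after threshold / bootstrap / DPI: 4868 / 4821 / 1031
vs planted network: precision 0.903, recall 0.931, mode agreement 1.000

top 10 master regulators (hypergeometric enrichment):
       regulon_size  overlap             p  odds_ratio           fdr
TF006            60       60  8.137799e-42  501.148344  1.627560e-40
TF016            55       55  2.844248e-38  453.721569  2.844248e-37
...
10/10 of the top-ranked TFs were planted as tumor-active.
```

The threshold is the MI level below which TF–gene dependence is
indistinguishable from the permutation null; the three edge counts show the
filtering cascade; precision/recall compare the surviving edges with the
planted network; and the MRA table ranks TFs by how strongly the tumor
signature concentrates in their regulons — here the ten planted-active TFs
occupy exactly the top ten ranks. The other examples cover the signature
(`01`), per-sample dES with survival stratification (`03`, log-rank
p ≈ 4e-17 between active-high and repressed tumors with a planted
protective regulon), and interactions/subtyping (`04`).

A thin CLI mirrors the stages for shell use:
`mrnet simulate|preprocess|signature|network|mra|activity|survival|interact|cluster|run-all`
(see `mrnet <subcommand> --help`).

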