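# Methods

## Problem and model

Bulk tumour expression profiles mix malignant and non-malignant cells, so the
estimated fraction of malignant cells — tumour purity — confounds
miRNA–mRNA co-expression: a miRNA enriched in immune cells and a gene
expressed by those same cells will correlate even with no regulatory link.
The scan implemented here asks, for every miRNA × immune-pathway pair,
whether the genes most associated with the miRNA *after removing the purity
component* concentrate in that pathway.

The pipeline has three stages per miRNA *i*:

1. **Purity-adjusted association.** For each gene *j*, with Pearson
   correlations `R_MG` (miRNA–gene), `R_MP` (miRNA–purity) and `R_GP`
   (gene–purity) over the n shared samples, the first-order partial
   correlation is

       PCC = (R_MG − R_MP·R_GP) / (√(1 − R_MP²) · √(1 − R_GP²)),

   with a two-sided p-value from `t = PCC·√((n−3)/(1−PCC²))` on n−3
   degrees of freedom (one covariate partialled out). The gene is then
   scored by the rank score `RS = −log10(p) × sign(PCC)`.

2. **Enrichment on the RS-ranked list.** Genes are ordered by RS
   (descending; ties by gene id for determinism). For a pathway of k genes
   in a universe of N, the weighted Kolmogorov–Smirnov running sum advances
   by `|RS|^w / Σ_hits |RS|^w` at pathway members and retreats by `1/(N−k)`
   elsewhere; the enrichment score ES is the signed deviation of maximal
   absolute value (exact magnitude ties resolve to the positive deviation).
   The default weight exponent is w = 1; w = 0 recovers the classic
   unweighted KS statistic.

3. **Permutation significance and miRES.** The null draws random gene sets
   of size k from the ranked universe. The p-value conditions on the sign
   of the observed ES and uses a +1 pseudocount:
   `p = (1 + #{null: same sign, |ES_null| ≥ |ES_obs|}) / (1 + #{null: same sign})`,
   so p ∈ (0, 1]. ES sign and p combine into
   `miRES = 1 − 2p` (ES > 0) or `2p − 1` (ES < 0), which lives in [−1, 1].
   A pair is significant when |miRES| > 0.995 **and** its
   Benjamini–Hochberg FDR — pooled over all miRNA × pathway pairs of the
   scan — is below 0.05. Note that miRES crosses zero at p = ½, so it
   carries the ES sign only for p < ½; this is a property of the defining
   formula, not a defect of the estimate.

## Numerical and sampling choices

- **p-value floor.** p-values are floored at 1e-300 before `−log10`, so RS
  stays finite; RS is only used for ordering and as enrichment weights.
- **Fast ES evaluation.** Only the running sum's values just before and
  just after each hit can attain the maximal deviation, so each permuted
  set costs O(k) rather than O(N); permutations are evaluated in vectorized
  blocks.
- **Shared nulls.** Within one miRNA the null distribution depends only on
  the ranked weights and the set size, so one batch of permutations serves
  every pathway of that size. P-values of same-size pathways of one miRNA
  therefore share Monte-Carlo noise; across miRNAs the draws are
  independent streams spawned from the single scan seed.
- **Two-stage permutation refinement.** With m scanned pairs, BH
  significance at level α requires p ≲ α/m, which is finer than the
  attainable floor `1/(1 + #same-sign)` of the default 1000 permutations
  (about 2/n_perm). Pairs whose same-sign exceedance count falls at or
  below `refine_count` (default 9) after the first pass are therefore
  re-estimated from `n_perm_refine` (default 20 000) fresh permutations.
  Under a null scan only a few per cent of pairs trigger refinement, so the
  scan stays near the 1000-permutation cost while small p-values get the
  resolution the dual threshold needs.
- **Determinism.** Every stochastic operation takes an explicit integer
  seed; the scan spawns one independent stream per miRNA from it, so
  results (including record order) are bit-reproducible.
- **No-purity fallback.** Without a purity vector the association reduces
  to the plain Pearson correlation; its p-value then uses the standard
  n−2 degrees of freedom, and a warning is emitted.
- **Degenerate inputs.** Constant vectors are rejected where a correlation
  is undefined; constant expression rows z-score to zero with a warning; a
  gene set whose hit weights are all zero falls back to the unweighted
  statistic with a warning; ES exactly 0 (miRES undefined) yields a
  warned-about zero record in the scan and an error in the scalar API.

## Risk signature and survival

The packaged three-miRNA signature scores a sample as
`0.015·z(miR-216a-5p) − 0.035·z(miR-194-3p) − 0.124·z(miR-3677-3p)` on
per-cohort z-scored expression (z-scoring is repeated per dataset so the
coefficients transfer across platforms), with high risk defined as a score
strictly above the packaged cutoff 0.05. Refitting the penalized Cox model
that produced these constants is out of scope by design: the constants are
the model; the package's job is to apply and evaluate it. On a new cohort
the cutoff can be re-derived by the maximally selected log-rank statistic:
candidate cutpoints are midpoints of adjacent sorted unique scores whose
groups each hold at least `minprop` (default 0.1) of subjects, and the
candidate maximizing the log-rank chi-square wins, ties going to the
smaller value. The cutpoint search evaluates an in-package vectorized
log-rank profile over all candidates at once; the scalar two-group log-rank
test is delegated to lifelines, and the two routes are checked against each
other in the tests. Benjamini–Hochberg adjustment is delegated to
statsmodels behind `bh_fdr`.

## Per-sample pathway scores

`ssgsea` orders each sample's genes by expression (descending, ties by gene
id), assigns rank values N..1 with weights `rank^alpha` (alpha = 0.25), and
scores a set as the summed difference between the weighted in-set ECDF and
the uniform out-of-set ECDF — the usual single-sample enrichment
construction for immune-cell infiltration. Scores are reported raw by
default; an optional flag min–max scales each set to [0, 1] across samples
for cross-set display.

## Drug screen

Given a drugs × samples table of log2 IC50 values, a drug is selected when
both hold: |Pearson r| with the continuous risk score > 0.3 at BH-FDR
< 0.05 across drugs, and |mean(high) − mean(low)| > 0.5 on the log2 scale
with Welch-t BH-FDR < 0.05 across drugs. Welch's unequal-variance t-test is
used because group variances are not assumed equal. FDR is pooled per
criterion over drugs. Constant IC50 rows are excluded with a warning.

## Synthetic cohorts

The generator (`immumirna.synth`) emulates the structure the pipeline
assumes, with ground truth recorded at generation time. Defaults define the
standard study conditions used throughout the tests: 200 samples, 50
miRNAs, 2000 genes, five disjoint 40-gene pathways.

- Purity ~ Uniform(0.3, 0.9).
- miRNA log-expression: baseline Uniform(3, 6) (natural-log scale), plus a
  per-miRNA purity slope Uniform(−δ, δ) with δ = 1, plus N(0, 0.5²) noise.
  Gene log-expression is built the same way (baseline Uniform(2, 6), slope
  bound b = 1). A fraction (5%) of features get baseline −1 so they are
  mostly zero and exercise the count filter.
- A planted pair adds `±effect · z(miRNA log-expression)` to 60% of the
  pathway's genes (effect 0.8 by default — a strong but realistic
  regulator given noise sd 0.5 and purity confounding).
- Counts are Poisson around the exponentiated log-expression, so the
  count-level zero filter and library-size normalization are exercised end
  to end.
- Survival: a true score (fixed linear combination of the leading miRNAs'
  z-scored log-expression) enters a Weibull proportional-hazards model,
  hazard multiplier `exp(β_surv·score + log(hr_step)·1{score > cutpoint})`
  with shape 1.5, scale 5 time-units and independent Exponential(8)
  censoring (roughly a third of subjects censored). The step term
  (hr_step > 1) creates a true cutpoint for recovery experiments; by
  default it is off and the hazard is log-linear in the score.

What the generator does **not** emulate: RNA-seq library-size variation and
overdispersion, correlated gene–gene structure beyond the planted effects
and shared purity, overlapping pathways, pathway-size heterogeneity, and
informative censoring. Passing tests therefore show that the statistics
recover the planted structure under the stated model, not that they are
robust to every property of real cohorts.

## Problem sizes used in the checks

Oracle-equivalence checks run at tiny sizes (universes of 5–30 items) where
exhaustive enumeration is exact. Calibration uses 2000 null replicates
(partial-correlation p-values, n = 50), 500 replicates (log-rank p-values,
n = 200) and 20 null cohorts at the default dimensions. Recovery uses 20
seeds each for the planted regulator (β = 0.8, n = 200), the step-hazard
cutpoint (HR = 3, n = 300) and the drug screen (one planted drug among 20
null drugs, n = 80).

## Known limitations

- Gene-set permutation treats genes as exchangeable; correlated genes (for
  example co-regulated targets of *another* miRNA) inflate enrichment
  relative to this null, a standard caveat of gene-set permutation GSEA.
  The null-cohort false-positive calibration covers the no-signal case
  only.
- The refined permutation p is still Monte-Carlo; reported FDRs near the
  threshold carry sampling noise of order `1/√n_perm_refine`.
- The packaged coefficients apply to z-scored expression; applying them to
  unstandardized data shifts the score scale and invalidates the packaged
  cutoff (the code warns).
- miRES at ES exactly 0 is undefined; the scan reports 0 with a warning.
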