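# Methods

This note documents the statistical models, defaults, and design
decisions behind `strata-tx`, and what the synthetic-data experiments do
and do not establish about behaviour on real data.

## Cohort model and synthetic data

Counts are generated as a gamma–Poisson (negative-binomial) mixture: for
gene *g* and sample *j*,

```
count_gj ~ Poisson(lambda_gj),  lambda_gj ~ Gamma(shape = 1/alpha_g, scale = alpha_g * mu_gj)
log mu_gj = b_g + beta_g · z_j + log2FC_gs · ln(2) · dx_j + log sf_j
```

so that `Var = mu + alpha * mu^2`, the parameterization used by the
downstream GLM. Per-gene baselines `b_g` and dispersions `alpha_g` are
log-normal; `z_j` are the z-scored nuisance covariates (Age uniform over
60–95 years, RIN and PMI truncated normal: RIN mean 7.5 sd 1 on [2, 10],
PMI mean 10 sd 5 hours on [0.5, 40]); `sf_j` are log-normal library-size
multipliers (sd 0.25); `dx_j` is the 0/1 diagnosis indicator. Diagnosis
effects are planted on a configurable fraction of genes (default 0.1)
independently per stratum, with |L2FC| ~ Normal(1, 0.25) and a fair-coin
sign. The default stratum layout is the 119-subject two-sex design
(female 36 CTL / 28 AD, male 39 CTL / 16 AD). PMI values are missing
completely at random (default rate 0.1) and are represented as true
missing values — imputation to the fixed sentinel −1 is an explicit
pipeline stage, so the imputation rule itself is testable.

Default generator magnitudes (baseline log-mean 4.0 ± 1.2 giving median
counts of a few dozen, median dispersion 0.1, covariate effect sd 0.1 on
the natural-log scale) were chosen once as typical of filtered bulk
brain RNA-seq; there is no empirical basis in any single dataset, and
they are surfaced in `SimConfig` rather than buried.

What the generator does **not** emulate: gene–gene correlation,
batch/plate effects beyond the three covariates, covariate–diagnosis
confounding (covariates are drawn independently of diagnosis), GC or
length biases, and read-level artifacts. Passing recovery tests
therefore demonstrate correctness of the estimators under the stated
model, not robustness to real-data pathologies such as confounded
designs or outlier samples.

In synthetic pipeline mode the gene-set collection contains (a) pure
"planted" sets equal to each stratum's truly up-/down-regulated genes,
(b) "signal" sets mixing 30–80 % planted genes with background genes —
because real pathway collections spread a perturbation across many
partially overlapping sets — and (c) random sets (default 150). The
synthetic literature corpus assigns disease-associated labels a true
co-mention proportion of 0.3 against a 0.02 background, with log-normal
total mention counts.

## Variance partitioning

Per gene, the fixed-effect linear model
`log2(count/sf + 1) ~ Age + RIN + PMI + Diagnosis` is fit by OLS. Each
term receives its marginal ΔR² (full-model R² minus the R² of the model
refit without that term), the ΔR² values are rescaled to sum to the
full-model R², and the residual fraction is 1 − R², so fractions sum to
1 (±1e−8). This is a deliberate simplification of mixed-model variance
partitioning: with one two-level factor and three continuous covariates,
random effects add machinery without changing the quantity of interest.
Collinear covariates shrink every marginal ΔR²; the rescaling then
attributes shared variance proportionally. Zero-variance genes are
flagged with residual 1 and never retained by the filter. A constant
covariate is a hard error naming the covariate.

The pre-differential-expression filter retains genes whose
diagnosis-attributed fraction is ≥ `min_diagnosis_fraction`
(default 0.01). The threshold is a free parameter: 0.01 removes genes
whose diagnosis signal is indistinguishable from the null ΔR² at cohort
sizes of tens of samples while keeping essentially all genuinely
affected genes in the synthetic experiments.

## Differential expression

- **Size factors**: median-of-ratios over genes nonzero in every
  sample, rescaled to geometric mean 1. With no all-nonzero gene the
  estimator refuses (suggesting a pseudo-reference), rather than
  guessing.
- **Dispersion**: per-gene method of moments on normalized counts
  within diagnosis groups, `alpha = max(0, (s² − m)/m²)`, pooled across
  groups with weights n−1. Because this cell-based estimate absorbs
  covariate-driven mean variation, the Wald stage refines it under the
  full design: after an initial GLM fit, alpha is re-estimated from the
  fitted means by solving `E[(y − mu)²] = mu + alpha mu²` on the
  residuals (with an n/(n−p) degrees-of-freedom correction) and the
  gene is refit once. Without the refinement the test is conservative
  when covariates genuinely shift expression. An optional shrinkage of
  log-dispersions toward a quadratic log-mean trend is available
  (`shrink_dispersion`, default off) for small cohorts.
- **Wald test**: per-gene NB log-linear fit (IRLS at fixed alpha via
  statsmodels; Poisson when alpha ≈ 0) of
  `count ~ Age + RIN + PMI + Diagnosis` with offset `log sf`. Nuisance
  columns are standardized for conditioning; the diagnosis coefficient
  is invariant to that rescaling. `L2FC = coef/ln 2` with **positive =
  up in AD**; p is the two-sided normal tail of coef/SE, floored at
  1e−300 so −log10(p) stays finite. Genes whose fit fails are flagged,
  excluded from BH and from ranking — never silently assigned values.
- **BH adjustment**: standard step-up with monotonicity (statsmodels),
  missing values excluded and reinserted.

## Pre-ranked GSEA

Genes are ordered by `−log10(p) × L2FC` (raw p; the volcano/top-gene
reporting uses the adjusted-p variant of the same statistic), ties
broken by lexicographic gene id so the ranking is deterministic. The
enrichment score is the classic weighted Kolmogorov–Smirnov running
sum: hits add `|rank|^exponent` normalized over the set's hits, misses
subtract `1/(N − N_hits)`; ES is the extremum of largest magnitude. If
a set's hits all carry rank exactly 0, equal weights are used so the
score stays defined.

The null is gene-sampling: `n_perm` (default 1000) random same-size
subsets of the ranked universe, drawn once per distinct set size in
sorted-size order so results are independent of collection order. For
permutations the running-sum extremum is evaluated only at the 2k
positions adjacent to hits, which is exact and keeps the null loop
vectorized. NES divides ES by the mean |null ES| of matching sign; the
permutation p is the sign-matched exceedance fraction with a +1
pseudocount (so p ≥ 1/(1 + #same-sign nulls) — at n_perm = 1000 the
finest attainable p is ≈ 0.002, which bounds how small BH q-values can
get when few pathways carry signal). q-values are BH over the
permutation p-values of all tested pathways — simpler and monotone
compared with the NES-binning FDR some GSEA implementations use, and
noted as a divergence from them. Defaults exponent 1, min_size 15,
max_size 500 are the conventional pre-ranked settings; significance is
called at q < 0.05 per direction.

Cross-stratum comparison intersects and differences the significant
calls per direction. In strict mode both results must have tested
identical pathway sets; the pipeline uses non-strict mode because the
per-stratum variance filter can push a set below `min_size` in one
stratum only (an untested set counts as not significant there). The
pipeline derives one shared GSEA permutation seed for all strata, so
byte-identical strata produce byte-identical enrichment tables.

## Literature Impact Z-score

`r = co-mentions / total mentions`, with `r = 0` (flagged) when a label
has zero total mentions — a convention, since the quantity is undefined.
Query normalization lower-cases, maps `_`/`-` to spaces, quotes
multi-word labels as exact phrases and conjoins the disease term
(configurable, default "Alzheimer's disease") with AND. One null sample
of `n_null` labels (default 1000) is drawn **without replacement** from
the pathway universe and shared across all scored labels; per-label
resampling is possible by calling `sample_null` per label but the
shared null is the default because a single null distribution is the
natural reading of the statistic. `Z = (r − mean)/sd` with the n−1
sample standard deviation; a degenerate null (sd ≈ 0) is an error
advising a more varied universe. Z is invariant under uniform scaling
of all corpus counts and under affine shifts applied to r and the null
alike. Live PubMed counts via NCBI E-utilities are optional, retried
with backoff, cached in the JSON count store, and never fabricated on
failure — unscored labels carry missing values.

## Pipeline, seeding, reproducibility

One master seed; each stage's seed is the first 8 hex digits of
SHA-256(`"{master}:{stage}"`) mod 2³¹, so stages are independently
reproducible and adding a stage never perturbs another stage's stream.
A stratum with fewer than 2 samples in either diagnosis group is
skipped with a prominent warning. Missing metadata other than PMI is an
error (only the PMI imputation rule is sanctioned). The run manifest
records config, stage seeds, package version and per-stage gene counts;
in synthetic/fixture mode a rerun from the same config writes
byte-identical outputs (the manifest contains no timestamps for this
reason). Volcano classification uses padj < 0.05 and |L2FC| ≥ 1; the
top-20 table orders by |−log10(padj) × L2FC| regardless of sign.

## Problem sizes in tests and the acceptance script

The statistical checks use desk-scale sizes chosen to make their Monte
Carlo error small relative to the tolerance being asserted: type-I
error on 2000 null genes at 60+60 samples (binomial SE ≈ 0.005 against
a [0.03, 0.07] band), L2FC recovery on 100 planted genes (SE ≈ 0.02
against ±0.15), variance-share recovery at n = 500 (±0.05), GSEA
planted recovery at n_perm = 1000 with a 40-set background collection
(permutation-p granularity bounds attainable q; see above), and the
exhaustive ES oracle over every subset of universes up to size 8. The
acceptance script runs the full pipeline at the default 2000 genes,
119 subjects, 1000 permutations and a 1500-label universe.

## Known limitations

- The NB engine is intentionally minimal: no outlier refitting,
  independent filtering, LFC shrinkage, or likelihood-ratio tests.
  Effect estimates on very low-count genes are noisy and their Wald p
  slightly anticonservative in general; at the default simulated depths
  calibration holds (see the acceptance output).
- Variance partitioning assumes fixed effects and continuous/two-level
  covariates only; repeated measures or batch factors need a
  mixed-model tool.
- The ES permutation null samples genes, not phenotypes; inter-gene
  correlation in real data therefore inflates significance relative to
  a phenotype-permutation null, a known property of pre-ranked GSEA.
- Pathway-label queries do no synonym or MeSH expansion; the
  literature statistic measures co-mention of the literal phrase, and
  label phrasing affects r.
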