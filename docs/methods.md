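# Methods

## Overview

`tilsig` derives a prognostic gene panel from a two-population T-cell
expression contrast and evaluates it on an expression + survival cohort.
The statistical machinery is deliberately conventional; the package's
specific content is the composition — candidate funnel, survival-trend
retention rule, ratio-of-means score, percentile stratification — plus a
synthetic-data layer that makes every stage testable against planted truth.

## Differential expression

Inputs are linear TPM matrices (log2(x+1) input is back-transformed).
For each gene the fold change is

    log2FC = log2((mean_A + c) / (mean_B + c)),    c = pseudocount (default 1)

on linear group means, and the p-value comes from a test on
log2(x + c) values: Welch two-sample t by default, with Wilcoxon rank-sum
and paired t (pairing by column order) as options. The contrast's own test
is configurable because TPM-scale group comparison has no single canonical
test; Welch on logs is the distribution-light default. Genes constant and
identical in both groups get p = 1 and class `ns`; constant but different
get p = 0. Volcano classification calls a gene `up` when
log2FC ≥ fc_threshold and p ≤ p_threshold (`inclusive`, the default) or
with strict inequalities (`inclusive=false`); `down` symmetric. FDR is
Benjamini–Hochberg step-up throughout, implemented directly (and
cross-checked against statsmodels in the tests).

Z-score matrices standardize each gene row to mean 0, sample SD (ddof = 1)
1; constant rows map to zero and are flagged.

## Signature derivation

* **Candidates.** The top K (default 100) genes per volcano class, ranked
  by |log2FC| descending, ties by smaller p then lexicographic symbol. A
  class smaller than K is returned whole with a warning.
* **Annotation.** Candidates are matched to the cohort's gene space by
  exact symbol comparison (case-folding optional); the annotated/missing
  partition is retained as provenance.
* **Trend filter.** Per annotated gene a direction of association with
  disease-specific death is computed on patients with usable DSS:
  * `event_mean` (default): sign of (mean log2(x+1) among DSS-event
    patients − among event-free patients). Assumption-light; uses the event
    indicator only, ignoring time and censoring.
  * `cox_sign`: sign of the univariate Cox coefficient on standardized
    log2(x+1) expression, optionally gated at Wald p ≤ α. Uses the full
    time-to-event structure; the gate trades recall for specificity
    (null genes pass a one-sided gate at ≈ α/2).
  Up-candidates are retained when the direction is positive, down-candidates
  when negative. The funnel counts (candidates → annotated → retained per
  arm) are logged and serialized with the panel.
* **ppScore.** Per patient, mean linear-scale expression of the retained up
  arm divided by that of the retained down arm. Averaging on the linear
  scale makes the score exactly invariant to any positive global rescaling
  of the matrix and to gene order within arms (floating-point agreement to
  ~1e-12 relative). A log-scale variant is exposed. Patients whose down-arm
  mean is zero are flagged `excluded` rather than scored.
* **Stratification.** The threshold is the linear-interpolation quantile
  (default median) of the scoreable patients' scores; score > threshold is
  `high`, score ≤ threshold `low` — ties go low. With an even number of
  distinct scores this yields an exact half split (18 patients → 9/9);
  group sizes always differ by at most one.

## Survival statistics

* **Kaplan–Meier** product-limit estimator, implemented directly. Subjects
  censored at an event time stay in the risk set at that time and leave
  afterwards (censored-after-event convention). With no censoring the curve
  equals the empirical survival function.
* **Log-rank** two-group test and the **multivariate Cox** model delegate
  to lifelines (Efron tie handling, Wald 95% CIs). Categorical covariates
  are dummy-encoded against fixed reference levels (stage I, age < 55,
  female, cecum, no residual disease); patients with a `missing` level or
  absent DSS are dropped (complete case), constant covariates are an error,
  and < 5 complete cases per parameter triggers a warning. The test suite
  additionally checks both against independent brute-force oracles
  (risk-table O−E enumeration; grid-search maximization of the partial
  likelihood to 1e-4).
* A **vectorized univariate Cox** (Newton–Raphson on the Breslow partial
  likelihood, one independent scalar model per column) supports per-gene
  screening in the trend filter; with tie-free data it agrees with
  lifelines to ≤ 1e-4 (verified in tests). Breslow vs Efron differs only
  at tied event times, where single-gene screening precision is not
  material.
* **Stage χ²** is the Pearson test without continuity correction on the
  2 × stage table; missing-stage patients are excluded and counted, empty
  margins dropped with a warning, and expected counts < 5 set a flag.

## Association analyses

Gene–fraction correlation is simple least-squares of fraction on
log2(x+1) expression; the reported R is the signed Pearson coefficient and
p the two-sided slope test (identical to the Pearson test); Spearman is an
option. Constant vectors are flagged undefined and excluded from the
significance denominator. Over-representation analysis is the textbook
hypergeometric upper tail P(X ≥ k) with fold enrichment (k/q)/(K/N) and BH
across terms — a deliberate, offline replacement for web-service functional
annotation; term lists are supplied as GMT. Curated marker panels
(immune checkpoints, Treg, Th1, Th2, Th17) ship as packaged YAML; the Th17
panel uses HIF1A as the hypoxia-inducible-factor symbol.

## Synthetic data: what it emulates, and what it does not

* **TIL contrast.** log2(x+1) values are Normal per gene
  (μ_g ~ N(base, 1.5) clipped ≥ 1, σ_g ~ U(sd range)) with a fixed mean
  shift ±effect planted in group A for a fraction of genes, back-transformed
  and renormalized so columns sum to 1e6 (TPM). Defaults — 10000 genes,
  18 samples per group, 10% of genes planted per direction at effect 3 —
  reproduce the structure of a sorted CD4⁺ vs CD8⁺ TIL comparison in which
  roughly two thousand genes pass the volcano thresholds and the top-100
  per arm is a strict subset. Renormalization introduces a real
  compositional shift (all of group A's fold changes move by −log2 of the
  planted arms' net library change) and the pseudocount distorts fold
  changes of very low-expressed genes when the generative scale differs
  from the TPM scale; recovery tests therefore use balanced arms at a
  scale-matched base mean. Not emulated: count noise, batch effects,
  library-size artifacts, gene–gene correlation.
* **Survival cohort.** The latent risk score z is the standardized
  difference of mean log2(x+1) expression between planted up- and
  down-risk genes; event times are Exponential with rate
  baseline·exp(β·z), censoring independent Exponential, so the Cox model is
  correctly specified and β is recoverable. Defaults
  baseline = 4e-4/day and censoring = 6e-4/day give an event fraction of
  b/(b+c) = 40% at β = 0, matching a mature disease-specific-survival
  registry; 5.5% of patients lack DSS annotation (flagged unusable, so a
  512-patient cohort yields ≈ 484 usable, mirroring registry gaps). Stage
  is an ordinal cut of sa·z + √(1−sa²)·ε with population stage mix
  18/36/30/16%, so `stage_association` gives the χ² test a plantable
  alternative. Age, gender, anatomic location (7 levels) and residual
  disease are independent draws — the Cox adjustment set is realistic in
  shape but carries no confounding by construction.
* **Immune fractions.** CD4/CD8 fractions are clipped Gaussians
  (0.25 ± 0.05, 0.20 ± 0.05); a coupled gene shares the fraction's latent
  factor so its population Pearson correlation equals the requested r
  exactly (both margins linear in the same Gaussian).

Consequences for interpretation: passing tests demonstrate calibration and
planted-effect recovery under a correctly specified, independence-heavy
model — they do not certify behaviour under count overdispersion,
confounded covariates, informative censoring or correlated genes. Two
pipeline outputs are null by construction under the default generator: the
within-TIL high-vs-low ppScore contrast (no patient-level heterogeneity is
planted in the TIL matrices, so its FDR < 0.01 gene count is ≈ 0) and the
gene–fraction correlations (fractions are simulated independently of the
cohort expression, so significance rates sit at the nominal 5%).

## Numerical choices and degenerate inputs

Quantiles use linear interpolation; stratification ties go to the low
group. Duplicate gene rows collapse by per-sample maximum at read time
(logged). BH q-values are capped at 1. The univariate Cox Newton iteration
clips linear predictors at ±30 and steps at ±2 per iteration, stopping at a
1e-10 step norm; constant columns return NaN. All-identical scores, empty
retained arms, cohorts without events, all-zero count columns and
sub-minimum sample counts raise errors rather than returning silent
defaults. Every simulation consumes a `numpy` Generator seeded from the
config seed via `SeedSequence`, and the pipeline writes artifacts with
fixed float formatting, so identical config + seed reproduce byte-identical
files (SHA-256 checksums recorded in the run report).

## Problem sizes

The shipped tests and the acceptance script run the pipeline at the study
scale it emulates — 10000 genes, 18 + 18 TIL samples, 512 patients — and
the Monte-Carlo checks use 20–500 replicate seeds per property (100 for
parameter-recovery intervals, 500 for null calibration at α = 0.05),
sizes at which the binomial error of an observed rate is well inside the
asserted bands.

## Known limitations

* The trend filter's `event_mean` mode ignores follow-up time; under heavy
  or informative censoring its direction estimate degrades (use
  `cox_sign`).
* The ppScore's linear-scale averaging weights genes by absolute
  expression, so a few highly expressed panel genes dominate the score;
  this is inherent to a ratio-of-means definition and is why the score
  correlates imperfectly with an equal-weight latent risk.
* Gene identifiers are plain symbols; there is no identifier-mapping layer,
  and annotation against a cohort is exact string matching.
* No proportional-hazards diagnostics, time-varying covariates or
  competing-risks handling.
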