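# tilsig

Derivation and evaluation of a **poor-prognosis gene signature (ppScore)**
from sorted tumor-infiltrating lymphocyte (TIL) transcriptomes, with a fully
synthetic acceptance surface.

## The problem

Bulk RNA-seq of FACS-sorted CD4⁺ and CD8⁺ TILs from tumor resections yields
two gene × sample TPM matrices. Contrasting them identifies genes deregulated
in the CD4⁺ compartment; the top deregulated genes can then be screened
against a large expression + survival cohort (e.g. a TCGA-style colorectal
dataset) to extract a prognostic panel. `tilsig` implements that workflow as
a reusable, testable pipeline:

1. **Differential expression** — TPM quantification, Welch t (or Wilcoxon /
   paired t) on log2(TPM+1), volcano classification at |log2 FC| ≥ 2 and
   p ≤ 0.05, Benjamini–Hochberg FDR.
2. **Candidate selection** — top-K (default 100) up- and down-regulated
   genes ranked by |log2 FC|.
3. **Trend filter** — each candidate annotated in the validation cohort is
   kept only if its expression direction tracks poorer disease-specific
   survival (DSS): by default the sign of the mean log-expression difference
   between DSS-event and event-free patients; alternatively the sign of a
   univariate Cox coefficient, optionally gated at p ≤ α.
4. **ppScore** — per patient,

   ```
   ppScore_i = mean_{g ∈ up-panel} x_gi / mean_{g ∈ down-panel} x_gi
   ```

   on linear-scale expression, followed by a median (or any percentile)
   split into high/low strata.
5. **Survival statistics** — Kaplan–Meier curves, two-group log-rank test,
   multivariate Cox proportional hazards (ppScore stratum + stage, age band,
   gender, anatomic location, residual disease; Efron ties), and a Pearson
   χ² test of the stage distribution between strata.
6. **Associations** — per-gene Pearson/Spearman correlation of signature
   genes with deconvolution-estimated CD4/CD8 immune fractions, curated
   T-cell panel (checkpoint, Treg/Th1/Th2/Th17) Z-score matrices, and
   hypergeometric over-representation analysis against GMT gene sets.

Because matched patient data cannot ship with the package, the
`tilsig.synthetic` module generates every input with planted ground truth:
log-normal TPM matrices with planted fold changes, survival cohorts whose
exponential hazard is log-linear in a latent score built from planted risk
genes, and immune-fraction tables with Gaussian-copula gene coupling. All
generators are deterministic under a fixed seed.

## Worked example

```bash
cat > config.yaml <<EOF
seed: 1
outdir: run1
cohort: {beta: 0.693, stage_association: 0.35}   # planted HR = 2 per SD
EOF
tilsig run-all --config config.yaml
```

This simulates 10000 genes × (18 + 18) TIL samples and a 512-patient
validation cohort, then runs every stage. With seed 1 the report prints
(abridged):

```
n_deg: 1953  (960 up, 993 down)
funnel up:   100 candidates -> 99 annotated -> 56 retained
funnel down: 100 candidates -> 98 annotated -> 56 retained
n_high: 256   n_low: 256
logrank:      p = 2.53e-04
cox_ppscore:  HR = 1.83 (95% CI 1.34-2.49), p = 1.36e-04
chi_squared_stage: p = 0.343
```

Reading: the planted contrast produces ~2000 differentially expressed genes;
nearly all top-100 candidates are annotated in the cohort; the trend filter
keeps the majority whose direction agrees with poorer DSS; the resulting
ppScore splits the cohort 256/256, and the high stratum has significantly
poorer survival with a hazard ratio near the planted value of 2 after
adjusting for clinical covariates. Each stage is also available as a library
function (`tilsig.differential_expression`, `tilsig.trend_filter`,
`tilsig.compute_ppscore`, `tilsig.fit_cox`, …) and as a CLI subcommand
(`simulate`, `deg`, `derive-signature`, `score`, `survival`, `correlate`,
`enrich`, `panels`).

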