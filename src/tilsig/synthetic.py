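"""Seeded synthetic-data generators with planted ground truth.

Three generators mirror the data the pipeline consumes:

* paired two-population TIL expression matrices with planted per-gene fold
  changes (log-normal TPM model),
* survival cohorts whose exponential hazard is log-linear in a latent score
  built from planted risk genes, with independent exponential censoring,
* immune-fraction tables (CD4/CD8) with optional Gaussian-copula coupling
  between chosen genes and a fraction.

Every generator is a pure function of its parameters and seed, so identical
inputs reproduce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix, Scale, SurvivalCohort, GeneSetCollection

__all__ = [
    "ExpressionSimParams",
    "SurvivalSimParams",
    "SimTruth",
    "simulate_til_expression",
    "simulate_survival_cohort",
    "simulate_immune_fractions",
    "simulate_gene_sets",
]

STAGES = ("I", "II", "III", "IV")
# approximate stage mix of a large colorectal adenocarcinoma cohort
STAGE_PROBS = (0.18, 0.36, 0.30, 0.16)
LOCATIONS = ("cecum", "ascending colon", "transverse colon", "descending colon",
             "sigmoid", "rectosigmoid", "rectum")
LOCATION_PROBS = (0.14, 0.12, 0.08, 0.08, 0.24, 0.16, 0.18)
AGE_BANDS = ("<55", "55-64", "65-74", ">74")


@dataclass
class SimTruth:
    """Planted ground truth attached to a simulated dataset."""

    gene_class: pd.Series            # per gene: "up" / "down" / "null"
    latent_score: pd.Series | None = None   # per patient, standardized
    beta: float | None = None               # planted log-hazard per SD of score

    @property
    def up_genes(self) -> list[str]:
        return list(self.gene_class.index[self.gene_class == "up"])

    @property
    def down_genes(self) -> list[str]:
        return list(self.gene_class.index[self.gene_class == "down"])


@dataclass
class ExpressionSimParams:
    """Two-population expression simulation: log2(x+1) values are Normal
    per gene with a planted mean shift in group A, back-transformed to linear
    and renormalized to TPM (columns sum to 1e6).

    ``frac_up``/``frac_down`` are the fractions of genes planted up/down in
    group A; ``effect_log2fc`` the planted shift on the log2 scale;
    ``gene_sd_range`` the per-gene noise SD range on the log2 scale. With
    ``paired`` a shared per-patient intercept couples the two groups.
    """

    n_genes: int = 10000
    n_samples_per_group: int = 18
    paired: bool = False
    frac_up: float = 0.1
    frac_down: float = 0.1
    effect_log2fc: float = 3.0
    base_mean_log2: float = 5.0
    gene_sd_range: tuple[float, float] = (0.3, 0.8)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frac_up < 0 or self.frac_down < 0 or self.frac_up + self.frac_down > 1:
            raise ValueError("frac_up + frac_down must lie in [0, 1]")
        if self.effect_log2fc < 0:
            raise ValueError("effect_log2fc must be >= 0")
        lo, hi = self.gene_sd_range
        if lo <= 0 or hi < lo:
            raise ValueError("gene_sd_range must be positive and ordered")


def _tpm_normalize(linear: np.ndarray) -> np.ndarray:
    colsum = linear.sum(axis=0)
    colsum[colsum == 0] = 1.0
    return linear / colsum * 1e6


def simulate_til_expression(
    params: ExpressionSimParams,
) -> tuple[ExpressionMatrix, ExpressionMatrix, SimTruth]:
    """Simulate paired group-A / group-B TIL expression matrices.

    Returns ``(mat_a, mat_b, truth)`` with matrices on the linear TPM scale
    and ``truth.gene_class`` recording the planted per-gene class.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    genes = [f"G{i:05d}" for i in range(p.n_genes)]
    n_up = int(round(p.frac_up * p.n_genes))
    n_down = int(round(p.frac_down * p.n_genes))
    classes = np.array(["null"] * p.n_genes, dtype=object)
    order = rng.permutation(p.n_genes)
    classes[order[:n_up]] = "up"
    classes[order[n_up:n_up + n_down]] = "down"
    delta = np.where(classes == "up", p.effect_log2fc,
                     np.where(classes == "down", -p.effect_log2fc, 0.0))

    mu = np.clip(rng.normal(p.base_mean_log2, 1.5, size=p.n_genes), 1.0, None)
    sd = rng.uniform(*p.gene_sd_range, size=p.n_genes)
    n = p.n_samples_per_group
    log_a = (mu + delta)[:, None] + sd[:, None] * rng.standard_normal((p.n_genes, n))
    log_b = mu[:, None] + sd[:, None] * rng.standard_normal((p.n_genes, n))
    if p.paired:
        patient = rng.normal(0.0, 0.5, size=n)
        log_a += patient[None, :]
        log_b += patient[None, :]
    lin_a = _tpm_normalize(np.clip(np.power(2.0, np.clip(log_a, 0, None)) - 1.0, 0, None))
    lin_b = _tpm_normalize(np.clip(np.power(2.0, np.clip(log_b, 0, None)) - 1.0, 0, None))

    samples_a = [f"A{i + 1:02d}" for i in range(n)]
    samples_b = [f"B{i + 1:02d}" for i in range(n)]
    mat_a = ExpressionMatrix(pd.DataFrame(lin_a, index=genes, columns=samples_a),
                             Scale.LINEAR_TPM)
    mat_b = ExpressionMatrix(pd.DataFrame(lin_b, index=genes, columns=samples_b),
                             Scale.LINEAR_TPM)
    truth = SimTruth(pd.Series(classes, index=genes, name="gene_class"))
    return mat_a, mat_b, truth


@dataclass
class SurvivalSimParams:
    """Survival-cohort simulation with exponential event and censoring times.

    The per-patient latent score is the standardized difference between mean
    log2(x+1) expression of the planted up- and down-risk genes; the event
    hazard is ``baseline_rate * exp(beta * z)``. ``stage_association`` couples
    an ordinal stage draw to the latent score through a shared Gaussian.
    ``missing_dss_rate`` blanks DSS annotation for a random patient fraction
    (those patients are flagged unusable, mirroring real registry gaps).
    """

    n_patients: int = 512
    n_genes: int = 200
    risk_genes_up: tuple[str, ...] = ()
    risk_genes_down: tuple[str, ...] = ()
    beta: float = 0.0
    baseline_rate: float = 4.0e-4      # events per day
    censor_rate: float = 6.0e-4        # censorings per day
    stage_association: float = 0.0
    missing_dss_rate: float = 0.055
    genes: tuple[str, ...] = ()        # explicit gene space (overrides n_genes)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_rate <= 0 or self.censor_rate <= 0:
            raise ValueError("rates must be > 0")
        if not np.isfinite(self.beta):
            raise ValueError("beta must be finite")
        if not 0.0 <= self.stage_association <= 1.0:
            raise ValueError("stage_association must lie in [0, 1]")
        if not 0.0 <= self.missing_dss_rate < 1.0:
            raise ValueError("missing_dss_rate must lie in [0, 1)")


def simulate_survival_cohort(
    params: SurvivalSimParams,
    expression: ExpressionMatrix | None = None,
) -> tuple[SurvivalCohort, SimTruth]:
    """Simulate a survival cohort whose hazard depends on planted risk genes.

    If ``expression`` is not supplied, a null log-normal matrix over the
    requested gene space is generated internally.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    patients = [f"P{i + 1:04d}" for i in range(p.n_patients)]

    if expression is None:
        if p.genes:
            genes = list(p.genes)
        else:
            genes = [f"G{i:05d}" for i in range(p.n_genes)]
        for g in (*p.risk_genes_up, *p.risk_genes_down):
            if g not in genes:
                raise ValueError(f"planted risk gene {g!r} not in gene space")
        mu = np.clip(rng.normal(5.0, 1.5, size=len(genes)), 1.0, None)
        sd = rng.uniform(0.5, 1.0, size=len(genes))
        logv = mu[:, None] + sd[:, None] * rng.standard_normal((len(genes), p.n_patients))
        lin = _tpm_normalize(np.clip(np.power(2.0, np.clip(logv, 0, None)) - 1.0, 0, None))
        expression = ExpressionMatrix(
            pd.DataFrame(lin, index=genes, columns=patients), Scale.LINEAR_TPM)
    else:
        missing = [g for g in (*p.risk_genes_up, *p.risk_genes_down)
                   if g not in set(expression.gene_ids)]
        if missing:
            raise ValueError(f"planted risk genes absent from expression: {missing[:5]}")
        if expression.n_samples != p.n_patients:
            raise ValueError("expression sample count != n_patients")
        patients = list(expression.sample_ids)

    logx = expression.to_log2p1().values
    if p.risk_genes_up or p.risk_genes_down:
        up = (logx.loc[list(p.risk_genes_up)].mean(axis=0)
              if p.risk_genes_up else pd.Series(0.0, index=patients))
        down = (logx.loc[list(p.risk_genes_down)].mean(axis=0)
                if p.risk_genes_down else pd.Series(0.0, index=patients))
        raw = up - down
        sdv = raw.std(ddof=1)
        z = (raw - raw.mean()) / (sdv if sdv > 0 else 1.0)
    else:
        z = pd.Series(0.0, index=patients)
    zv = z.to_numpy()

    rate = p.baseline_rate * np.exp(p.beta * zv)
    t_event = rng.exponential(1.0 / rate)
    t_cens = rng.exponential(1.0 / p.censor_rate, size=p.n_patients)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(float)

    sa = p.stage_association
    u = sa * zv + np.sqrt(max(0.0, 1.0 - sa ** 2)) * rng.standard_normal(p.n_patients)
    from scipy.stats import norm
    cuts = norm.ppf(np.cumsum(STAGE_PROBS))[:-1]
    stage = np.array(STAGES, dtype=object)[np.searchsorted(cuts, u)]

    age = rng.normal(67.0, 12.0, size=p.n_patients)
    age_band = np.select(
        [age < 55, age < 65, age < 75], ["<55", "55-64", "65-74"], default=">74"
    ).astype(object)
    gender = rng.choice(["male", "female"], size=p.n_patients, p=[0.53, 0.47])
    location = rng.choice(LOCATIONS, size=p.n_patients, p=LOCATION_PROBS)
    residual = rng.choice(["no", "yes", "missing"], size=p.n_patients,
                          p=[0.85, 0.10, 0.05])

    time = time.astype(object)
    event = event.astype(object)
    if p.missing_dss_rate > 0:
        miss = rng.random(p.n_patients) < p.missing_dss_rate
        time[miss] = np.nan
        event[miss] = np.nan

    clinical = pd.DataFrame(
        {
            "dss_time": pd.to_numeric(pd.Series(time, index=patients)),
            "dss_event": pd.to_numeric(pd.Series(event, index=patients)),
            "stage": stage,
            "age_band": age_band,
            "gender": gender,
            "anatomic_location": location,
            "residual_disease": residual,
        },
        index=pd.Index(patients, name="patient_id"),
    )
    cohort = SurvivalCohort(clinical).attach_expression(expression)
    gene_class = pd.Series("null", index=expression.gene_ids, name="gene_class",
                           dtype=object)
    gene_class.loc[list(p.risk_genes_up)] = "up"
    gene_class.loc[list(p.risk_genes_down)] = "down"
    truth = SimTruth(gene_class, latent_score=z, beta=p.beta)
    return cohort, truth


def simulate_immune_fractions(
    n_patients: int,
    coupled_genes: Mapping[str, str] | Sequence[str] | None = None,
    coupling_r: float = 0.0,
    seed: int = 0,
    null_genes: Sequence[str] = (),
    fraction_params: Mapping[str, tuple[float, float]] | None = None,
) -> tuple[pd.DataFrame, ExpressionMatrix]:
    """Simulate CD4/CD8 immune fractions and a coupled expression matrix.

    ``coupled_genes`` maps gene symbol -> subset ("CD4" or "CD8"); a plain
    sequence couples every gene to CD4. Coupled genes share a Gaussian factor
    with the stated fraction so their population Pearson correlation equals
    ``coupling_r`` by construction; ``null_genes`` are independent of both
    fractions. Returns ``(fractions, expression)`` with the expression matrix
    on the log2(x+1) scale.
    """
    if not -1.0 <= coupling_r <= 1.0:
        raise ValueError("coupling_r must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    patients = [f"P{i + 1:04d}" for i in range(n_patients)]
    fraction_params = fraction_params or {"CD4": (0.25, 0.05), "CD8": (0.20, 0.05)}
    latents = {s: rng.standard_normal(n_patients) for s in fraction_params}
    fractions = pd.DataFrame(
        {s: np.clip(m + sd * latents[s], 0.0, 1.0)
         for s, (m, sd) in fraction_params.items()},
        index=pd.Index(patients, name="patient_id"),
    )

    if coupled_genes is None:
        coupled: dict[str, str] = {}
    elif isinstance(coupled_genes, Mapping):
        coupled = dict(coupled_genes)
    else:
        coupled = {g: "CD4" for g in coupled_genes}
    for g, s in coupled.items():
        if s not in latents:
            raise ValueError(f"unknown subset {s!r} for gene {g!r}")

    rows: dict[str, np.ndarray] = {}
    resid = np.sqrt(max(0.0, 1.0 - coupling_r ** 2))
    for g, s in coupled.items():
        eps = rng.standard_normal(n_patients)
        rows[g] = coupling_r * latents[s] + resid * eps
    for g in null_genes:
        if g in rows:
            raise ValueError(f"gene {g!r} listed as both coupled and null")
        rows[g] = rng.standard_normal(n_patients)
    genes = list(rows)
    mu = np.clip(rng.normal(5.0, 1.0, size=len(genes)), 1.0, None)
    vals = np.clip(
        np.array([mu[i] + 1.0 * rows[g] for i, g in enumerate(genes)])
        if genes else np.empty((0, n_patients)),
        0.0, None)
    expr = ExpressionMatrix(pd.DataFrame(vals, index=genes, columns=patients),
                            Scale.LOG2P1)
    return fractions, expr


def simulate_gene_sets(
    genes: Sequence[str],
    enriched_in: Sequence[str] = (),
    n_sets: int = 20,
    set_size: int = 50,
    enriched_fraction: float = 0.8,
    seed: int = 0,
) -> GeneSetCollection:
    """Build a synthetic gene-set collection over ``genes``.

    The first set ("PLANTED_MODULE") draws ``enriched_fraction`` of its
    members from ``enriched_in``; the remaining sets are uniform draws, so
    over-representation analysis has one true positive and calibrated nulls.
    """
    rng = np.random.default_rng(seed)
    genes = list(genes)
    sets: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    if enriched_in:
        pool = [g for g in enriched_in if g in set(genes)]
        k_enr = min(len(pool), int(round(enriched_fraction * set_size)))
        chosen = list(rng.choice(pool, size=k_enr, replace=False))
        others = [g for g in genes if g not in set(chosen)]
        fill = list(rng.choice(others, size=max(0, set_size - k_enr), replace=False))
        sets["PLANTED_MODULE"] = chosen + fill
        desc["PLANTED_MODULE"] = "synthetic module enriched in planted genes"
    for i in range(n_sets - bool(enriched_in)):
        name = f"RANDOM_SET_{i + 1:02d}"
        sets[name] = list(rng.choice(genes, size=min(set_size, len(genes)),
                                     replace=False))
        desc[name] = "synthetic uniform gene set"
    return GeneSetCollection(sets, desc)
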