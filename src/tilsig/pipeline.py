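"""Config-driven end-to-end pipeline.

Stages: simulate the two-population TIL contrast -> differential expression
-> top-K candidate selection -> simulate the validation survival cohort ->
trend filter -> ppScore + stratification -> Kaplan-Meier / log-rank /
multivariate Cox / stage chi-squared -> high-vs-low ppScore contrast within
the TIL cohort -> immune-fraction correlations -> over-representation
analysis. All artifacts are plain TSV/JSON; re-running with the same config
and seed reproduces byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_io import write_expression_matrix, write_gmt
from .diffexpr import differential_expression
from .signature import select_top_candidates, trend_filter, score_and_stratify
from .survival import km_estimate, logrank_test, fit_cox, chi_squared_stage_test
from .assoc import (correlate_genes_with_fractions, summarize_significant_fraction,
                    ora_enrichment)
from .synthetic import (ExpressionSimParams, SurvivalSimParams,
                        simulate_til_expression, simulate_survival_cohort,
                        simulate_immune_fractions, simulate_gene_sets)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "PipelineError", "run_full_pipeline"]


@dataclass
class PipelineConfig:
    """All pipeline inputs and thresholds.

    Defaults mirror the study conditions: 10000 genes, 18 samples per TIL
    population, a 512-patient validation cohort, volcano thresholds
    log2FC >= 2 / p <= 0.05, top-K = 100 candidates per arm, median ppScore
    split, and FDR < 0.01 for the high-vs-low contrast.
    """

    seed: int = 0
    outdir: str = "tilsig_run"
    expression: dict = field(default_factory=dict)   # ExpressionSimParams overrides
    cohort: dict = field(default_factory=dict)       # SurvivalSimParams overrides
    annotation_rate: float = 0.98
    fc_threshold: float = 2.0
    p_threshold: float = 0.05
    inclusive: bool = True
    test: str = "welch"
    pseudocount: float = 1.0
    top_k: int = 100
    trend_method: str = "event_mean"
    trend_alpha: float | None = None
    split_quantile: float = 0.5
    highlow_fdr: float = 0.01
    n_gene_sets: int = 20
    gene_set_size: int = 50
    plots: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.annotation_rate <= 1.0:
            raise ValueError("annotation_rate must lie in (0, 1]")
        if self.fc_threshold <= 0 or not 0 < self.p_threshold <= 1:
            raise ValueError("volcano thresholds out of domain")
        if not 0 < self.split_quantile < 1:
            raise ValueError("split_quantile must lie in (0, 1)")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if not 0 < self.highlow_fdr <= 1:
            raise ValueError("highlow_fdr must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in raw:
            raise ValueError("config must set a seed")
        return cls(**raw)


@dataclass
class RunReport:
    """Machine-readable record of one pipeline run."""

    version: str
    config: dict
    funnel: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    statistics: dict = field(default_factory=dict)
    checksums: dict = field(default_factory=dict)
    completed_stages: list = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True,
                      default=str)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the partial report."""

    def __init__(self, stage: str, report: RunReport, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.report = report
        self.cause = cause


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage and return the :class:`RunReport`.

    Artifacts (DEG table, panel JSON, score/label TSV, KM tables, statistics
    JSON, correlation and enrichment tables, the report itself) are written
    under ``config.outdir``.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(version=__version__, config=dataclasses.asdict(config))
    artifacts: dict[str, Path] = {}
    seeds = (np.random.SeedSequence(config.seed).generate_state(5) % (2 ** 31)).tolist()

    stage = "simulate_til_expression"
    try:
        ep = ExpressionSimParams(**{"seed": seeds[0], **config.expression})
        mat_a, mat_b, til_truth = simulate_til_expression(ep)
        report.counts["n_genes"] = ep.n_genes
        report.counts["n_til_samples_per_group"] = ep.n_samples_per_group

        stage = "differential_expression"
        deg = differential_expression(
            mat_a, mat_b, pseudocount=config.pseudocount, test=config.test,
            fc_threshold=config.fc_threshold, p_threshold=config.p_threshold,
            inclusive=config.inclusive)
        deg.index.name = "gene"
        artifacts["deg"] = out / "deg.tsv"
        deg.to_csv(artifacts["deg"], sep="\t", float_format="%.6g")
        report.counts["n_deg"] = int((deg["class"] != "ns").sum())
        report.counts["n_deg_up"] = int((deg["class"] == "up").sum())
        report.counts["n_deg_down"] = int((deg["class"] == "down").sum())

        stage = "select_top_candidates"
        cand_up, cand_down = select_top_candidates(deg, k=config.top_k)

        stage = "simulate_survival_cohort"
        rng = np.random.default_rng(seeds[1])
        n_keep = int(round(config.annotation_rate * len(til_truth.gene_class)))
        kept = sorted(rng.choice(til_truth.gene_class.index.to_numpy(),
                                 size=n_keep, replace=False).tolist())
        kept_set = set(kept)
        sp = SurvivalSimParams(**{
            "seed": seeds[2],
            "risk_genes_up": tuple(g for g in til_truth.up_genes if g in kept_set),
            "risk_genes_down": tuple(g for g in til_truth.down_genes if g in kept_set),
            "genes": tuple(kept),
            **config.cohort})
        cohort, cohort_truth = simulate_survival_cohort(sp)
        report.counts["n_patients"] = cohort.n_patients
        report.counts["n_usable_dss"] = int(cohort.usable_for_survival.sum())
        artifacts["clinical"] = out / "cohort_clinical.tsv"
        cohort.clinical.to_csv(artifacts["clinical"], sep="\t", float_format="%.6g")

        stage = "trend_filter"
        panel = trend_filter(cand_up, cand_down, cohort,
                             method=config.trend_method, alpha=config.trend_alpha)
        artifacts["panel"] = out / "panel.json"
        panel.to_json(artifacts["panel"])
        report.funnel = panel.funnel()

        stage = "ppscore"
        ppres = score_and_stratify(cohort, panel,
                                   split_quantile=config.split_quantile)
        artifacts["scores"] = out / "scores.tsv"
        ppres.as_frame().to_csv(artifacts["scores"], sep="\t", float_format="%.6g")
        report.counts["n_high"] = ppres.n_high
        report.counts["n_low"] = ppres.n_low
        report.counts["n_score_excluded"] = len(ppres.excluded_reason)

        stage = "survival_statistics"
        clin = cohort.clinical
        usable = cohort.usable_for_survival
        hi = usable & (ppres.labels == "high")
        lo = usable & (ppres.labels == "low")
        km_high = km_estimate(clin.loc[hi, "dss_time"], clin.loc[hi, "dss_event"])
        km_low = km_estimate(clin.loc[lo, "dss_time"], clin.loc[lo, "dss_event"])
        artifacts["km_high"] = out / "km_high.tsv"
        artifacts["km_low"] = out / "km_low.tsv"
        km_high.as_frame().to_csv(artifacts["km_high"], sep="\t", index=False,
                                  float_format="%.6g")
        km_low.as_frame().to_csv(artifacts["km_low"], sep="\t", index=False,
                                 float_format="%.6g")
        lr = logrank_test(clin.loc[hi, "dss_time"], clin.loc[hi, "dss_event"],
                          clin.loc[lo, "dss_time"], clin.loc[lo, "dss_event"])
        extra = pd.DataFrame({"ppscore_high":
                              ppres.labels.map({"high": 1.0, "low": 0.0})})
        cox = fit_cox(cohort, ["ppscore_high", "stage", "age_band", "gender",
                               "anatomic_location", "residual_disease"],
                      extra=extra)
        chi = chi_squared_stage_test(ppres.labels[usable], clin.loc[usable, "stage"])
        report.statistics["logrank"] = {"statistic": lr.statistic, "p": lr.p_value}
        report.statistics["cox_ppscore"] = {
            "hr": cox.hr("ppscore_high"), "p": cox.p("ppscore_high"),
            "ci_low": float(cox.summary.loc["ppscore_high", "ci_low"]),
            "ci_high": float(cox.summary.loc["ppscore_high", "ci_high"]),
            "converged": cox.converged, "n_used": cox.n_used,
            "n_events": cox.n_events}
        report.statistics["chi_squared_stage"] = {
            "statistic": chi.statistic, "dof": chi.dof, "p": chi.p_value}
        artifacts["cox"] = out / "cox_summary.tsv"
        cox.summary.to_csv(artifacts["cox"], sep="\t", float_format="%.6g")

        stage = "highlow_til_contrast"
        til_pp = score_and_stratify(
            _as_cohort_like(mat_a), panel, split_quantile=config.split_quantile)
        hi_s = til_pp.labels.index[til_pp.labels == "high"].tolist()
        lo_s = til_pp.labels.index[til_pp.labels == "low"].tolist()
        hl_deg = differential_expression(
            mat_a.subset_samples(hi_s), mat_a.subset_samples(lo_s),
            pseudocount=config.pseudocount, test=config.test,
            fc_threshold=config.fc_threshold, p_threshold=config.p_threshold,
            inclusive=config.inclusive)
        hl_deg.index.name = "gene"
        artifacts["highlow_deg"] = out / "highlow_deg.tsv"
        hl_deg.to_csv(artifacts["highlow_deg"], sep="\t", float_format="%.6g")
        sig = hl_deg["q_value"] < config.highlow_fdr
        report.counts["n_til_high"] = len(hi_s)
        report.counts["n_til_low"] = len(lo_s)
        report.counts["n_highlow_deg_fdr"] = int(sig.sum())
        report.counts["n_highlow_deg_fdr_up"] = int((sig & (hl_deg["log2fc"] > 0)).sum())
        report.counts["n_highlow_deg_fdr_down"] = int((sig & (hl_deg["log2fc"] < 0)).sum())

        stage = "immune_fraction_correlation"
        fractions, _ = simulate_immune_fractions(cohort.n_patients, seed=seeds[3])
        artifacts["fractions"] = out / "fractions.tsv"
        fractions.to_csv(artifacts["fractions"], sep="\t", float_format="%.6g")
        sig_genes = panel.retained_up + panel.retained_down
        sig_expr = cohort.expression.subset_genes(sig_genes)
        artifacts["signature_expression"] = out / "signature_expression.tsv"
        write_expression_matrix(sig_expr, artifacts["signature_expression"])
        corr = correlate_genes_with_fractions(sig_expr, fractions)
        artifacts["correlations"] = out / "correlations.tsv"
        pd.concat({"r": corr.r, "p": corr.p}, axis=1).to_csv(
            artifacts["correlations"], sep="\t", float_format="%.6g")
        for arm, genes in (("up", panel.retained_up), ("down", panel.retained_down)):
            summ = summarize_significant_fraction(corr, genes)
            for subset in summ.index:
                report.statistics[f"pct_significant_{arm}_{subset}"] = float(
                    summ.loc[subset, "percent_significant"])

        stage = "ora_enrichment"
        universe = list(til_truth.gene_class.index)
        gene_sets = simulate_gene_sets(universe, enriched_in=til_truth.up_genes,
                                       n_sets=config.n_gene_sets,
                                       set_size=config.gene_set_size,
                                       seed=seeds[4])
        artifacts["gene_sets"] = out / "gene_sets.gmt"
        write_gmt(gene_sets, artifacts["gene_sets"])
        enr = ora_enrichment(panel.retained_up, gene_sets, universe)
        artifacts["enrichment"] = out / "enrichment.tsv"
        enr.to_csv(artifacts["enrichment"], sep="\t", float_format="%.6g")
        top = enr.index[0]
        report.statistics["top_enrichment"] = {
            "term": str(top), "p": float(enr.loc[top, "p_value"]),
            "fold_enrichment": float(enr.loc[top, "fold_enrichment"])}

        if config.plots:
            stage = "plots"
            from .plots import km_plot, volcano_plot
            km_plot({"high ppScore": km_high, "low ppScore": km_low},
                    out / "km.png")
            volcano_plot(deg, out / "volcano.png",
                         fc_threshold=config.fc_threshold,
                         p_threshold=config.p_threshold)
    except Exception as exc:  # noqa: BLE001 - stage name must reach the caller
        report.checksums = {k: _sha256(v) for k, v in artifacts.items()}
        report.to_json(out / "report.json")
        raise PipelineError(stage, report, exc) from exc

    report.completed_stages = [
        "simulate_til_expression", "differential_expression",
        "select_top_candidates", "simulate_survival_cohort", "trend_filter",
        "ppscore", "survival_statistics", "highlow_til_contrast",
        "immune_fraction_correlation", "ora_enrichment"]
    report.checksums = {k: _sha256(v) for k, v in artifacts.items()}
    report.to_json(out / "report.json")
    return report


def _as_cohort_like(mat):
    """Wrap an expression matrix as a minimal cohort for scoring only."""
    from .data_io import SurvivalCohort
    clin = pd.DataFrame({"dss_time": np.nan, "dss_event": np.nan},
                        index=pd.Index(mat.sample_ids, name="patient_id"))
    return SurvivalCohort(clin, mat)
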