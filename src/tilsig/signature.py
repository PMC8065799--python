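"""Poor-prognosis signature derivation and the ppScore statistic.

The signature funnel: the top-K up- and down-regulated candidates from a
differential-expression table are aligned to a validation cohort, each
annotated candidate is tested for a direction of association with poorer
disease-specific survival (the trend filter), and the retained genes form
the up and down arms of the panel. The per-patient ppScore is the ratio of
the mean linear-scale expression of the up arm to that of the down arm;
patients are stratified high/low at a score percentile (median by default).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix, SurvivalCohort, align_genes
from .survival import univariate_cox

logger = logging.getLogger(__name__)

__all__ = [
    "SignaturePanel",
    "PPScoreResult",
    "select_top_candidates",
    "trend_filter",
    "compute_ppscore",
    "stratify_by_percentile",
    "score_and_stratify",
]


def select_top_candidates(deg: pd.DataFrame, k: int = 100) -> tuple[list[str], list[str]]:
    """Pick the top-``k`` genes of each volcano class from a DEG table.

    Within each class genes are ranked by |log2fc| descending, ties broken by
    smaller p-value then lexicographic gene symbol. If a class holds fewer
    than ``k`` genes, all are returned with a warning.
    """
    out: list[list[str]] = []
    for cls in ("up", "down"):
        sub = deg[deg["class"] == cls].copy()
        sub["_abs"] = sub["log2fc"].abs()
        # lexicographic pre-sort + stable sort makes gene symbol the tertiary key
        sub = (sub.sort_index(kind="stable")
                  .sort_values(["_abs", "p_value"], ascending=[False, True],
                               kind="stable"))
        if len(sub) < k:
            warnings.warn(f"only {len(sub)} {cls}-class genes available for k={k}",
                          stacklevel=2)
        out.append(sub.index[:k].tolist())
    return out[0], out[1]


@dataclass
class SignaturePanel:
    """Ordered up/down gene lists with funnel provenance.

    ``retained_* ⊆ annotated_* ⊆ candidates_*`` for each arm. ``stats`` holds
    the per-gene trend statistics (arm, direction, effect, p, retained).
    """

    candidates_up: list[str]
    candidates_down: list[str]
    annotated_up: list[str] = field(default_factory=list)
    annotated_down: list[str] = field(default_factory=list)
    retained_up: list[str] = field(default_factory=list)
    retained_down: list[str] = field(default_factory=list)
    method: str = "event_mean"
    alpha: float | None = None
    stats: pd.DataFrame | None = None

    def funnel(self) -> dict[str, int]:
        return {
            "candidates_up": len(self.candidates_up),
            "annotated_up": len(self.annotated_up),
            "retained_up": len(self.retained_up),
            "candidates_down": len(self.candidates_down),
            "annotated_down": len(self.annotated_down),
            "retained_down": len(self.retained_down),
        }

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["stats"] = (self.stats.reset_index().to_dict(orient="list")
                      if self.stats is not None else None)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SignaturePanel":
        with open(path) as fh:
            d = json.load(fh)
        stats = d.pop("stats", None)
        panel = cls(**d)
        if stats is not None:
            panel.stats = pd.DataFrame(stats).set_index("gene")
        return panel


def trend_filter(
    candidates_up: list[str],
    candidates_down: list[str],
    cohort: SurvivalCohort,
    method: str = "event_mean",
    alpha: float | None = None,
    case_fold: bool = False,
) -> SignaturePanel:
    """Retain candidates whose expression direction tracks poorer DSS.

    Per annotated gene a direction of association with disease-specific death
    is computed on the cohort's usable patients:

    * ``event_mean`` (default): sign of mean log2(x+1) expression among
      DSS-event patients minus among event-free patients;
    * ``cox_sign``: sign of the univariate Cox coefficient on standardized
      log2(x+1) expression, optionally gated at Wald p <= ``alpha``.

    Up-candidates are retained when the direction is positive (higher
    expression with poorer survival), down-candidates when negative.
    """
    if method not in ("event_mean", "cox_sign"):
        raise ValueError(f"unknown trend method {method!r}")
    if cohort.expression is None:
        raise ValueError("cohort has no attached expression")
    rep_up = align_genes(candidates_up, cohort.expression, case_fold=case_fold)
    rep_down = align_genes(candidates_down, cohort.expression, case_fold=case_fold)
    usable = cohort.usable_for_survival
    clin = cohort.clinical.loc[usable]
    if len(clin) == 0 or clin["dss_event"].sum() == 0:
        raise ValueError("trend filter undefined: cohort has no DSS events")
    logx = cohort.expression.to_log2p1().values.loc[:, usable[usable].index]

    genes = rep_up.annotated + rep_down.annotated
    arms = ["up"] * len(rep_up.annotated) + ["down"] * len(rep_down.annotated)
    sub = logx.loc[genes]
    if method == "event_mean":
        ev = clin["dss_event"].to_numpy(float) == 1.0
        effect = sub.to_numpy()[:, ev].mean(axis=1) - sub.to_numpy()[:, ~ev].mean(axis=1)
        pvals = np.full(len(genes), np.nan)
    else:
        fits = univariate_cox(clin["dss_time"].to_numpy(float),
                              clin["dss_event"].to_numpy(float),
                              sub.T, standardize=True)
        effect = fits["coef"].to_numpy()
        pvals = fits["p"].to_numpy()

    direction = np.sign(effect)
    gate = np.ones(len(genes), bool) if alpha is None else (pvals <= alpha)
    retained = np.where(np.array(arms) == "up",
                        (direction > 0) & gate,
                        (direction < 0) & gate)
    stats = pd.DataFrame(
        {"arm": arms, "direction": direction, "effect": effect, "p": pvals,
         "retained": retained},
        index=pd.Index(genes, name="gene"),
    )
    panel = SignaturePanel(
        candidates_up=list(candidates_up),
        candidates_down=list(candidates_down),
        annotated_up=rep_up.annotated,
        annotated_down=rep_down.annotated,
        retained_up=[g for g, a, r in zip(genes, arms, retained) if a == "up" and r],
        retained_down=[g for g, a, r in zip(genes, arms, retained) if a == "down" and r],
        method=method,
        alpha=alpha,
        stats=stats,
    )
    logger.info("trend filter (%s): funnel %s", method, panel.funnel())
    return panel


@dataclass
class PPScoreResult:
    """Per-patient ppScore with optional stratum labels.

    ``scores`` is indexed by patient; ``labels`` holds ``high``/``low`` (or
    ``excluded``); ``threshold`` is the split-quantile score value.
    ``excluded_reason`` maps excluded patients to why (e.g. a zero down-arm
    mean makes the ratio undefined).
    """

    scores: pd.Series
    threshold: float | None = None
    labels: pd.Series | None = None
    excluded_reason: dict[str, str] = field(default_factory=dict)

    @property
    def n_high(self) -> int:
        return int((self.labels == "high").sum()) if self.labels is not None else 0

    @property
    def n_low(self) -> int:
        return int((self.labels == "low").sum()) if self.labels is not None else 0

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"ppscore": self.scores})
        if self.labels is not None:
            df["label"] = self.labels
        return df


def compute_ppscore(
    cohort_expression: ExpressionMatrix,
    panel: SignaturePanel,
    on_log_scale: bool = False,
) -> PPScoreResult:
    """Ratio-of-means ppScore per patient.

    ``ppScore_i = mean_{g in retained_up}(x_gi) / mean_{g in retained_down}(x_gi)``
    with expression on the linear scale (log2p1 input is back-transformed
    first; ``on_log_scale`` averages log2(x+1) values instead). Patients with
    a zero down-arm mean are flagged excluded.
    """
    if not panel.retained_up or not panel.retained_down:
        raise ValueError("panel has an empty retained arm")
    missing = [g for g in (*panel.retained_up, *panel.retained_down)
               if g not in set(cohort_expression.gene_ids)]
    if missing:
        raise ValueError(f"panel genes absent from expression: {missing[:5]}")
    mat = (cohort_expression.to_log2p1() if on_log_scale
           else cohort_expression.to_linear()).values
    up_mean = mat.loc[panel.retained_up].mean(axis=0)
    down_mean = mat.loc[panel.retained_down].mean(axis=0)
    excluded = {str(pat): "zero_down_arm_mean"
                for pat in down_mean.index[down_mean == 0]}
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = up_mean / down_mean
    scores[down_mean == 0] = np.nan
    scores.name = "ppscore"
    if excluded:
        logger.info("ppScore: %d patients excluded (zero down-arm mean)", len(excluded))
    return PPScoreResult(scores=scores, excluded_reason=excluded)


def stratify_by_percentile(
    result: PPScoreResult | pd.Series,
    split_quantile: float = 0.5,
) -> PPScoreResult:
    """Label patients high/low at a score quantile.

    The threshold is the linear-interpolation quantile of the scoreable
    patients' scores; patients with score > threshold are ``high``, score <=
    threshold are ``low`` (ties at the threshold go low). Excluded patients
    keep the label ``excluded``.
    """
    if not 0.0 < split_quantile < 1.0:
        raise ValueError("split_quantile must lie in (0, 1)")
    res = result if isinstance(result, PPScoreResult) else PPScoreResult(result)
    usable = res.scores.dropna()
    if len(usable) < 2:
        raise ValueError("need at least 2 scoreable patients")
    if usable.nunique() == 1:
        raise ValueError("all scores identical: no split exists")
    threshold = float(np.quantile(usable.to_numpy(), split_quantile,
                                  method="linear"))
    labels = pd.Series("excluded", index=res.scores.index, dtype=object)
    labels[usable.index] = np.where(usable > threshold, "high", "low")
    labels.name = "label"
    return PPScoreResult(scores=res.scores, threshold=threshold, labels=labels,
                         excluded_reason=dict(res.excluded_reason))


def score_and_stratify(
    cohort: SurvivalCohort,
    panel: SignaturePanel,
    split_quantile: float = 0.5,
    on_log_scale: bool = False,
) -> PPScoreResult:
    """Convenience: ppScore on the cohort's expression, then stratify."""
    if cohort.expression is None:
        raise ValueError("cohort has no attached expression")
    res = compute_ppscore(cohort.expression, panel, on_log_scale=on_log_scale)
    return stratify_by_percentile(res, split_quantile)
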