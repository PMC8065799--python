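"""Survival and categorical statistics: Kaplan–Meier estimation, the
two-group log-rank test, multivariate Cox proportional-hazards fits and the
chi-squared test of stage distribution between score strata.

The multivariate Cox fit and the log-rank test delegate to lifelines (Efron
tie handling for Cox); the Kaplan–Meier product-limit estimator and a fast
vectorized univariate Cox (Breslow ties, used for per-gene screening) are
implemented here directly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank

from .data_io import SurvivalCohort

logger = logging.getLogger(__name__)

__all__ = [
    "KMCurve",
    "LogRankResult",
    "CoxResult",
    "ChiSquaredResult",
    "km_estimate",
    "logrank_test",
    "fit_cox",
    "univariate_cox",
    "chi_squared_stage_test",
    "REFERENCE_LEVELS",
]

# reference levels for categorical covariates in the Cox model; stage I and
# the youngest age band anchor the hazard-ratio scale
REFERENCE_LEVELS = {
    "stage": "I",
    "age_band": "<55",
    "gender": "female",
    "anatomic_location": "cecum",
    "residual_disease": "no",
}


def _clean(times, events) -> tuple[np.ndarray, np.ndarray, int]:
    t = pd.to_numeric(pd.Series(times), errors="coerce").to_numpy(float)
    e = pd.to_numeric(pd.Series(events), errors="coerce").to_numpy(float)
    ok = np.isfinite(t) & np.isfinite(e)
    n_excluded = int((~ok).sum())
    t, e = t[ok], e[ok]
    if (t < 0).any():
        raise ValueError("negative survival times")
    if not np.isin(e, [0.0, 1.0]).all():
        raise ValueError("event indicators must be 0/1")
    return t, e, n_excluded


@dataclass
class KMCurve:
    """Product-limit survival curve.

    ``event_times`` are the distinct times with >=1 event; ``at_risk`` and
    ``n_events`` the corresponding risk-set and event counts; ``survival``
    the estimate S(t) just after each event time. Subjects censored at an
    event time are kept in the risk set at that time and removed after
    (censored-after-event convention).
    """

    event_times: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray
    n_subjects: int
    n_excluded: int = 0

    def survival_at(self, t: float) -> float:
        """S(t): step function, right-continuous, S(0) = 1."""
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.event_times, "at_risk": self.at_risk,
                             "events": self.n_events, "survival": self.survival})


def km_estimate(times, events) -> KMCurve:
    """Kaplan–Meier product-limit estimate of the survival function.

    Rows with a missing time or event are excluded and counted in
    ``n_excluded``.
    """
    t, e, n_excl = _clean(times, events)
    if t.size == 0:
        raise ValueError("no usable subjects for Kaplan-Meier estimation")
    uniq = np.unique(t[e == 1])
    at_risk = np.array([(t >= u).sum() for u in uniq], dtype=int)
    n_events = np.array([((t == u) & (e == 1)).sum() for u in uniq], dtype=int)
    with np.errstate(invalid="ignore"):
        surv = np.cumprod(1.0 - n_events / at_risk)
    return KMCurve(uniq, at_risk, n_events, surv, n_subjects=t.size,
                   n_excluded=n_excl)


@dataclass
class LogRankResult:
    statistic: float
    dof: int
    p_value: float


def logrank_test(times_1, events_1, times_2, events_2) -> LogRankResult:
    """Two-group log-rank test (chi-squared with 1 df)."""
    t1, e1, _ = _clean(times_1, events_1)
    t2, e2, _ = _clean(times_2, events_2)
    if t1.size == 0 or t2.size == 0:
        raise ValueError("both groups must be non-empty")
    if e1.sum() + e2.sum() == 0:
        raise ValueError("log-rank test undefined with zero events")
    res = _ll_logrank(t1, t2, event_observed_A=e1, event_observed_B=e2)
    return LogRankResult(float(res.test_statistic), 1, float(res.p_value))


@dataclass
class CoxResult:
    """Cox proportional-hazards fit.

    ``summary`` is indexed by covariate with columns ``coef``, ``hr``,
    ``ci_low``, ``ci_high`` (95% Wald) and ``p``.
    """

    summary: pd.DataFrame
    converged: bool
    n_used: int
    n_events: int
    reference_levels: dict = field(default_factory=dict)

    def hr(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hr"])

    def p(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "p"])


def _encode_covariates(df: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    refs_used: dict[str, str] = {}
    cols: list[pd.Series | pd.DataFrame] = []
    for name in df.columns:
        col = df[name]
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.astype(float))
            continue
        levels = sorted(col.astype(str).unique())
        ref = REFERENCE_LEVELS.get(name)
        if ref not in levels:
            ref = levels[0]
        refs_used[name] = ref
        for lev in levels:
            if lev == ref:
                continue
            cols.append((col.astype(str) == lev).astype(float)
                        .rename(f"{name}[{lev}]"))
    return pd.concat(cols, axis=1), refs_used


def fit_cox(
    cohort: SurvivalCohort,
    covariates: list[str],
    extra: pd.DataFrame | None = None,
) -> CoxResult:
    """Multivariate Cox PH fit on the cohort's usable patients.

    ``covariates`` names clinical columns and/or columns of ``extra`` (a
    patient-indexed frame, e.g. a high/low score label). Categorical
    covariates are dummy-encoded against :data:`REFERENCE_LEVELS`; patients
    with a "missing" level or absent DSS are dropped (complete case).
    Efron tie handling; Wald 95% CIs.
    """
    data = cohort.clinical.copy()
    if extra is not None:
        data = data.join(extra, how="left")
    missing_cols = [c for c in covariates if c not in data.columns]
    if missing_cols:
        raise ValueError(f"unknown covariates: {missing_cols}")
    sub = data.loc[cohort.usable_for_survival, ["dss_time", "dss_event", *covariates]]
    for c in covariates:
        if not pd.api.types.is_numeric_dtype(sub[c]):
            sub = sub[sub[c].astype(str) != "missing"]
    sub = sub.dropna()
    X, refs = _encode_covariates(sub[covariates])
    for c in X.columns:
        if X[c].nunique() <= 1:
            raise ValueError(f"constant covariate: {c!r}")
    n_params = X.shape[1]
    if len(sub) < 5 * n_params:
        warnings.warn(f"only {len(sub)} complete cases for {n_params} parameters",
                      stacklevel=2)
    design = pd.concat([sub[["dss_time", "dss_event"]], X], axis=1)
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(design, duration_col="dss_time", event_col="dss_event")
    except ConvergenceError:
        logger.warning("Cox fit did not converge")
        empty = pd.DataFrame(np.nan, index=X.columns,
                             columns=["coef", "hr", "ci_low", "ci_high", "p"])
        return CoxResult(empty, converged=False, n_used=len(sub),
                         n_events=int(sub["dss_event"].sum()),
                         reference_levels=refs)
    s = cph.summary
    summary = pd.DataFrame(
        {"coef": s["coef"], "hr": s["exp(coef)"],
         "ci_low": s["exp(coef) lower 95%"], "ci_high": s["exp(coef) upper 95%"],
         "p": s["p"]})
    summary.index.name = "covariate"
    return CoxResult(summary, converged=True, n_used=len(sub),
                     n_events=int(sub["dss_event"].sum()),
                     reference_levels=refs)


def univariate_cox(
    times,
    events,
    X: pd.DataFrame,
    standardize: bool = True,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> pd.DataFrame:
    """Independent single-covariate Cox fits for every column of ``X``.

    Newton–Raphson on the Breslow partial likelihood, vectorized across
    columns (each column is a separate one-parameter model, e.g. one gene's
    standardized log expression). Returns a DataFrame indexed like
    ``X.columns`` with ``coef``, ``se``, ``z`` and Wald ``p``; constant
    columns yield NaN.
    """
    t = np.asarray(times, float)
    d = np.asarray(events, float)
    x = X.to_numpy(float)
    if x.shape[0] != t.size:
        raise ValueError("X rows must match number of subjects")
    order = np.argsort(-t, kind="stable")
    t, d, x = t[order], d[order], x[order]
    sd0 = x.std(axis=0, ddof=1)
    const = sd0 == 0
    if standardize:
        with np.errstate(invalid="ignore", divide="ignore"):
            x = (x - x.mean(axis=0)) / sd0
        x[:, const] = 0.0
    # risk set of subject i = all j with t_j >= t_i; with descending sort this
    # is the prefix up to the last member of i's tie group
    ridx = np.searchsorted(-t, -t, side="right") - 1
    m = x.shape[1]
    beta = np.zeros(m)
    info = np.full(m, np.nan)
    for _ in range(max_iter):
        eta = np.clip(x * beta, -30.0, 30.0)
        w = np.exp(eta)
        s0 = np.cumsum(w, axis=0)[ridx]
        s1 = np.cumsum(w * x, axis=0)[ridx]
        s2 = np.cumsum(w * x * x, axis=0)[ridx]
        mu = s1 / s0
        U = ((x - mu) * d[:, None]).sum(axis=0)
        info = ((s2 / s0 - mu * mu) * d[:, None]).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            step = np.where(info > 0, U / info, 0.0)
        step = np.clip(step, -2.0, 2.0)
        beta = beta + step
        if np.nanmax(np.abs(step), initial=0.0) < tol:
            break
    with np.errstate(invalid="ignore", divide="ignore"):
        se = 1.0 / np.sqrt(info)
        z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    out = pd.DataFrame({"coef": beta, "se": se, "z": z, "p": p}, index=X.columns)
    out.loc[const, :] = np.nan
    return out


@dataclass
class ChiSquaredResult:
    """Pearson chi-squared test of a group x stage contingency table."""

    table: pd.DataFrame
    statistic: float
    dof: int
    p_value: float
    low_expected: bool = False
    dropped_margins: list[str] = field(default_factory=list)
    n_excluded_missing: int = 0


def chi_squared_stage_test(labels, stages) -> ChiSquaredResult:
    """Pearson chi-squared (no continuity correction) on the 2 x S table of
    high/low labels against disease stage.

    Patients with stage "missing" (or NaN) are excluded and counted; empty
    rows/columns are dropped with a warning; expected counts below 5 set the
    ``low_expected`` flag.
    """
    lab = pd.Series(labels).astype(str)
    stg = pd.Series(stages).reset_index(drop=True).astype(object)
    lab = lab.reset_index(drop=True)
    keep = stg.notna() & (stg.astype(str) != "missing")
    n_excl = int((~keep).sum())
    table = pd.crosstab(lab[keep], stg[keep].astype(str))
    dropped = []
    for axis in (0, 1):
        sums = table.sum(axis=1 - axis)
        empty = sums.index[sums == 0].tolist()
        if empty:
            dropped.extend(map(str, empty))
            table = table.drop(index=empty) if axis == 0 else table.drop(columns=empty)
            logger.warning("chi-squared: dropped empty margin(s) %s", empty)
    if table.shape[1] < 2 or table.shape[0] < 2:
        raise ValueError("need at least a 2x2 table after exclusions")
    stat, p, dof, expected = stats.chi2_contingency(table.to_numpy(),
                                                    correction=False)
    low = bool((expected < 5).any())
    if low:
        logger.warning("chi-squared: expected counts below 5")
    return ChiSquaredResult(table, float(stat), int(dof), float(p),
                            low_expected=low, dropped_margins=dropped,
                            n_excluded_missing=n_excl)
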