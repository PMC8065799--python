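"""Kaplan-Meier, log-rank, Cox PH and stage chi-squared, each checked
against an independent brute-force oracle on small instances."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tilsig import (
    ExpressionMatrix,
    Scale,
    SurvivalCohort,
    chi_squared_stage_test,
    fit_cox,
    km_estimate,
    logrank_test,
    univariate_cox,
)


class TestKaplanMeier:
    def test_all_events_hand_values(self):
        curve = km_estimate([1, 2, 3], [1, 1, 1])
        np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3, 0.0])
        np.testing.assert_array_equal(curve.at_risk, [3, 2, 1])

    def test_one_censor_hand_values(self):
        curve = km_estimate([1, 2, 3], [1, 0, 1])
        np.testing.assert_array_equal(curve.event_times, [1, 3])
        assert curve.survival_at(1) == pytest.approx(2 / 3)
        assert curve.survival_at(3) == pytest.approx(0.0)

    def test_all_censored_flat_curve(self):
        curve = km_estimate([5, 10, 15], [0, 0, 0])
        assert curve.event_times.size == 0
        assert curve.survival_at(100.0) == 1.0

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(100, size=40)
        curve = km_estimate(t, np.ones(40))
        for tau in np.quantile(t, [0.1, 0.5, 0.9]):
            assert curve.survival_at(tau) == pytest.approx((t > tau).mean())

    def test_missing_rows_excluded_and_counted(self):
        curve = km_estimate([1, 2, np.nan], [1, 1, 1])
        assert curve.n_subjects == 2 and curve.n_excluded == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no usable"):
            km_estimate([], [])

    def test_monotone_non_increasing(self):
        rng = np.random.default_rng(12)
        t = rng.exponential(50, 60)
        e = (rng.random(60) < 0.6).astype(float)
        s = km_estimate(t, e).survival
        assert (np.diff(s) <= 1e-12).all()
        assert ((s >= 0) & (s <= 1)).all()


def _logrank_oracle(t1, e1, t2, e2):
    """O-E risk-table enumeration of the two-group log-rank statistic."""
    t = np.concatenate([t1, t2])
    e = np.concatenate([e1, e2])
    g = np.concatenate([np.zeros(len(t1)), np.ones(len(t2))])
    num, var = 0.0, 0.0
    for tau in np.unique(t[e == 1]):
        at = t >= tau
        n, n1 = at.sum(), (at & (g == 0)).sum()
        d = ((t == tau) & (e == 1)).sum()
        d1 = ((t == tau) & (e == 1) & (g == 0)).sum()
        num += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return num ** 2 / var


class TestLogRank:
    def test_identical_groups_null(self):
        t = [5.0, 10.0, 15.0]
        e = [1, 0, 1]
        res = logrank_test(t, e, t, e)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_six_subject_oracle(self):
        t1, e1 = np.array([2.0, 5.0, 9.0]), np.array([1, 1, 0])
        t2, e2 = np.array([3.0, 7.0, 11.0]), np.array([1, 1, 1])
        res = logrank_test(t1, e1, t2, e2)
        expected = _logrank_oracle(t1, e1, t2, e2)
        assert res.statistic == pytest.approx(expected, rel=1e-9)
        assert res.p_value == pytest.approx(stats.chi2.sf(expected, 1), rel=1e-9)

    def test_random_instances_match_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(5):
            t1 = rng.exponential(50, 8).round(1)
            t2 = rng.exponential(30, 7).round(1)
            e1 = (rng.random(8) < 0.7).astype(int)
            e2 = (rng.random(7) < 0.7).astype(int)
            if e1.sum() + e2.sum() == 0:
                continue
            res = logrank_test(t1, e1, t2, e2)
            assert res.statistic == pytest.approx(
                _logrank_oracle(t1, e1, t2, e2), rel=1e-8)

    def test_group_swap_symmetry(self):
        rng = np.random.default_rng(6)
        t1, t2 = rng.exponential(40, 10), rng.exponential(60, 12)
        e1, e2 = np.ones(10), np.ones(12)
        a = logrank_test(t1, e1, t2, e2)
        b = logrank_test(t2, e2, t1, e1)
        assert a.statistic == pytest.approx(b.statistic, rel=1e-12)

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError, match="zero events"):
            logrank_test([1, 2], [0, 0], [3, 4], [0, 0])

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            logrank_test([], [], [1, 2], [1, 1])


def _partial_loglik(beta, t, e, x):
    """Breslow partial log-likelihood (equals Efron when no ties)."""
    ll = 0.0
    for i in np.flatnonzero(e == 1):
        risk = t >= t[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


def _grid_max(t, e, x):
    grid = np.linspace(-5, 5, 2001)
    best = grid[np.argmax([_partial_loglik(b, t, e, x) for b in grid])]
    for width in (0.02, 0.001):
        grid = np.linspace(best - width, best + width, 401)
        best = grid[np.argmax([_partial_loglik(b, t, e, x) for b in grid])]
    return best


def _cohort_from(t, e, extra_cols):
    patients = [f"P{i}" for i in range(len(t))]
    clinical = pd.DataFrame({"dss_time": t, "dss_event": e},
                            index=pd.Index(patients, name="patient_id"))
    extra = pd.DataFrame(extra_cols, index=clinical.index)
    return SurvivalCohort(clinical), extra


class TestCox:
    def test_single_binary_covariate_matches_grid_oracle(self):
        t = np.array([3.0, 5.0, 7.0, 11.0, 13.0, 17.0, 19.0, 23.0])
        e = np.array([1, 1, 0, 1, 1, 0, 1, 1])
        x = np.array([1.0, 0.0, 1.0, 1.0, 0.0, 0.0, 1.0, 0.0])
        cohort, extra = _cohort_from(t, e, {"group": x})
        res = fit_cox(cohort, ["group"], extra=extra)
        assert res.converged
        assert res.summary.loc["group", "coef"] == pytest.approx(
            _grid_max(t, e, x), abs=1e-4)
        assert res.hr("group") == pytest.approx(
            np.exp(res.summary.loc["group", "coef"]), rel=1e-12)
        lo, hi = res.summary.loc["group", ["ci_low", "ci_high"]]
        assert lo <= res.hr("group") <= hi

    def test_constant_covariate_named_in_error(self):
        cohort, extra = _cohort_from([1.0, 2.0, 3.0], [1, 1, 1],
                                     {"flat": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="flat"):
            fit_cox(cohort, ["flat"], extra=extra)

    def test_categorical_encoding_uses_reference_levels(self, small_cohort):
        res = fit_cox(small_cohort, ["gender"])
        assert res.reference_levels["gender"] == "female"
        assert "gender[male]" in res.summary.index

    def test_missing_category_rows_dropped(self, small_cohort):
        res = fit_cox(small_cohort, ["gender"])
        # one patient lacks DSS annotation in the fixture
        assert res.n_used == int(small_cohort.usable_for_survival.sum())


class TestUnivariateCox:
    def test_matches_lifelines_per_gene(self):
        from lifelines import CoxPHFitter
        rng = np.random.default_rng(17)
        n = 80
        X = pd.DataFrame(rng.standard_normal((n, 4)),
                         columns=[f"g{i}" for i in range(4)])
        t = rng.exponential(100 * np.exp(-0.5 * X["g0"].to_numpy()))
        t = t + rng.random(n) * 1e-9  # tie-free
        e = (rng.random(n) < 0.7).astype(float)
        mine = univariate_cox(t, e, X)
        for c in X.columns:
            z = (X[c] - X[c].mean()) / X[c].std(ddof=1)
            df = pd.DataFrame({"T": t, "E": e, "x": z})
            ref = CoxPHFitter().fit(df, "T", "E")
            assert mine.loc[c, "coef"] == pytest.approx(ref.params_["x"], abs=1e-4)
            assert mine.loc[c, "p"] == pytest.approx(ref.summary.loc["x", "p"],
                                                     rel=1e-2, abs=1e-4)

    def test_constant_column_flagged_nan(self):
        X = pd.DataFrame({"flat": np.ones(10), "var": np.arange(10.0)})
        out = univariate_cox(np.arange(1.0, 11.0), np.ones(10), X)
        assert np.isnan(out.loc["flat", "coef"])
        assert np.isfinite(out.loc["var", "coef"])


class TestChiSquaredStage:
    def test_uniform_table_null(self):
        labels = ["high"] * 20 + ["low"] * 20
        stages = (["I"] * 10 + ["II"] * 10) * 2
        res = chi_squared_stage_test(labels, stages)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_perfect_separation_hand_value(self):
        labels = ["high"] * 10 + ["low"] * 10
        stages = ["I"] * 10 + ["II"] * 10
        res = chi_squared_stage_test(labels, stages)
        assert res.statistic == pytest.approx(20.0)
        assert res.dof == 1
        assert res.p_value == pytest.approx(stats.chi2.sf(20.0, 1), rel=1e-6)

    def test_missing_stage_excluded_and_counted(self):
        labels = ["high", "high", "low", "low", "low"]
        stages = ["I", "II", "I", "II", "missing"]
        res = chi_squared_stage_test(labels, stages)
        assert res.n_excluded_missing == 1
        assert int(res.table.to_numpy().sum()) == 4

    def test_low_expected_counts_flagged(self):
        res = chi_squared_stage_test(["high", "high", "low", "low"],
                                     ["I", "II", "I", "II"])
        assert res.low_expected

    def test_single_stage_rejected(self):
        with pytest.raises(ValueError, match="2x2"):
            chi_squared_stage_test(["high", "low"], ["I", "I"])

    def test_dof_matches_table_shape(self):
        rng = np.random.default_rng(2)
        labels = rng.choice(["high", "low"], 200)
        stages = rng.choice(["I", "II", "III", "IV"], 200)
        res = chi_squared_stage_test(labels, stages)
        assert res.dof == (res.table.shape[0] - 1) * (res.table.shape[1] - 1)
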