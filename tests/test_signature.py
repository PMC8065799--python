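"""Candidate selection, survival-trend filtering, ppScore and stratification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from tilsig import (
    ExpressionMatrix,
    Scale,
    SignaturePanel,
    SurvivalCohort,
    compute_ppscore,
    select_top_candidates,
    stratify_by_percentile,
    trend_filter,
    score_and_stratify,
)


def _deg(rows):
    df = pd.DataFrame(rows, columns=["gene", "log2fc", "p_value", "class"])
    return df.set_index("gene")


class TestSelectTopCandidates:
    def test_top_k_of_each_class(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(50):
            rows.append((f"U{i:02d}", 2 + rng.random(), rng.random() * 0.05, "up"))
            rows.append((f"D{i:02d}", -2 - rng.random(), rng.random() * 0.05, "down"))
            rows.append((f"N{i:02d}", rng.normal(), rng.random(), "ns"))
        up, down = select_top_candidates(_deg(rows), k=10)
        assert len(up) == 10 and len(down) == 10
        assert all(g.startswith("U") for g in up)
        assert all(g.startswith("D") for g in down)

    def test_ranking_by_abs_fc_then_p(self):
        deg = _deg([
            ("A", 3.0, 0.04, "up"),
            ("B", 5.0, 0.01, "up"),
            ("C", 3.0, 0.01, "up"),
        ])
        up, _ = select_top_candidates(deg, k=3)
        assert up == ["B", "C", "A"]

    def test_full_tie_breaks_lexicographically(self):
        deg = _deg([("ZZZ", 2.5, 0.01, "up"), ("AAA", 2.5, 0.01, "up")])
        up, _ = select_top_candidates(deg, k=2)
        assert up == ["AAA", "ZZZ"]

    def test_short_class_returns_all_with_warning(self):
        deg = _deg([("A", 2.5, 0.01, "up"), ("B", 3.0, 0.01, "up"),
                    ("C", -2.5, 0.01, "down")])
        with pytest.warns(UserWarning, match="only 2"):
            up, down = select_top_candidates(deg, k=5)
        assert up == ["B", "A"] and down == ["C"]


def _cohort(expr_rows, genes, times, events):
    patients = [f"P{i}" for i in range(len(times))]
    clinical = pd.DataFrame(
        {"dss_time": times, "dss_event": events},
        index=pd.Index(patients, name="patient_id"))
    mat = ExpressionMatrix(pd.DataFrame(expr_rows, index=genes, columns=patients),
                           Scale.LINEAR_TPM)
    return SurvivalCohort(clinical, mat)


class TestTrendFilter:
    def test_event_mean_direction(self):
        # RISKY is higher in the two event patients, PROTECT lower
        cohort = _cohort(
            [[10, 10, 1, 1], [1, 1, 10, 10], [5, 5, 5, 5]],
            ["RISKY", "PROTECT", "FLAT"],
            [100, 120, 400, 500], [1, 1, 0, 0])
        panel = trend_filter(["RISKY", "PROTECT"], ["PROTECT", "RISKY"], cohort)
        assert panel.retained_up == ["RISKY"]
        assert panel.retained_down == ["PROTECT"]

    def test_annotation_funnel_recorded(self):
        cohort = _cohort([[1, 2, 3, 4]], ["G0"], [10, 20, 30, 40], [1, 1, 0, 0])
        panel = trend_filter(["G0", "UNKNOWN1"], ["UNKNOWN2"], cohort)
        assert panel.funnel()["candidates_up"] == 2
        assert panel.funnel()["annotated_up"] == 1
        assert panel.annotated_down == []

    def test_zero_events_rejected(self):
        cohort = _cohort([[1, 2, 3]], ["G0"], [10, 20, 30], [0, 0, 0])
        with pytest.raises(ValueError, match="no DSS events"):
            trend_filter(["G0"], [], cohort)

    def test_cox_sign_retains_planted_risk_gene(self):
        rng = np.random.default_rng(42)
        n = 200
        x = rng.normal(5, 1, n)
        t = rng.exponential(1000 * np.exp(-0.8 * (x - 5)))
        expr = np.vstack([np.power(2.0, x) - 1,
                          np.power(2.0, rng.normal(5, 1, n)) - 1])
        cohort = _cohort(expr, ["RISK", "NULL"], t, np.ones(n))
        panel = trend_filter(["RISK", "NULL"], [], cohort,
                             method="cox_sign", alpha=0.05)
        assert "RISK" in panel.retained_up
        assert panel.stats.loc["RISK", "p"] < 0.05

    def test_alpha_gate_monotone(self):
        rng = np.random.default_rng(3)
        n = 120
        expr = np.power(2.0, rng.normal(5, 1, size=(20, n))) - 1
        genes = [f"G{i}" for i in range(20)]
        cohort = _cohort(expr, genes, rng.exponential(500, n),
                         (rng.random(n) < 0.6).astype(float))
        loose = trend_filter(genes, [], cohort, method="cox_sign", alpha=0.9)
        tight = trend_filter(genes, [], cohort, method="cox_sign", alpha=0.05)
        assert set(tight.retained_up) <= set(loose.retained_up)

    def test_panel_json_round_trip(self, tmp_path):
        cohort = _cohort([[10, 10, 1, 1], [1, 1, 10, 10]], ["A", "B"],
                         [10, 20, 300, 400], [1, 1, 0, 0])
        panel = trend_filter(["A"], ["B"], cohort)
        path = tmp_path / "panel.json"
        panel.to_json(path)
        back = SignaturePanel.from_json(path)
        assert back.retained_up == panel.retained_up
        assert back.retained_down == panel.retained_down
        assert back.method == panel.method


def _panel(up, down):
    return SignaturePanel(candidates_up=up, candidates_down=down,
                          annotated_up=up, annotated_down=down,
                          retained_up=up, retained_down=down)


class TestComputePPScore:
    def test_hand_ratio(self):
        mat = ExpressionMatrix(
            pd.DataFrame({"P1": [2.0, 4.0, 1.0, 3.0]},
                         index=["U1", "U2", "D1", "D2"]), Scale.LINEAR_TPM)
        res = compute_ppscore(mat, _panel(["U1", "U2"], ["D1", "D2"]))
        assert res.scores["P1"] == pytest.approx(1.5)

    def test_scale_invariance_exact(self):
        rng = np.random.default_rng(8)
        vals = rng.uniform(1, 100, size=(6, 10))
        genes = [f"U{i}" for i in range(3)] + [f"D{i}" for i in range(3)]
        panel = _panel([f"U{i}" for i in range(3)], [f"D{i}" for i in range(3)])
        base = compute_ppscore(
            ExpressionMatrix(pd.DataFrame(vals, index=genes), Scale.LINEAR_TPM), panel)
        scaled = compute_ppscore(
            ExpressionMatrix(pd.DataFrame(vals * 37.5, index=genes), Scale.LINEAR_TPM),
            panel)
        np.testing.assert_allclose(base.scores.to_numpy(), scaled.scores.to_numpy(),
                                   rtol=1e-12)

    def test_gene_reorder_invariance_exact(self):
        rng = np.random.default_rng(9)
        vals = rng.uniform(1, 100, size=(6, 5))
        genes = ["U0", "U1", "U2", "D0", "D1", "D2"]
        mat = ExpressionMatrix(pd.DataFrame(vals, index=genes), Scale.LINEAR_TPM)
        a = compute_ppscore(mat, _panel(["U0", "U1", "U2"], ["D0", "D1", "D2"]))
        b = compute_ppscore(mat, _panel(["U2", "U0", "U1"], ["D1", "D2", "D0"]))
        np.testing.assert_allclose(a.scores.to_numpy(), b.scores.to_numpy(),
                                   rtol=1e-12)

    def test_identical_arms_give_unit_score(self):
        rng = np.random.default_rng(1)
        vals = np.tile(rng.uniform(1, 50, size=(2, 7)), (2, 1))
        mat = ExpressionMatrix(pd.DataFrame(vals, index=["U0", "U1", "D0", "D1"]),
                               Scale.LINEAR_TPM)
        res = compute_ppscore(mat, _panel(["U0", "U1"], ["D0", "D1"]))
        np.testing.assert_allclose(res.scores.to_numpy(), 1.0)

    def test_zero_down_arm_excluded(self):
        mat = ExpressionMatrix(
            pd.DataFrame({"P1": [5.0, 0.0], "P2": [5.0, 2.0]}, index=["U", "D"]),
            Scale.LINEAR_TPM)
        res = compute_ppscore(mat, _panel(["U"], ["D"]))
        assert np.isnan(res.scores["P1"])
        assert res.excluded_reason == {"P1": "zero_down_arm_mean"}

    def test_empty_arm_rejected(self):
        mat = ExpressionMatrix(pd.DataFrame({"P1": [1.0]}, index=["U"]),
                               Scale.LINEAR_TPM)
        with pytest.raises(ValueError, match="empty retained arm"):
            compute_ppscore(mat, SignaturePanel(candidates_up=["U"],
                                               candidates_down=[],
                                               retained_up=["U"],
                                               retained_down=[]))


class TestStratify:
    def test_18_distinct_scores_split_9_9(self):
        rng = np.random.default_rng(5)
        scores = pd.Series(rng.permutation(np.arange(1.0, 19.0)),
                           index=[f"P{i}" for i in range(18)])
        res = stratify_by_percentile(scores)
        assert res.n_high == 9 and res.n_low == 9

    def test_two_scores(self):
        res = stratify_by_percentile(pd.Series([1.0, 2.0], index=["a", "b"]))
        assert res.labels["a"] == "low" and res.labels["b"] == "high"

    def test_five_distinct_ties_to_low(self):
        res = stratify_by_percentile(
            pd.Series([10.0, 20.0, 30.0, 40.0, 50.0],
                      index=list("abcde")))
        assert res.threshold == 30.0
        assert res.n_low == 3 and res.n_high == 2

    def test_identical_scores_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            stratify_by_percentile(pd.Series([2.0, 2.0, 2.0]))

    def test_excluded_patients_keep_label(self):
        scores = pd.Series([1.0, 2.0, np.nan], index=["a", "b", "c"])
        res = stratify_by_percentile(scores)
        assert res.labels["c"] == "excluded"
        assert res.n_high + res.n_low == 2

    @given(st.lists(st.floats(min_value=0.1, max_value=1e6,
                              allow_nan=False, allow_infinity=False),
                    min_size=2, max_size=200, unique=True))
    def test_balance_contract(self, values):
        res = stratify_by_percentile(pd.Series(values))
        assert res.n_high + res.n_low == len(values)
        assert abs(res.n_high - res.n_low) <= 1
        assert (pd.Series(values)[res.labels == "high"] > res.threshold).all()


def test_score_and_stratify_requires_expression():
    clinical = pd.DataFrame({"dss_time": [1.0], "dss_event": [1]},
                            index=pd.Index(["P1"], name="patient_id"))
    with pytest.raises(ValueError, match="no attached expression"):
        score_and_stratify(SurvivalCohort(clinical), _panel(["U"], ["D"]))
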