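"""Regression models, spline dose-response, and multiple imputation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vistraj import association
from vistraj.errors import DataError, EstimationError


def cataract_2x2():
    # counts from the published class-by-level table
    return pd.DataFrame(
        {
            "high": [1] * 90 + [1] * 1740 + [0] * 67 + [0] * 338,
            "cataract": [1] * 90 + [0] * 1740 + [1] * 67 + [0] * 338,
        }
    )


class TestLogistic:
    def test_saturated_2x2_matches_closed_form_odds_ratio(self):
        res = association.logistic_fit(cataract_2x2(), "high", ["cataract"])
        closed = (90 * 338) / (67 * 1740)
        assert res.table.set_index("term").loc["cataract", "odds_ratio"] == pytest.approx(
            closed, abs=1e-8
        )

    def test_null_predictor_ci_covers_one(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame({"y": rng.integers(0, 2, 4000), "x": rng.standard_normal(4000)})
        res = association.logistic_fit(df, "y", ["x"])
        row = res.table.set_index("term").loc["x"]
        assert row["or_ci_low"] < 1.0 < row["or_ci_high"]
        assert abs(row["odds_ratio"] - 1.0) < 0.15

    def test_recovers_generating_log_odds(self):
        rng = np.random.default_rng(8)
        n = 3000
        x = rng.standard_normal(n)
        z = rng.integers(0, 2, n)
        lin = -0.5 + 0.8 * x + 0.4 * z
        y = (rng.random(n) < 1 / (1 + np.exp(-lin))).astype(int)
        df = pd.DataFrame({"y": y, "x": x, "z": z})
        res = association.logistic_fit(df, "y", ["x"], ["z"])
        t = res.table.set_index("term")
        for term, truth in (("x", 0.8), ("z", 0.4), ("const", -0.5)):
            assert abs(t.loc[term, "coef"] - truth) < 3 * t.loc[term, "se"]

    def test_separation_raises_naming_term(self):
        df = pd.DataFrame({"y": [0] * 20 + [1] * 20, "x": [0.0] * 20 + [1.0] * 20})
        with pytest.raises(EstimationError, match="x"):
            association.logistic_fit(df, "y", ["x"])

    def test_collinear_design_raises(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(200)
        df = pd.DataFrame({"y": rng.integers(0, 2, 200), "x": x, "x2": 2 * x})
        with pytest.raises(EstimationError, match="singular"):
            association.logistic_fit(df, "y", ["x", "x2"])

    def test_categorical_reference_coding(self, paper_cohort, true_labels):
        df = paper_cohort.estimation_view().copy()
        df["high"] = (true_labels == 0).astype(int)
        res = association.logistic_fit(df, "high", ["smoking"])
        terms = set(res.table["term"])
        assert "smoking[current]" in terms and "smoking[former]" in terms
        assert not any("never" in t for t in terms)  # reference level absorbed


class TestLinear:
    def test_outcome_equal_to_class_indicator(self):
        df = pd.DataFrame({"g": [0, 1, 0, 1, 1, 0], "y": [0.0, 1.0, 0.0, 1.0, 1.0, 0.0]})
        res = association.linear_fit(df, "y", ["g"])
        assert res.coef("g") == pytest.approx(1.0, abs=1e-12)
        assert res.se("g") == pytest.approx(0.0, abs=1e-9)

    def test_unadjusted_coefficient_equals_group_mean_difference(self, paper_cohort, true_labels):
        df = paper_cohort.estimation_view().copy()
        df["high"] = (true_labels == 0).astype(int)
        res = association.linear_fit(df, "iadl", ["high"])
        means = df.groupby("high")["iadl"].mean()
        assert res.coef("high") == pytest.approx(means[1] - means[0], abs=1e-10)

    def test_recovers_generating_outcome_shifts(self, paper_cohort, true_labels):
        # generating contrasts are the published unadjusted class effects
        df = paper_cohort.estimation_view().copy()
        df["high"] = (true_labels == 0).astype(int)
        for outcome, truth in (("cognition", 3.186), ("adl", -0.505), ("iadl", -2.447)):
            res = association.linear_fit(df, outcome, ["high"])
            assert abs(res.coef("high") - truth) < 3 * res.se("high")

    def test_subject_order_invariance(self, paper_cohort, true_labels):
        df = paper_cohort.estimation_view().copy()
        df["high"] = (true_labels == 0).astype(int)
        perm = np.random.default_rng(3).permutation(len(df))
        r1 = association.linear_fit(df, "cognition", ["high", "age"])
        r2 = association.linear_fit(df.iloc[perm], "cognition", ["high", "age"])
        assert np.allclose(r1.table["coef"], r2.table["coef"], atol=1e-10)

    def test_wald_ci_coverage_near_nominal(self):
        rng = np.random.default_rng(12)
        n, shift, hits, reps = 2235, 3.186, 0, 300
        for _ in range(reps):
            g = (rng.random(n) < 0.819).astype(float)
            y = 24.0 + shift * g + 6.0 * rng.standard_normal(n)
            x = np.column_stack([np.ones(n), g])
            beta, res, *_ = np.linalg.lstsq(x, y, rcond=None)
            sigma2 = res[0] / (n - 2)
            se = np.sqrt(sigma2 * np.linalg.inv(x.T @ x)[1, 1])
            hits += abs(beta[1] - shift) < 1.96 * se
        # 99.9% binomial band around 0.95 at 300 replicates
        assert 0.909 <= hits / reps <= 0.991


class TestSpline:
    KNOTS = (18.0, 21.0, 24.0, 28.0)

    def test_zero_nonlinear_terms_below_first_knot(self):
        b = association.rcs_basis(np.array([15.0, 17.9]), self.KNOTS)
        assert np.allclose(b[:, 1:], 0.0)

    def test_hand_evaluated_truncated_power_value(self):
        b = association.rcs_basis(np.array([22.0]), self.KNOTS)
        scale = (28.0 - 18.0) ** 2
        x1 = (22 - 18) ** 3 / scale  # later terms vanish at x=22
        x2 = (22 - 21) ** 3 / scale
        assert b[0, 1] == pytest.approx(x1)
        assert b[0, 2] == pytest.approx(x2)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.floats(28.5, 80.0), st.floats(0.2, 4.0))
    def test_linear_beyond_boundary_knots(self, x0, h):
        grid = np.array([x0, x0 + h, x0 + 2 * h])
        b = association.rcs_basis(grid, self.KNOTS)
        second_diff = b[0] - 2 * b[1] + b[2]
        assert np.allclose(second_diff, 0.0, atol=1e-8)

    def test_curve_is_zero_at_reference(self, paper_cohort, true_labels):
        df = paper_cohort.estimation_view().copy()
        df["high"] = (true_labels == 0).astype(int)
        spec = association.SplineSpec(reference=21.0)
        dose = association.rcs_dose_response(df, "bmi", "high", ["age"], spec)
        at_ref = dose.curve.loc[np.isclose(dose.curve["bmi"], 21.0), "log_odds"]
        assert np.allclose(at_ref, 0.0, atol=1e-12)

    def test_nonlinearity_detected_with_quadratic_effect(self):
        rng = np.random.default_rng(21)
        n = 4000
        x = rng.normal(22, 3, n)
        lin = 0.5 - 0.08 * (x - 22) ** 2
        y = (rng.random(n) < 1 / (1 + np.exp(-lin))).astype(int)
        df = pd.DataFrame({"y": y, "bmi": x})
        dose = association.rcs_dose_response(df, "bmi", "y", spec=association.SplineSpec())
        assert dose.p_nonlinearity < 0.05

    def test_type_one_error_controlled_under_linear_effect(self):
        rejections, reps = 0, 60
        for r in range(reps):
            rng = np.random.default_rng(3000 + r)
            n = 500
            x = rng.normal(22, 3, n)
            y = (rng.random(n) < 1 / (1 + np.exp(-(0.1 * (x - 22))))).astype(int)
            df = pd.DataFrame({"y": y, "bmi": x})
            dose = association.rcs_dose_response(df, "bmi", "y", spec=association.SplineSpec())
            rejections += dose.p_nonlinearity < 0.05
        # 99.9% binomial upper bound at nominal 5% over 60 replicates
        assert rejections <= 9

    def test_knots_outside_range_raise(self):
        df = pd.DataFrame({"y": [0, 1] * 20, "bmi": np.linspace(19, 23, 40)})
        with pytest.raises(DataError):
            association.rcs_dose_response(
                df, "bmi", "y", spec=association.SplineSpec(knots=(10.0, 20.0, 22.0, 40.0))
            )


class TestImputation:
    def test_rubin_rules_hand_arithmetic(self):
        pooled = association.rubin_pool([[1.0], [1.2], [1.4]], [[0.04], [0.04], [0.04]])
        assert pooled["estimate"][0] == pytest.approx(1.2)
        assert pooled["between_var"][0] == pytest.approx(0.04)
        assert pooled["total_var"][0] == pytest.approx(0.04 + (4 / 3) * 0.04)
        assert pooled["total_var"][0] == pytest.approx(0.0933, abs=5e-4)

    def test_no_missing_values_equals_direct_fit(self, paper_cohort, true_labels):
        df = paper_cohort.estimation_view().copy()
        df["high"] = (true_labels == 0).astype(int)
        direct = association.linear_fit(df, "cognition", ["high"], ["age"])
        mi = association.impute_and_pool(df, "linear", "cognition", ["high"], ["age"], m=3, seed=0)
        assert np.allclose(mi.table["coef"], direct.table["coef"], atol=1e-12)
        assert mi.pooled_m is None  # reduces to the direct fit, B = 0

    def test_mcar_missingness_recovery(self, paper_cohort, true_labels):
        df = paper_cohort.estimation_view().copy()
        df["high"] = (true_labels == 0).astype(int)
        rng = np.random.default_rng(4)
        df.loc[rng.random(len(df)) < 0.15, "age"] = np.nan
        mi = association.impute_and_pool(
            df, "linear", "cognition", ["high"], ["age"], m=5, seed=5
        )
        direct_truth = 3.186  # generating class shift
        assert abs(mi.coef("high") - direct_truth) < 3 * mi.se("high")
        assert mi.pooled_m == 5

    def test_fully_missing_variable_raises(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 3.0, 4.0], "g": [0, 1, 0, 1], "x": [np.nan] * 4})
        with pytest.raises(DataError):
            association.impute_and_pool(df, "linear", "y", ["g"], ["x"], m=2, seed=0)
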