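import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from cinelv.errors import CohortSchemaError, UndefinedCorrelationError
from cinelv.remodelling import (
    OUTCOMES_WK4,
    PREDICTORS_WK1,
    CorrelationTable,
    correlation_table,
    ols_fit,
    stepwise_forward,
    table1_report,
    validate_cohort,
)
from cinelv.synthetic import CohortSpec, generate_cohort


def _mi_frame(**cols):
    n = len(next(iter(cols.values())))
    base = {"subject_id": [f"m{i}" for i in range(n)], "group": "MI"}
    base.update(cols)
    return pd.DataFrame(base)


class TestCorrelationTable:
    def test_hand_dataset_matches_covariance_formula(self):
        x = np.array([1.0, 2.0, 4.0, 7.0, 11.0])
        y = np.array([2.0, 1.5, 5.0, 6.0, 12.0])
        df = _mi_frame(x=x, y=y)
        ct = correlation_table(df, ["x"], ["y"])
        r_oracle = (np.mean(x * y) - x.mean() * y.mean()) / (
            np.std(x) * np.std(y))
        n = 5
        t = r_oracle * np.sqrt(n - 2) / np.sqrt(1 - r_oracle**2)
        p_oracle = 2 * stats.t.sf(abs(t), n - 2)
        row = ct.table.iloc[0]
        assert row["r"] == pytest.approx(r_oracle, abs=1e-12)
        assert row["p"] == pytest.approx(p_oracle, rel=1e-9)
        assert row["n"] == 5

    def test_perfect_linear_relation(self):
        x = np.arange(1.0, 11.0)
        df = _mi_frame(x=x, y=3 * x + 2)
        row = correlation_table(df, ["x"], ["y"]).table.iloc[0]
        assert row["r"] == pytest.approx(1.0)
        assert row["p"] < 1e-12

    def test_constant_column_named_in_error(self):
        df = _mi_frame(x=np.ones(5), y=np.arange(5.0))
        with pytest.raises(UndefinedCorrelationError, match="x"):
            correlation_table(df, ["x"], ["y"])

    def test_sham_rows_excluded_by_default(self):
        x = np.arange(1.0, 9.0)
        df = _mi_frame(x=x, y=2 * x)
        sham = pd.DataFrame({"subject_id": ["s0", "s1"], "group": "sham",
                             "x": [100.0, -100.0], "y": [-50.0, 50.0]})
        both = pd.concat([df, sham], ignore_index=True)
        row = correlation_table(both, ["x"], ["y"]).table.iloc[0]
        assert row["r"] == pytest.approx(1.0)
        assert row["n"] == 8


class TestOlsFit:
    def test_two_points_interpolate(self):
        df = _mi_frame(x=[1.0, 3.0], y=[2.0, 8.0])
        fit = ols_fit(df, "y", "x")
        assert fit.slope == pytest.approx(3.0)
        assert fit.intercept == pytest.approx(-1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_noise_free_cohort_recovers_printed_line(self):
        spec = CohortSpec(seed=5, esv1_sd=0, sv1_sd=0, mass1_sd=0, is1_sd=0,
                          edv4_sd=0, esv4_sd=0, mass4_sd=0, ef4_sd=0)
        cohort, truth = generate_cohort(spec)
        fit = ols_fit(cohort, "lv_edv_wk4", "lv_esv_wk1")
        assert fit.slope == pytest.approx(1.33, rel=1e-9)
        assert fit.intercept == pytest.approx(26.0, rel=1e-9)

    def test_constant_predictor(self):
        df = _mi_frame(x=np.ones(5), y=np.arange(5.0))
        with pytest.raises(CohortSchemaError):
            ols_fit(df, "y", "x")

    def test_r_squared_equals_pearson_r_squared(self, default_cohort):
        cohort, _ = default_cohort
        fit = ols_fit(cohort, "lv_edv_wk4", "lv_esv_wk1")
        r = correlation_table(cohort, ["lv_esv_wk1"], ["lv_edv_wk4"]).table.iloc[0]["r"]
        assert fit.r_squared == pytest.approx(r**2, abs=1e-12)

    def test_matches_statsmodels(self, default_cohort):
        cohort, _ = default_cohort
        fit = ols_fit(cohort, "lv_edv_wk4", "lv_esv_wk1")
        mi = cohort[cohort.group == "MI"]
        X = sm.add_constant(mi["lv_esv_wk1"].to_numpy())
        sm_fit = sm.OLS(mi["lv_edv_wk4"].to_numpy(), X).fit()
        assert fit.intercept == pytest.approx(sm_fit.params[0], rel=1e-10)
        assert fit.slope == pytest.approx(sm_fit.params[1], rel=1e-10)
        assert fit.intercept_se == pytest.approx(sm_fit.bse[0], rel=1e-8)
        assert fit.slope_se == pytest.approx(sm_fit.bse[1], rel=1e-8)
        assert fit.r_squared == pytest.approx(sm_fit.rsquared, rel=1e-10)

    def test_unit_rescaling_transforms_coefficients(self, default_cohort):
        cohort, _ = default_cohort
        fit_ul = ols_fit(cohort, "lv_edv_wk4", "lv_esv_wk1")
        ml = cohort.copy()
        ml["lv_esv_wk1"] /= 1000.0  # ul -> ml
        ml["lv_edv_wk4"] /= 1000.0
        fit_ml = ols_fit(ml, "lv_edv_wk4", "lv_esv_wk1")
        assert fit_ml.slope == pytest.approx(fit_ul.slope, rel=1e-9)
        assert fit_ml.intercept == pytest.approx(fit_ul.intercept / 1000.0, rel=1e-9)
        assert fit_ml.r_squared == pytest.approx(fit_ul.r_squared, rel=1e-12)


class TestStepwiseForward:
    def test_single_candidate_reduces_to_ols_entry_decision(self, default_cohort):
        cohort, _ = default_cohort
        res = stepwise_forward(cohort, "lv_edv_wk4", ["lv_esv_wk1"])
        # with one candidate the partial F is the squared slope t of the
        # simple regression, so entry <=> simple-regression p < alpha
        mi = cohort[cohort.group == "MI"]
        lr = stats.linregress(mi["lv_esv_wk1"], mi["lv_edv_wk4"])
        assert res.selected == (["lv_esv_wk1"] if lr.pvalue < 0.05 else [])
        assert res.steps[0].p == pytest.approx(lr.pvalue, rel=1e-9)
        assert res.steps[0].partial_f == pytest.approx(
            (lr.slope / lr.stderr) ** 2, rel=1e-9)

    def test_first_step_partial_f_matches_statsmodels(self, default_cohort):
        cohort, _ = default_cohort
        res = stepwise_forward(cohort, "lv_edv_wk4", PREDICTORS_WK1)
        mi = cohort[cohort.group == "MI"]
        first = res.steps[0].predictor
        X = sm.add_constant(mi[first].to_numpy())
        sm_fit = sm.OLS(mi["lv_edv_wk4"].to_numpy(), X).fit()
        assert res.steps[0].p == pytest.approx(sm_fit.pvalues[1], rel=1e-8)

    def test_selects_generating_predictor_on_default_cohort(self, default_cohort):
        cohort, _ = default_cohort
        res = stepwise_forward(cohort, "lv_edv_wk4", PREDICTORS_WK1)
        assert res.selected[0] == "lv_esv_wk1"

    def test_duplicated_candidate_entered_once(self, default_cohort):
        cohort, _ = default_cohort
        dup = cohort.copy()
        dup["lv_esv_wk1_copy"] = dup["lv_esv_wk1"]
        with pytest.warns(UserWarning, match="collinear"):
            res = stepwise_forward(
                dup, "lv_edv_wk4", ["lv_esv_wk1", "lv_esv_wk1_copy"])
        assert res.selected == ["lv_esv_wk1"]

    def test_r_squared_nondecreasing_across_steps(self):
        rng = np.random.default_rng(21)
        n = 40
        a = rng.normal(0, 1, n)
        b = rng.normal(0, 1, n)
        y = 2 * a + 1 * b + rng.normal(0, 0.5, n)
        df = _mi_frame(a=a, b=b, c=rng.normal(0, 1, n), y=y)
        res = stepwise_forward(df, "y", ["a", "b", "c"])
        r2 = [s.r_squared_after for s in res.steps]
        assert res.selected[:2] == ["a", "b"]
        assert r2 == sorted(r2)

    def test_too_few_rows(self):
        df = _mi_frame(a=[1.0, 2.0], y=[1.0, 2.0])
        with pytest.raises(CohortSchemaError):
            stepwise_forward(df, "y", ["a"], entry_alpha=0.05)


class TestTable1Report:
    def test_best_predictor_is_esv_wk1_for_volume_and_mass(self, default_cohort):
        cohort, _ = default_cohort
        ct, formatted = table1_report(cohort)
        best = ct.best_predictors()
        for outcome in ("lv_mass_wk4", "lv_esv_wk4", "lv_edv_wk4"):
            assert best[outcome] == "lv_esv_wk1"
        assert formatted.shape == (len(PREDICTORS_WK1), len(OUTCOMES_WK4))
        assert len(ct.table) == 20

    def test_independent_columns_show_no_strong_correlation(self):
        rng = np.random.default_rng(9)
        n = 50
        cols = {c: rng.normal(50, 5, n) for c in PREDICTORS_WK1 + OUTCOMES_WK4}
        df = _mi_frame(**cols)
        ct = correlation_table(df)
        assert (ct.table["r"].abs() < 0.6).all()

    def test_report_survives_serialisation(self, default_cohort, tmp_path):
        cohort, _ = default_cohort
        ct, _ = table1_report(cohort)
        ct.to_json(tmp_path / "ct.json")
        import json

        records = json.loads((tmp_path / "ct.json").read_text())
        rebuilt = CorrelationTable.from_records(records)
        pd.testing.assert_frame_equal(rebuilt.table, ct.table)

    def test_regression_plot_export(self, default_cohort, tmp_path):
        from cinelv.remodelling import plot_regression

        cohort, _ = default_cohort
        fit = plot_regression(cohort, "lv_edv_wk4", "lv_esv_wk1",
                              tmp_path / "fig.png")
        assert (tmp_path / "fig.png").stat().st_size > 0
        assert fit.slope == pytest.approx(
            ols_fit(cohort, "lv_edv_wk4", "lv_esv_wk1").slope)

    def test_schema_validation(self, default_cohort):
        cohort, _ = default_cohort
        with pytest.raises(CohortSchemaError, match="lv_esv_wk1"):
            table1_report(cohort.drop(columns=["lv_esv_wk1"]))
        dup = pd.concat([cohort, cohort.iloc[:1]], ignore_index=True)
        with pytest.raises(CohortSchemaError, match="duplicated"):
            validate_cohort(dup)
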