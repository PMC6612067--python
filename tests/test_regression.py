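"""Logistic persistence models: closed-form oracles, elimination, LRT, report."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from husegment.regression import (
    FitError,
    ModelDesign,
    backward_eliminate,
    build_design,
    fit_logistic,
    likelihood_ratio_test,
    report_models,
)


def design_from_arrays(y, columns: dict, factors: dict, forced=None) -> ModelDesign:
    X = pd.DataFrame({"const": np.ones(len(y)), **columns})
    return ModelDesign(
        y=pd.Series(y), X=X, factors=factors, forced=forced or set()
    )


def expand_2x2(a, b, c, d):
    """Individual rows for an exposed/unexposed 2x2 outcome table."""
    y = [1] * a + [0] * b + [1] * c + [0] * d
    x = [1.0] * (a + b) + [0.0] * (c + d)
    return np.array(y), np.array(x)


class TestFitOracle:
    def test_or_equals_cross_product_ratio(self):
        # exposed 20/80, unexposed 10/90 -> OR = (20/80)/(10/90) = 2.25
        y, x = expand_2x2(20, 80, 10, 90)
        fit = fit_logistic(design_from_arrays(y, {"x": x}, {"x": ["x"]}))
        assert fit.or_table.set_index("term").at["x", "OR"] == pytest.approx(
            2.25, rel=1e-6
        )

    def test_independent_covariate_gives_null_or(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 4000)
        x = rng.integers(0, 2, 4000).astype(float)
        fit = fit_logistic(design_from_arrays(y, {"x": x}, {"x": ["x"]}))
        row = fit.or_table.set_index("term").loc["x"]
        assert row["ci_low"] < 1 < row["ci_high"]
        assert row["OR"] == pytest.approx(1.0, abs=0.25)

    def test_intercept_only_model_has_zero_mcfadden(self):
        y = np.array([0, 0, 1, 1, 1, 0])
        fit = fit_logistic(design_from_arrays(y, {}, {}))
        assert fit.mcfadden_r2 == pytest.approx(0.0, abs=1e-9)
        assert fit.deviance == pytest.approx(-2 * fit.loglik)

    def test_constant_outcome_is_a_fit_error(self):
        y = np.ones(10)
        with pytest.raises(FitError, match="constant"):
            fit_logistic(design_from_arrays(y, {"x": np.arange(10.0)}, {"x": ["x"]}))

    def test_complete_separation_is_a_fit_error(self):
        y = np.array([0] * 20 + [1] * 20)
        x = y.astype(float)
        with pytest.raises(FitError, match="separation"):
            fit_logistic(design_from_arrays(y, {"x": x}, {"x": ["x"]}))

    def test_collinear_column_dropped_with_warning(self, caplog):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 200)
        x = rng.normal(size=200)
        with caplog.at_level("WARNING"):
            fit = fit_logistic(
                design_from_arrays(
                    y, {"x": x, "x2": 2 * x}, {"x": ["x"], "x2": ["x2"]}
                )
            )
        assert "collinear" in caplog.text
        assert "x2" not in fit.params.index


class TestLRT:
    def test_identical_models_give_zero_chi2(self):
        y = np.array([0, 1] * 20)
        fit = fit_logistic(design_from_arrays(y, {}, {}))
        chi2, df, p = likelihood_ratio_test(fit, fit)
        assert chi2 == 0.0 and p == 1.0

    def test_chi2_survival_oracle(self):
        assert stats.chi2.sf(10, 1) == pytest.approx(1.565e-3, rel=1e-3)

    def test_added_strong_predictor_is_detected(self):
        rng = np.random.default_rng(8)
        n = 2000
        x = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(0.1 + 1.5 * x)))  # strong effect, power ~1
        y = (rng.random(n) < p).astype(int)
        null = fit_logistic(design_from_arrays(y, {}, {}))
        full = fit_logistic(design_from_arrays(y, {"x": x}, {"x": ["x"]}))
        chi2, df, pval = likelihood_ratio_test(null, full)
        assert df == 1 and pval < 1e-3
        assert full.deviance <= null.deviance  # deviance non-increasing

    def test_non_nested_models_rejected(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 60)
        a = fit_logistic(design_from_arrays(y, {"x": rng.normal(size=60)}, {"x": ["x"]}))
        b = fit_logistic(design_from_arrays(y, {"z": rng.normal(size=60)}, {"z": ["z"]}))
        with pytest.raises(ValueError, match="nested"):
            likelihood_ratio_test(a, b)


def simulate_factor_design(rng, n=5000, noise_levels=4, strong_beta=1.0):
    """Binary exposure (real effect), strong 4-level factor, pure-noise factor."""
    expo = rng.integers(0, 2, n).astype(float)
    strong = rng.integers(0, 4, n)
    noise = rng.integers(0, noise_levels, n)
    eta = -1.5 + 0.8 * expo + strong_beta * (strong > 0)
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    cols = {"expo": expo}
    factors = {"expo": ["expo"]}
    for name, arr, k in (("strong", strong, 4), ("noise", noise, noise_levels)):
        for lv in range(1, k):
            col = f"{name}[{lv}]"
            cols[col] = (arr == lv).astype(float)
            factors.setdefault(name, []).append(col)
    return design_from_arrays(y, cols, factors, forced={"expo"})


class TestBackwardElimination:
    def test_noise_removed_strong_and_forced_retained(self):
        rng = np.random.default_rng(123)
        design = simulate_factor_design(rng)
        fit, final, trace = backward_eliminate(design, alpha=0.001)
        removed = {t["removed"] for t in trace}
        assert "noise" in removed
        assert "strong" in final.factors and "expo" in final.factors

    def test_forced_exposure_survives_even_as_pure_noise(self):
        rng = np.random.default_rng(5)
        n = 2000
        expo = rng.integers(0, 2, n).astype(float)  # unrelated to outcome
        y = rng.integers(0, 2, n)
        design = design_from_arrays(y, {"expo": expo}, {"expo": ["expo"]},
                                    forced={"expo"})
        fit, final, trace = backward_eliminate(design, alpha=0.001)
        assert trace == [] and "expo" in final.factors

    def test_strongly_associated_factors_yield_empty_trace(self):
        rng = np.random.default_rng(77)
        design = simulate_factor_design(rng, noise_levels=4, strong_beta=2.0)
        design = design.drop_factors(["noise"])
        fit, final, trace = backward_eliminate(design, alpha=0.001)
        assert trace == []

    def test_wald_criterion_agrees_on_clear_cases(self):
        rng = np.random.default_rng(9)
        design = simulate_factor_design(rng)
        _, _, trace = backward_eliminate(design, alpha=0.001, criterion="wald")
        assert {t["removed"] for t in trace} == {"noise"}


class TestBuildDesign:
    def covariates(self, pids):
        n = len(pids)
        return pd.DataFrame(
            {
                "patient_id": pids,
                "age_at_first_visit": 50.0,
                "ccmi": [np.nan] + [1.0] * (n - 1),
                "pps": 2.0,
                "gender": ["female"] * n,
                "race": ["chinese"] * n,
                "nationality": ["singaporean"] * n,
                "treatment_tier": ["subsidised_only"] * n,
                "housing_type": ["flat_3room_plus"] * n,
            }
        )

    def seg(self):
        pids = [f"P{i}" for i in range(6)]
        return pd.DataFrame(
            {
                "patient_id": pids,
                "group": ["NonHU", "Cost", "SOC", "NonHU", "Cost", "NonHU"],
                "persisted": pd.array(
                    [False, True, True, pd.NA, False, True], dtype="boolean"
                ),
            }
        )

    def test_decedents_excluded_and_missing_ccmi_zeroed(self):
        d = build_design(self.seg(), self.covariates([f"P{i}" for i in range(6)]), "m1")
        assert d.n == 5  # P3 (persisted NA -> died in year 1) excluded
        assert d.X["ccmi"].iloc[0] == 0.0  # P0's missing CCMI -> 0

    def test_m0_has_only_group_factor(self):
        d = build_design(self.seg(), self.covariates([f"P{i}" for i in range(6)]), "m0")
        assert set(d.factors) == {"group"}
        assert d.forced == {"group"}

    def test_m2_adds_condition_indicators(self):
        flags = pd.DataFrame({"patient_id": ["P0", "P1"], "CondA": [1, 0]})
        d = build_design(
            self.seg(), self.covariates([f"P{i}" for i in range(6)]), "m2",
            common_conditions=["CondA"], condition_flags=flags,
        )
        assert "cond: CondA" in d.factors
        col = d.X["cond: CondA"]
        assert col.iloc[0] == 1.0 and col.sum() == 1.0


def test_report_blanks_eliminated_factors_and_prints_reference_rows():
    rng = np.random.default_rng(31)
    n = 3000
    g = rng.choice(["NonHU", "Cost", "SOC"], n, p=[0.7, 0.15, 0.15])
    eta = -2.0 + 1.0 * (g == "Cost") + 1.5 * (g == "SOC")
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    seg = pd.DataFrame(
        {"patient_id": [f"P{i}" for i in range(n)], "group": g,
         "persisted": pd.array(y.astype(bool), dtype="boolean")}
    )
    cov = pd.DataFrame(
        {"patient_id": seg["patient_id"], "age_at_first_visit": 40.0,
         "ccmi": 0.0, "pps": rng.integers(0, 5, n).astype(float),
         "gender": rng.choice(["female", "male"], n),
         "race": "chinese", "nationality": "singaporean",
         "treatment_tier": "subsidised_only", "housing_type": "flat_3room_plus"}
    )
    fit0 = fit_logistic(build_design(seg, cov, "m0"))
    fit1, d1, trace = backward_eliminate(build_design(seg, cov, "m1"))
    report = report_models(
        {"m0": fit0, "m1": fit1}, {"m1": likelihood_ratio_test(fit0, fit1)}
    )
    ref_row = report[report["term"] == "group[NonHU] (ref)"].iloc[0]
    assert ref_row["m0"] == "1.00" and ref_row["m1"] == "1.00"
    removed = {t["removed"] for t in trace}
    for f in removed:
        rows = report[report["factor"] == f]
        assert (rows["m1"] == "").all() if len(rows) else True
    # printed ORs parse back to the fitted values at 2-decimal rounding
    cost_or = float(report.loc[report["term"] == "group[Cost]", "m0"].iloc[0].split()[0])
    assert cost_or == pytest.approx(
        fit0.or_table.set_index("term").at["group[Cost]", "OR"], abs=0.005
    )
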