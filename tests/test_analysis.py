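import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from phenotyper import synthetic
from phenotyper.analysis import (
    CoxFitError,
    choose_imputation_method,
    compute_risk_scores,
    evaluate_auc,
    fit_cox,
    impute,
    km_by_median,
    pooled_stepwise_select,
    rubin_pool,
    standardize,
    train_validate_split,
)


class TestChooseImputationMethod:
    def test_binary_flag_pmm(self):
        assert choose_imputation_method(pd.Series([0, 1, 1, 0, 1])) == "PMM"

    def test_symmetric_continuous_model_prediction(self, rng):
        values = pd.Series(rng.normal(0, 1, 2000))
        assert choose_imputation_method(values) == "MODEL_PREDICTION"

    def test_lognormal_pmm(self, rng):
        values = pd.Series(rng.lognormal(0, 1, 2000))
        assert choose_imputation_method(values) == "PMM"

    def test_categorical_pmm(self):
        assert choose_imputation_method(pd.Series(["a", "b", None])) == "PMM"

    def test_all_missing_errors(self):
        with pytest.raises(ValueError):
            choose_imputation_method(pd.Series([np.nan, np.nan]))


class TestImpute:
    def panel_with_missing(self, rng, n=200, rate=0.2):
        z = rng.normal(0, 1, n)
        x = 0.8 * z + rng.normal(0, 0.6, n)
        frame = pd.DataFrame({"participant_id": [f"P{i}" for i in range(n)],
                              "z": z, "x": x})
        frame.loc[rng.random(n) < rate, "x"] = np.nan
        return frame

    def test_no_missing_yields_identical_copies(self, rng):
        frame = pd.DataFrame({"participant_id": ["P1", "P2"], "x": [1.0, 2.0]})
        result = impute(frame, m=3, seed=0)
        for panel in result.panels:
            pd.testing.assert_frame_equal(panel, frame)

    def test_deterministic_given_seed(self, rng):
        frame = self.panel_with_missing(rng)
        a = impute(frame, m=3, seed=42)
        b = impute(frame, m=3, seed=42)
        for pa, pb in zip(a.panels, b.panels):
            pd.testing.assert_frame_equal(pa, pb)

    def test_observed_cells_untouched(self, rng):
        frame = self.panel_with_missing(rng)
        observed = frame["x"].notna()
        result = impute(frame, m=3, seed=0)
        for panel in result.panels:
            assert np.allclose(panel.loc[observed, "x"], frame.loc[observed, "x"])

    def test_mcar_pooled_mean_covers_truth(self):
        # simulation oracle: Rubin CI for the mean covers 0 in >= 90% of reps
        n, covered = 300, 0
        reps = 100
        for rep in range(reps):
            rng = np.random.default_rng(1000 + rep)
            z = rng.normal(0, 1, n)
            x = 0.8 * z + rng.normal(0, 0.6, n)  # true mean 0
            frame = pd.DataFrame({"z": z, "x": x})
            frame.loc[rng.random(n) < 0.2, "x"] = np.nan
            result = impute(frame, m=5, seed=rep, n_iter=5)
            means = np.array([p["x"].mean() for p in result.panels])
            variances = np.array([p["x"].var(ddof=1) / n for p in result.panels])
            qbar = means.mean()
            total = variances.mean() + (1 + 1 / 5) * means.var(ddof=1)
            half = 1.96 * np.sqrt(total)
            covered += (qbar - half <= 0.0 <= qbar + half)
        assert covered >= 0.90 * reps


class TestFitCox:
    def test_null_covariate_near_zero(self):
        panel = synthetic.simulate_survival_panel(3000, {"x_bin": 0.0}, seed=5)
        beta, _ = fit_cox(panel, ["x_bin"])
        assert abs(beta.iloc[0]) < 0.1

    def test_planted_loghr_recovered(self):
        panel = synthetic.simulate_survival_panel(3000, {"x": 0.5}, seed=6)
        beta, cov = fit_cox(panel, ["x"])
        assert beta.iloc[0] == pytest.approx(0.5, abs=0.1)
        assert cov.iloc[0, 0] > 0

    def test_duplicate_columns_error(self):
        panel = synthetic.simulate_survival_panel(500, {"x": 0.5}, seed=7)
        panel["x_copy"] = panel["x"]
        with pytest.raises(CoxFitError, match="collinear"):
            fit_cox(panel, ["x", "x_copy"])

    def test_constant_column_error(self):
        panel = synthetic.simulate_survival_panel(500, {"x": 0.5}, seed=8)
        panel["const"] = 1.0
        with pytest.raises(CoxFitError, match="constant"):
            fit_cox(panel, ["x", "const"])

    def test_no_events_error(self):
        panel = synthetic.simulate_survival_panel(100, {"x": 0.0}, seed=9)
        panel["status"] = 0
        with pytest.raises(CoxFitError, match="no events"):
            fit_cox(panel, ["x"])


class TestRubinPool:
    def test_worked_example(self):
        coefs = [pd.Series({"x": 0.5}), pd.Series({"x": 0.7})]
        variances = [pd.Series({"x": 0.01}), pd.Series({"x": 0.01})]
        pooled = rubin_pool(coefs, variances)
        assert pooled.loc["x", "coef"] == pytest.approx(0.6)
        assert pooled.loc["x", "total_var"] == pytest.approx(0.04)
        assert pooled.loc["x", "se"] == pytest.approx(0.2)

    def test_identical_fits_reduce_to_within_se(self):
        coefs = [pd.Series({"x": 0.5})] * 3
        variances = [pd.Series({"x": 0.01})] * 3
        pooled = rubin_pool(coefs, variances)
        assert pooled.loc["x", "se"] == pytest.approx(0.1)

    def test_matches_textbook_formula_on_random_fits(self, rng):
        m = 7
        coefs = [pd.Series({"a": v}) for v in rng.normal(0.3, 0.2, m)]
        variances = [pd.Series({"a": v}) for v in rng.uniform(0.01, 0.05, m)]
        pooled = rubin_pool(coefs, variances)
        # independent textbook computation
        q = np.array([c["a"] for c in coefs])
        w = np.array([v["a"] for v in variances])
        B = q.var(ddof=1)
        T = w.mean() + (1 + 1 / m) * B
        r = (1 + 1 / m) * B / w.mean()
        df = (m - 1) * (1 + 1 / r) ** 2
        p = 2 * stats.t.sf(abs(q.mean() / np.sqrt(T)), df)
        assert pooled.loc["a", "coef"] == pytest.approx(q.mean())
        assert pooled.loc["a", "total_var"] == pytest.approx(T)
        assert pooled.loc["a", "p"] == pytest.approx(p, rel=1e-9)

    def test_mismatched_coefficients_error(self):
        with pytest.raises(ValueError, match="mismatch"):
            rubin_pool([pd.Series({"a": 1.0}), pd.Series({"b": 1.0})],
                       [pd.Series({"a": 0.1}), pd.Series({"b": 0.1})])

    def test_single_fit_errors(self):
        with pytest.raises(ValueError):
            rubin_pool([pd.Series({"a": 1.0})], [pd.Series({"a": 0.1})])


class TestPooledStepwise:
    def panels(self, seed=11, n=800):
        panel = synthetic.simulate_survival_panel(
            n, {"age": 0.02, "signal": 0.6}, seed=seed, n_noise=1)
        return [panel.copy(), panel.copy()]

    def test_empty_candidates_base_model_only(self):
        result = pooled_stepwise_select(self.panels(), candidates=[], forced=["age"])
        assert result.selected_vars == []
        assert list(result.summary.index) == ["age"]

    def test_selects_signal_over_noise(self):
        result = pooled_stepwise_select(
            self.panels(), candidates=["signal", "noise_0"], forced=["age"])
        assert "signal" in result.selected_vars

    def test_forced_vars_always_present(self):
        result = pooled_stepwise_select(
            self.panels(), candidates=["signal"], forced=["age"])
        assert "age" in result.summary.index

    def test_trace_replay_reproduces_model(self):
        result = pooled_stepwise_select(
            self.panels(), candidates=["signal", "noise_0"], forced=["age"])
        model = []
        for _, action, var, _ in result.selection_trace:
            if action == "add":
                model.append(var)
            else:
                model.remove(var)
        assert model == result.selected_vars

    def test_deterministic(self):
        a = pooled_stepwise_select(self.panels(), candidates=["signal", "noise_0"],
                                   forced=["age"])
        b = pooled_stepwise_select(self.panels(), candidates=["signal", "noise_0"],
                                   forced=["age"])
        assert a.selected_vars == b.selected_vars
        assert a.selection_trace == b.selection_trace

    def test_hr_ci_shape(self):
        result = pooled_stepwise_select(self.panels(), candidates=["signal"],
                                        forced=["age"])
        row = result.summary.loc["signal"]
        assert row["ci_low"] == pytest.approx(np.exp(row["coef"] - 1.96 * row["se"]))
        assert row["ci_high"] == pytest.approx(np.exp(row["coef"] + 1.96 * row["se"]))


class TestSplitAndScores:
    def test_two_to_one_split(self):
        train, valid = train_validate_split([f"P{i}" for i in range(300)], seed=1)
        assert len(train) == 200 and len(valid) == 100

    def test_partition(self):
        ids = [f"P{i}" for i in range(100)]
        train, valid = train_validate_split(ids, seed=2)
        assert set(train) | set(valid) == set(ids)
        assert set(train) & set(valid) == set()

    def test_deterministic(self):
        ids = [f"P{i}" for i in range(50)]
        assert (train_validate_split(ids, seed=3)[0] ==
                train_validate_split(ids, seed=3)[0]).all()

    def test_scores_m1_identity(self):
        panel = pd.DataFrame({"participant_id": ["A", "B"],
                              "x": [1.0, 2.0], "y": [0.5, -0.5]})
        beta = pd.Series({"x": 2.0, "y": 1.0})
        center = pd.Series({"x": 0.0, "y": 0.0})
        scores = compute_risk_scores([(beta, center)], [panel])
        assert scores["A"] == pytest.approx(2.5)
        assert scores["B"] == pytest.approx(3.5)

    def test_zero_beta_equal_scores(self):
        panel = pd.DataFrame({"participant_id": ["A", "B"], "x": [1.0, 9.0]})
        beta = pd.Series({"x": 0.0})
        scores = compute_risk_scores([(beta, pd.Series({"x": 0.0}))], [panel])
        assert scores["A"] == scores["B"] == 0.0

    def test_mean_of_dot_products_oracle(self, rng):
        panels, fits = [], []
        base = pd.DataFrame({"participant_id": ["A", "B", "C"],
                             "x": rng.normal(0, 1, 3), "y": rng.normal(0, 1, 3)})
        expected = np.zeros(3)
        m = 4
        for _ in range(m):
            beta = pd.Series({"x": rng.normal(), "y": rng.normal()})
            center = pd.Series({"x": rng.normal(), "y": rng.normal()})
            fits.append((beta, center))
            panels.append(base)
            expected += (base[["x", "y"]].to_numpy() - center[["x", "y"]].to_numpy()) \
                @ beta[["x", "y"]].to_numpy()
        scores = compute_risk_scores(fits, panels)
        assert np.allclose(scores.to_numpy(), expected / m)

    def test_missing_covariate_errors(self):
        panel = pd.DataFrame({"participant_id": ["A"], "x": [1.0]})
        beta = pd.Series({"x": 1.0, "zz": 1.0})
        with pytest.raises(ValueError, match="zz"):
            compute_risk_scores([(beta, pd.Series({"x": 0.0, "zz": 0.0}))], [panel])


class TestEvaluateAuc:
    def test_perfect_separation(self):
        auc, _ = evaluate_auc([1.0, 0.9, 0.1, 0.2], [1, 1, 0, 0])
        assert auc == 1.0

    def test_toy_three_quarters(self):
        auc, _ = evaluate_auc([0.9, 0.6, 0.7, 0.1], [1, 1, 0, 0])
        assert auc == pytest.approx(0.75)

    def test_null_limit(self, rng):
        scores = rng.normal(0, 1, 4000)
        status = (rng.random(4000) < 0.5).astype(int)
        auc, (lo, hi) = evaluate_auc(scores, status)
        assert auc == pytest.approx(0.5, abs=0.03)
        assert lo <= 0.5 <= hi

    def test_ties_count_half(self):
        auc, _ = evaluate_auc([0.5, 0.5], [1, 0])
        assert auc == pytest.approx(0.5)

    def test_one_class_errors(self):
        with pytest.raises(ValueError):
            evaluate_auc([0.1, 0.2], [1, 1])

    @settings(max_examples=25, deadline=None)
    @given(st.sampled_from(["exp", "cube", "affine"]))
    def test_invariant_under_monotone_transforms(self, kind):
        rng = np.random.default_rng(99)
        scores = rng.normal(0, 1, 200)
        status = (rng.random(200) < 0.4).astype(int)
        transform = {"exp": np.exp, "cube": lambda x: x ** 3,
                     "affine": lambda x: 3 * x + 7}[kind]
        base, _ = evaluate_auc(scores, status)
        moved, _ = evaluate_auc(transform(scores), status)
        assert moved == pytest.approx(base)


class TestKmByMedian:
    def test_planted_hr_low_logrank_p(self):
        panel = synthetic.simulate_survival_panel(1000, {"x": 0.7}, seed=21)
        scores = pd.Series(panel["x"].to_numpy(),
                           index=panel["participant_id"].to_numpy())
        out = km_by_median(scores, panel)
        assert out["logrank_p"] < 0.001
        assert set(out["curves"]) == {"high", "low"}

    def test_high_curve_below_low(self):
        panel = synthetic.simulate_survival_panel(2000, {"x": 1.5}, seed=22)
        scores = pd.Series(panel["x"].to_numpy(),
                           index=panel["participant_id"].to_numpy())
        out = km_by_median(scores, panel)
        t = 2.0
        high = out["curves"]["high"].predict(t)
        low = out["curves"]["low"].predict(t)
        assert high < low

    def test_degenerate_group_errors(self):
        panel = synthetic.simulate_survival_panel(10, {"x": 0.0}, seed=23)
        scores = pd.Series(np.ones(10), index=panel["participant_id"].to_numpy())
        with pytest.raises(ValueError):
            km_by_median(scores, panel)


def test_standardize_uses_reference_moments():
    a = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
    b = pd.DataFrame({"x": [10.0, 20.0, 30.0]})
    out = standardize([a, b], ["x"])
    assert out[0]["x"].mean() == pytest.approx(0.0)
    # second panel scaled by the first panel's moments, not its own
    assert out[1]["x"].mean() == pytest.approx((20.0 - 2.0) / 1.0)
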