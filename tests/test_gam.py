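import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit
from scipy.stats import spearmanr

import sealhab as sh
from sealhab.gam import CubicRegressionSpline, fit_binomial_gam

from oracles import auc_pair_fraction


class TestSplineBasis:
    def test_interpolates_knot_values(self):
        b = CubicRegressionSpline(np.array([0.0, 1.0, 2.5, 4.0]))
        np.testing.assert_allclose(b.design(b.knots), np.eye(4), atol=1e-12)

    def test_reproduces_linear_functions_everywhere(self):
        b = CubicRegressionSpline(np.array([0.0, 1.0, 2.5, 4.0]))
        x = np.linspace(-2.0, 6.0, 81)      # includes extrapolation
        np.testing.assert_allclose(b.design(x) @ (2.0 * b.knots + 1.0),
                                   2.0 * x + 1.0, atol=1e-9)

    def test_penalty_null_space_is_linear_only(self):
        b = CubicRegressionSpline(np.array([0.0, 1.0, 2.0, 3.0]))
        assert b.knots @ b.S @ b.knots < 1e-12
        assert np.ones(4) @ b.S @ np.ones(4) < 1e-12
        wiggly = np.array([0.0, 1.0, -1.0, 0.0])
        assert wiggly @ b.S @ wiggly > 1e-3
        # shrinkage version penalizes everything
        Ss = b.penalty(shrinkage=True)
        assert b.knots @ Ss @ b.knots > 0
        assert np.all(np.linalg.eigvalsh(Ss) > 0)


class TestFit:
    def test_recovers_logistic_truth(self):
        rng = np.random.default_rng(0)
        n = 4000
        z = rng.normal(0, 1, n)
        p = expit(-1.0 + 2.0 * z)
        y = (rng.random(n) < p).astype(int)
        m = fit_binomial_gam(pd.DataFrame({"label": y, "z": z}), ["z"])
        rho = spearmanr(m.predict(pd.DataFrame({"z": z})), p).statistic
        assert rho > 0.95

    def test_shrinks_pure_noise_smooth(self):
        small = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = (rng.random(1200) < 0.25).astype(int)
            df = pd.DataFrame({"label": y, "w": rng.normal(0, 1, 1200)})
            small += fit_binomial_gam(df, ["w"]).smooths[0].edf < 0.5
        assert small >= 8

    def test_smooth_edf_bounded_by_k_minus_one(self):
        rng = np.random.default_rng(1)
        n = 2000
        z = rng.normal(0, 1, n)
        y = (rng.random(n) < expit(np.sin(2 * z))).astype(int)
        m = fit_binomial_gam(pd.DataFrame({"label": y, "z": z}), ["z"], k=4)
        assert 0.0 <= m.smooths[0].edf <= 3.0 + 1e-6

    def test_intercept_only_predicts_prevalence(self):
        rng = np.random.default_rng(2)
        y = (rng.random(800) < 0.25).astype(int)
        m = fit_binomial_gam(pd.DataFrame({"label": y}), [])
        np.testing.assert_allclose(expit(m.intercept), y.mean(), rtol=1e-9)

    def test_constant_covariate_rejected(self):
        y = np.r_[np.ones(20), np.zeros(20)].astype(int)
        df = pd.DataFrame({"label": y, "c": 1.0})
        with pytest.raises(ValueError, match="constant"):
            fit_binomial_gam(df, ["c"])

    def test_too_few_presences_rejected(self):
        df = pd.DataFrame({"label": [1] * 5 + [0] * 100,
                           "z": np.random.default_rng(3).normal(size=105)})
        with pytest.raises(ValueError, match=">= 10"):
            fit_binomial_gam(df, ["z"])

    def test_predictions_in_unit_interval(self):
        rng = np.random.default_rng(4)
        z = rng.normal(0, 1, 500)
        y = (rng.random(500) < expit(3 * z)).astype(int)
        m = fit_binomial_gam(pd.DataFrame({"label": y, "z": z}), ["z"])
        p = m.predict(pd.DataFrame({"z": np.linspace(-10, 10, 100)}))
        assert np.all((p > 0) & (p < 1))

    def test_json_round_trip_preserves_predictions(self):
        rng = np.random.default_rng(5)
        z = rng.normal(0, 1, 600)
        y = (rng.random(600) < expit(z)).astype(int)
        m = fit_binomial_gam(pd.DataFrame({"label": y, "z": z}), ["z"])
        back = sh.HabitatModel.from_json(m.to_json())
        grid = pd.DataFrame({"z": np.linspace(-3, 3, 50)})
        np.testing.assert_allclose(back.predict(grid), m.predict(grid), rtol=1e-12)


class TestRocMetrics:
    def test_perfect_separation(self):
        auc, sens, spec = sh.roc_metrics([0.9, 0.8, 0.7, 0.3, 0.2, 0.1],
                                         [1, 1, 1, 0, 0, 0])
        assert (auc, sens, spec) == (1.0, 1.0, 1.0)

    def test_all_tied_scores_give_half_auc(self):
        auc, _, _ = sh.roc_metrics([0.5] * 6, [1, 1, 1, 0, 0, 0])
        assert auc == 0.5

    def test_single_inversion_matches_pair_oracle(self):
        scores = [0.9, 0.4, 0.7, 0.5, 0.2, 0.1]
        labels = [1, 1, 1, 0, 0, 0]
        auc, _, _ = sh.roc_metrics(scores, labels)
        assert auc == auc_pair_fraction(scores, labels)

    def test_fixed_threshold_mode(self):
        scores = [0.9, 0.6, 0.4, 0.1]
        labels = [1, 1, 0, 0]
        _, sens, spec = sh.roc_metrics(scores, labels, threshold=0.5)
        assert sens == 1.0 and spec == 1.0
        _, sens, spec = sh.roc_metrics(scores, labels, threshold=0.65)
        assert sens == 0.5 and spec == 1.0

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 30)
        scores = rng.choice([0.1, 0.2, 0.5, 0.7, 0.9], size=n)
        labels = rng.integers(0, 2, n)
        if labels.sum() in (0, n):
            labels[0] = 1 - labels[0]
        a1, _, _ = sh.roc_metrics(scores, labels)
        a2, _, _ = sh.roc_metrics(np.exp(3 * scores) - 1, labels)
        assert abs(a1 - a2) < 1e-12

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both"):
            sh.roc_metrics([0.1, 0.2], [1, 1])


def month_blocked_table(seed=0, n_per_month=260, signal=True):
    """Synthetic table whose rows are iid across months (month-invariant)."""
    rng = np.random.default_rng(seed)
    frames = []
    for m in range(5, 10):
        z = rng.normal(0, 1, n_per_month)
        w = rng.normal(0, 1, n_per_month)
        eta = -1.1 + (1.8 * z if signal else 0.0)
        y = (rng.random(n_per_month) < expit(eta)).astype(int)
        frames.append(pd.DataFrame({"label": y, "month": m, "z": z, "w": w}))
    return pd.concat(frames, ignore_index=True)


class TestMonthlyCv:
    def test_fold_count_equals_month_count(self):
        cv = sh.cv_monthly(month_blocked_table(), ["z"])
        assert len(cv.folds) == 5
        assert 0.5 <= cv.auc <= 1.0

    def test_month_invariant_data_gives_homogeneous_folds(self):
        cv = sh.cv_monthly(month_blocked_table(seed=1), ["z"])
        aucs = cv.folds["auc"].to_numpy()
        assert aucs.max() - aucs.min() < 0.05

    def test_single_month_rejected(self):
        tab = month_blocked_table()
        with pytest.raises(ValueError, match="2 distinct months"):
            sh.cv_monthly(tab[tab["month"] == 5], ["z"])


class TestForwardStepwise:
    def test_single_improving_candidate_selected(self):
        trace = sh.forward_stepwise(month_blocked_table(seed=2), ["z"])
        assert trace.selected == ["z"]
        assert len(trace.steps) == 1

    def test_noise_covariate_not_added(self):
        trace = sh.forward_stepwise(month_blocked_table(seed=3), ["z", "w"])
        assert trace.selected[0] == "z"
        assert "w" not in trace.selected

    def test_duplicate_covariate_cannot_improve(self):
        tab = month_blocked_table(seed=4)
        tab["z2"] = tab["z"]
        trace = sh.forward_stepwise(tab, ["z", "z2"])
        assert len(trace.selected) == 1

    def test_auc_path_strictly_increasing(self):
        tab = month_blocked_table(seed=5)
        tab["z2"] = 0.5 * tab["z"] + np.random.default_rng(6).normal(
            0, 0.8, len(tab))
        trace = sh.forward_stepwise(tab, ["z", "z2", "w"])
        aucs = trace.steps["auc"].to_numpy()
        assert np.all(np.diff(aucs) > 0)

    def test_selection_independent_of_candidate_order(self):
        tab = month_blocked_table(seed=7)
        a = sh.forward_stepwise(tab, ["z", "w"])
        b = sh.forward_stepwise(tab, ["w", "z"])
        assert a.selected == b.selected
        pd.testing.assert_frame_equal(a.ranking, b.ranking)

    def test_ranking_table_has_metric_columns(self):
        trace = sh.forward_stepwise(month_blocked_table(seed=8), ["z", "w"])
        assert list(trace.ranking.columns) == ["covariate", "auc",
                                               "sensitivity", "specificity"]
        assert len(trace.ranking) == 2


def test_pooled_refit_training_auc_near_cv_auc(pipeline_products):
    """The pooled full-data refit used for prediction should not score far
    below the aggregate cross-validated AUC of the same covariate set."""
    table = pipeline_products["table"]
    cv = sh.cv_monthly(table, ["CDIST", "DEPTH"])
    model = fit_binomial_gam(table, ["CDIST", "DEPTH"])
    auc, _, _ = sh.roc_metrics(model.predict(table.data),
                               table.data["label"].to_numpy(int))
    assert auc >= cv.auc - 0.1


class TestResponseCurve:
    def test_intercept_only_model_flat_zero(self):
        rng = np.random.default_rng(9)
        y = (rng.random(400) < 0.3).astype(int)
        m = fit_binomial_gam(pd.DataFrame({"label": y}), [])
        curve = sh.response_curve(m, "z", grid=np.linspace(0, 1, 10))
        assert (curve["effect"] == 0).all()

    def test_monotone_truth_gives_monotone_curve(self):
        rng = np.random.default_rng(10)
        n = 3000
        z = rng.uniform(-2, 2, n)
        y = (rng.random(n) < expit(1.5 * z)).astype(int)
        m = fit_binomial_gam(pd.DataFrame({"label": y, "z": z}), ["z"])
        curve = sh.response_curve(m, "z")
        inner = curve[(curve["z"] > np.quantile(z, 0.1))
                      & (curve["z"] < np.quantile(z, 0.9))]
        assert np.all(np.diff(inner["effect"]) > -1e-9)

    def test_partial_effect_centred_over_training_data(self):
        rng = np.random.default_rng(11)
        n = 2000
        z = rng.normal(0, 1, n)
        y = (rng.random(n) < expit(z)).astype(int)
        m = fit_binomial_gam(pd.DataFrame({"label": y, "z": z}), ["z"])
        effects = m.smooths[0].partial(z)
        assert abs(effects.mean()) < 1e-8

    def test_bounds_bracket_effect(self):
        rng = np.random.default_rng(12)
        z = rng.normal(0, 1, 900)
        y = (rng.random(900) < expit(z)).astype(int)
        m = fit_binomial_gam(pd.DataFrame({"label": y, "z": z}), ["z"])
        curve = sh.response_curve(m, "z")
        assert (curve["lower"] <= curve["effect"]).all()
        assert (curve["upper"] >= curve["effect"]).all()
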