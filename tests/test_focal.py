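"""Focal loss, decision threshold, feature reweighting and grid search."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from strokerisk.focal import (
    BoostingGrid,
    DecisionRule,
    FeatureWeightState,
    FocalParams,
    apply_weights,
    decide,
    fit_boosting,
    focal_grad_hess,
    focal_loss,
    select_best,
    shap_contributions,
    update_feature_weights,
)


class TestFocalLoss:
    def test_reduces_to_log_loss(self):
        assert focal_loss(0.5, 1, FocalParams(gamma=0, alpha=0.5)) == pytest.approx(0.5 * np.log(2))

    def test_perfect_confidence_limit(self):
        assert focal_loss(1 - 1e-13, 1, FocalParams()) == pytest.approx(0.0, abs=1e-10)

    def test_direct_evaluation(self):
        # 0.25 * (1-0.9)^2 * (-ln 0.9)
        expected = 0.25 * 0.01 * -np.log(0.9)
        assert focal_loss(0.9, 1, FocalParams(gamma=2, alpha=0.25)) == pytest.approx(expected, rel=1e-12)

    def test_gamma0_equals_half_cross_entropy_pointwise(self):
        p = np.linspace(0.01, 0.99, 50)
        for y in (0, 1):
            fl = focal_loss(p, np.full_like(p, y), FocalParams(gamma=0, alpha=0.5))
            ce = -(y * np.log(p) + (1 - y) * np.log(1 - p))
            np.testing.assert_allclose(fl, 0.5 * ce, rtol=1e-12)

    def test_decreasing_in_pt(self):
        p = np.linspace(0.05, 0.95, 30)
        fl = focal_loss(p, np.ones_like(p), FocalParams())
        assert (np.diff(fl) < 0).all()

    def test_bad_label_raises(self):
        with pytest.raises(ValueError):
            focal_loss(0.5, 2)


class TestFocalGradHess:
    def test_cross_entropy_gradient_at_zero(self):
        g, _ = focal_grad_hess(0.0, 1, FocalParams(gamma=0, alpha=0.5))
        assert 2 * g == pytest.approx(-0.5)  # alpha=0.5 scales CE by 1/2

    @pytest.mark.parametrize("gamma,alpha", [(0.0, 0.5), (2.0, 0.25), (1.0, 0.4)])
    def test_gradient_matches_central_difference(self, gamma, alpha):
        params = FocalParams(gamma=gamma, alpha=alpha)
        eps = 1e-5
        for y in (0, 1):
            for s in np.linspace(-6, 6, 25):
                g, _ = focal_grad_hess(s, y, params)
                def loss(sv):
                    return focal_loss(1 / (1 + np.exp(-sv)), y, params)
                numeric = (loss(s + eps) - loss(s - eps)) / (2 * eps)
                assert g == pytest.approx(numeric, abs=1e-6)

    @pytest.mark.parametrize("gamma", [0.0, 2.0])
    def test_hessian_nonnegative_on_grid(self, gamma):
        s = np.linspace(-8, 8, 200)
        for y in (0, 1):
            _, h = focal_grad_hess(s, np.full_like(s, y), FocalParams(gamma=gamma, alpha=0.25))
            assert (h >= 0).all()

    def test_hessian_matches_second_difference_up_to_floor(self):
        """The analytic hessian equals the numeric second derivative where
        the loss is locally convex; in the (genuinely non-convex) focal
        regions the implementation returns the stability floor."""
        params = FocalParams(gamma=2, alpha=0.25)
        eps = 1e-4
        for y in (0, 1):
            for s in np.linspace(-4, 4, 9):
                _, h = focal_grad_hess(s, y, params)
                def loss(sv):
                    return focal_loss(1 / (1 + np.exp(-sv)), y, params)
                numeric = (loss(s + eps) - 2 * loss(s) + loss(s - eps)) / eps**2
                assert h == pytest.approx(max(numeric, 1e-12), abs=1e-5)

    def test_nonfinite_score_rejected(self):
        with pytest.raises(ValueError):
            focal_grad_hess(np.inf, 1)


class TestDecide:
    def test_boundary_inclusive(self):
        assert decide(0.327) == 1
        assert decide(0.326) == 0
        assert decide(0.0) == 0

    def test_brute_force_agreement_near_boundary(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=1_000_00)
        tau = 0.327
        p = np.concatenate([p, [tau, tau - 1e-9, tau + 1e-9]])
        out = decide(p, DecisionRule(tau=tau))
        brute = np.array([1 if v >= tau else 0 for v in p])
        np.testing.assert_array_equal(out, brute)

    @given(st.floats(min_value=0.0, max_value=1.0), st.floats(min_value=0.01, max_value=0.99))
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_matches_comparison_semantics(self, p, tau):
        assert decide(p, DecisionRule(tau=tau)) == int(p >= tau)


class TestFeatureWeights:
    def test_mean_one_normalisation_full_update(self):
        state = FeatureWeightState(("a", "b", "c"), damping=1.0)
        out = update_feature_weights(state, [2.0, 1.0, 1.0])
        np.testing.assert_allclose(out.weights, [1.5, 0.75, 0.75])

    def test_zero_damping_leaves_weights(self):
        state = FeatureWeightState(("a", "b"), weights=np.array([1.2, 0.8]), damping=1e-12)
        out = update_feature_weights(state, [5.0, 1.0])
        np.testing.assert_allclose(out.weights, [1.2, 0.8], atol=1e-9)

    def test_geometric_convergence_rate(self):
        """Constant contributions: w_t - w_hat shrinks by (1-eta) per step."""
        eta = 0.3
        state = FeatureWeightState(("a", "b", "c"), damping=eta)
        target = np.array([2.0, 0.5, 0.5]) / np.mean([2.0, 0.5, 0.5])
        errors = []
        for _ in range(6):
            state = update_feature_weights(state, [2.0, 0.5, 0.5])
            errors.append(np.abs(state.weights - target).max())
        ratios = np.array(errors[1:]) / np.array(errors[:-1])
        np.testing.assert_allclose(ratios, 1 - eta, rtol=1e-9)

    def test_mean_conserved_after_every_update(self, rng):
        state = FeatureWeightState(tuple("abcdef"), damping=0.4)
        for _ in range(10):
            state = update_feature_weights(state, rng.uniform(0.1, 3.0, size=6))
            assert state.weights.mean() == pytest.approx(1.0)

    def test_all_zero_contributions_warn_and_keep_weights(self):
        state = FeatureWeightState(("a", "b"))
        with pytest.warns(UserWarning):
            out = update_feature_weights(state, [0.0, 0.0])
        np.testing.assert_allclose(out.weights, state.weights)

    def test_apply_weights_invertible(self, rng):
        state = FeatureWeightState(("a", "b", "c"), weights=np.array([0.5, 1.5, 1.0]))
        x = rng.normal(size=(20, 3))
        np.testing.assert_allclose(apply_weights(x, state) / state.weights[None, :], x, atol=1e-12)

    def test_uniform_weights_identity(self, rng):
        state = FeatureWeightState(("a", "b"))
        x = rng.normal(size=(10, 2))
        np.testing.assert_array_equal(apply_weights(x, state), x)


@pytest.fixture(scope="module")
def separable():
    rng = np.random.default_rng(1)
    x = rng.normal(size=(300, 2))
    y = (x[:, 0] + x[:, 1] > 0).astype(int)
    return x, y


class TestBoosting:
    def test_separable_data_perfect_at_half(self, separable):
        x, y = separable
        model = fit_boosting(x, y, num_boost_round=80, seed=0)
        pred = decide(model.predict_proba(x), DecisionRule(tau=0.5))
        assert (pred == y).mean() == 1.0

    def test_gamma0_matches_cross_entropy_ranking(self, separable):
        x, y = separable
        focal = fit_boosting(x, y, focal=FocalParams(gamma=0, alpha=0.5), seed=0)
        import lightgbm as lgb

        plain = lgb.train(
            {"objective": "binary", "verbosity": -1, "num_threads": 1,
             "deterministic": True, "seed": 0, "max_depth": 6},
            lgb.Dataset(x, label=y), num_boost_round=100,
        )
        rho = sps.spearmanr(focal.predict_proba(x), plain.predict(x)).statistic
        assert rho > 0.97

    def test_lower_tau_never_lowers_recall(self):
        rng = np.random.default_rng(3)
        n = 1100
        x = rng.normal(size=(n, 4))
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-(1.5 * x[:, 0] - 2.2)))).astype(int)
        model = fit_boosting(x[:800], y[:800], seed=0, num_boost_round=50)
        p = model.predict_proba(x[800:])
        yt = y[800:]
        recalls = []
        for tau in (0.2, 0.3, 0.327, 0.4, 0.5):
            pred = decide(p, DecisionRule(tau=tau))
            tp = ((pred == 1) & (yt == 1)).sum()
            fn = ((pred == 0) & (yt == 1)).sum()
            recalls.append(tp / (tp + fn))
        assert all(a >= b for a, b in zip(recalls, recalls[1:]))

    def test_single_class_training_rejected(self):
        x = np.zeros((10, 2))
        with pytest.raises(ValueError):
            fit_boosting(x, np.zeros(10))


class TestShapContributions:
    def test_planted_signal_recovered(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(500, 5))
        y = (x[:, 1] > 0).astype(int)
        model = fit_boosting(x, y, seed=0, num_boost_round=40)
        contrib = shap_contributions(model, x)
        assert contrib.argmax() == 1

    def test_noise_target_contributions_comparable(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(400, 4))
        y = rng.integers(0, 2, size=400)
        model = fit_boosting(x, y, seed=0, num_boost_round=30)
        contrib = shap_contributions(model, x)
        assert contrib.max() < 10 * (contrib.min() + 1e-6) or contrib.max() < 0.5

    def test_local_accuracy_identity(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(100, 3))
        y = (x[:, 0] > 0).astype(int)
        model = fit_boosting(x, y, seed=0, num_boost_round=25)
        per_row = np.asarray(model.booster.predict(x, pred_contrib=True))
        np.testing.assert_allclose(per_row.sum(axis=1), model.predict_raw(x), atol=1e-6)

    def test_feature_mismatch_raises(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(50, 3))
        y = (x[:, 0] > 0).astype(int)
        model = fit_boosting(x, y, seed=0, num_boost_round=5)
        with pytest.raises(ValueError):
            shap_contributions(model, x[:, :2])


class TestGridSearch:
    def test_default_active_grid_has_48_configurations(self):
        assert len(BoostingGrid().configurations()) == 48

    def test_single_configuration_grid(self):
        grid = BoostingGrid(num_leaves=(32,), learning_rate=(0.1,),
                            feature_fraction=(1.0,), lambda_l1=(0.0,), lambda_l2=(0.0,))
        assert len(grid.configurations()) == 1

    def test_selection_matches_brute_force_filter_then_argmax(self, rng):
        rows = []
        for i in range(48):
            rows.append({
                "num_leaves": int(rng.choice([32, 64, 128])),
                "learning_rate": float(rng.choice([0.05, 0.1])),
                "mean_auc": float(rng.uniform(0.6, 0.99)),
                "fit_time": float(rng.uniform(0.1, 5.0)),
            })
        lb = pd.DataFrame(rows)
        picked = select_best(lb)

        # independent re-implementation of the rule
        q25 = np.quantile(lb["fit_time"], 0.25)
        fast = lb[lb["fit_time"] <= q25]
        best_auc = fast["mean_auc"].max()
        cands = fast[fast["mean_auc"] == best_auc]
        cands = cands.sort_values(["num_leaves", "learning_rate"])
        expected = cands.iloc[0]
        assert picked["mean_auc"] == expected["mean_auc"]
        assert picked["num_leaves"] == expected["num_leaves"]

    def test_empty_leaderboard_rejected(self):
        with pytest.raises(ValueError):
            select_best(pd.DataFrame(columns=["fit_time", "mean_auc"]))
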