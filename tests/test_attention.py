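"""Attention classifier: architecture contract, blocks, Lion, training."""

import numpy as np
import pytest

from strokerisk import autodiff as ad
from strokerisk.attention import (
    ArchitectureConfig,
    AttentionClassifier,
    StoppingThresholds,
    cross_entropy,
    count_layers,
    lion_step,
    train_model,
)
from strokerisk.autodiff import Tensor
from strokerisk.focal import DecisionRule


@pytest.fixture()
def small_model():
    cfg = ArchitectureConfig(embed_dim=8, n_heads=2, n_self_blocks=2,
                             dropout=0.0, droppath=0.0, head_hidden=(8, 6))
    return AttentionClassifier(n_numeric=3, cat_cardinalities=[3, 4], config=cfg, seed=0)


class TestArchitecture:
    def test_default_layer_count_is_19(self):
        assert count_layers(ArchitectureConfig()) == 19

    def test_self_stack_contributes_three_per_block(self):
        assert count_layers(ArchitectureConfig(n_self_blocks=1)) == 10
        assert count_layers(ArchitectureConfig(n_self_blocks=0, cross_attention=False)) == 4

    def test_scales_linearly_in_blocks(self):
        counts = [count_layers(ArchitectureConfig(n_self_blocks=k)) for k in range(1, 5)]
        assert np.diff(counts).tolist() == [3, 3, 3]

    def test_ffn_width_ratio_is_four(self):
        model = AttentionClassifier(2, [3], ArchitectureConfig(embed_dim=16, n_heads=4), seed=0)
        w1 = model.params["self0.ffn.W1"].data
        assert w1.shape == (16, 64)

    def test_embed_dim_must_divide_heads(self):
        with pytest.raises(ValueError):
            ArchitectureConfig(embed_dim=30, n_heads=4)


class TestEmbedding:
    def test_token_tensor_shape(self, small_model, rng):
        x_num = rng.normal(size=(5, 3))
        x_cat = rng.integers(0, 3, size=(5, 2))
        num, tokens = small_model.embed_features(x_num, x_cat)
        assert num.shape == (5, 8)
        assert tokens.shape == (5, 2, 8)

    def test_identical_rows_identical_embeddings(self, small_model):
        x_num = np.ones((2, 3))
        x_cat = np.array([[1, 2], [1, 2]])
        num, tokens = small_model.embed_features(x_num, x_cat)
        np.testing.assert_array_equal(num.data[0], num.data[1])
        np.testing.assert_array_equal(tokens.data[0], tokens.data[1])

    def test_unknown_code_maps_to_extra_row(self, small_model):
        x_cat = np.array([[99, 0]])  # out of range -> Unknown row
        _, tokens = small_model.embed_features(np.zeros((1, 3)), x_cat)
        unknown_row = small_model.params["embed.cat0"].data[3]
        np.testing.assert_array_equal(tokens.data[0, 0], unknown_row)

    def test_zero_categorical_columns_numeric_only(self):
        cfg = ArchitectureConfig(embed_dim=8, n_heads=2, n_self_blocks=1)
        model = AttentionClassifier(4, [], cfg, seed=0)
        probs = model.forward(np.random.default_rng(0).normal(size=(3, 4)), None)
        assert probs.shape == (3, 2)
        np.testing.assert_allclose(probs.data.sum(axis=1), 1.0, atol=1e-6)


class TestSelfAttentionBlock:
    def test_output_shape_preserved(self, small_model, rng):
        tokens = Tensor(rng.normal(size=(4, 6, 8)))
        out = small_model.self_attention_block(0, tokens)
        assert out.shape == (4, 6, 8)

    def test_attention_rows_sum_to_one(self, small_model, rng):
        tokens = Tensor(rng.normal(size=(3, 5, 8)))
        small_model.self_attention_block(0, tokens)
        attn = small_model.last_attention["self0"]
        np.testing.assert_allclose(attn.sum(axis=-1), 1.0, atol=1e-6)

    def test_zeroed_residual_branches_make_identity(self, small_model, rng):
        for name in ("self0.attn.Wo", "self0.attn.bo", "self0.ffn.W2", "self0.ffn.b2"):
            small_model.params[name].data[:] = 0.0
        tokens = Tensor(rng.normal(size=(2, 4, 8)))
        out = small_model.self_attention_block(0, tokens, training=False)
        np.testing.assert_allclose(out.data, tokens.data, atol=1e-12)


class TestCrossAttentionBlock:
    def test_output_matches_query_shape(self, small_model, rng):
        cfg = ArchitectureConfig(embed_dim=8, n_heads=2, n_self_blocks=1,
                                 dropout=0.0, droppath=0.0)
        model = AttentionClassifier(3, [4], cfg, seed=1)
        q = Tensor(rng.normal(size=(5, 8)))
        ctx = Tensor(rng.normal(size=(5, 4, 8)))
        out = model.cross_attention_block(q, ctx)
        assert out.shape == (5, 8)

    def test_singleton_context_attention_weight_is_one(self, rng):
        cfg = ArchitectureConfig(embed_dim=8, n_heads=2, dropout=0.0, droppath=0.0)
        model = AttentionClassifier(3, [4], cfg, seed=1)
        q = Tensor(rng.normal(size=(2, 8)))
        ctx = Tensor(rng.normal(size=(2, 1, 8)))
        model.cross_attention_block(q, ctx)
        np.testing.assert_allclose(model.last_attention["cross"], 1.0, atol=1e-12)

    def test_permutation_invariance_of_context(self, rng):
        """No positional encoding: permuting context tokens leaves the
        fused stream unchanged."""
        cfg = ArchitectureConfig(embed_dim=8, n_heads=2, dropout=0.0, droppath=0.0)
        model = AttentionClassifier(3, [5], cfg, seed=2)
        q = Tensor(rng.normal(size=(3, 8)))
        ctx_data = rng.normal(size=(3, 5, 8))
        out1 = model.cross_attention_block(q, Tensor(ctx_data))
        perm = rng.permutation(5)
        out2 = model.cross_attention_block(q, Tensor(ctx_data[:, perm, :]))
        np.testing.assert_allclose(out1.data, out2.data, atol=1e-10)

    def test_empty_context_pass_through_with_warning(self, small_model, rng):
        q = Tensor(rng.normal(size=(2, 8)))
        with pytest.warns(UserWarning, match="pass-through"):
            out = small_model.cross_attention_block(q, None)
        np.testing.assert_array_equal(out.data, q.data)


class TestHead:
    def test_probabilities_normalise(self, small_model, rng):
        probs = small_model.forward(rng.normal(size=(6, 3)), rng.integers(0, 3, size=(6, 2)))
        assert probs.shape == (6, 2)
        np.testing.assert_allclose(probs.data.sum(axis=1), 1.0, atol=1e-6)

    def test_logit_shift_invariance(self, small_model):
        """Shifting final-layer bias by a constant leaves softmax output
        unchanged."""
        x_num = np.ones((2, 3))
        x_cat = np.zeros((2, 2), dtype=int)
        before = small_model.forward(x_num, x_cat).data.copy()
        small_model.params["head.b3"].data += 7.5  # same shift on both logits
        after = small_model.forward(x_num, x_cat).data
        np.testing.assert_allclose(before, after, atol=1e-9)

    def test_eval_forward_deterministic(self, small_model, rng):
        x_num = rng.normal(size=(4, 3))
        x_cat = rng.integers(0, 3, size=(4, 2))
        a = small_model.predict_proba(x_num, x_cat)
        b = small_model.predict_proba(x_num, x_cat)
        np.testing.assert_array_equal(a, b)


class TestLion:
    def test_sign_rule_from_rest(self):
        w, m = lion_step(np.array([1.0]), np.array([0.3]), np.array([0.0]),
                         lr=0.1, weight_decay=0.0)
        assert w[0] == pytest.approx(0.9)

    def test_zero_gradient_zero_momentum_no_move(self):
        w, m = lion_step(np.array([2.0]), np.array([0.0]), np.array([0.0]),
                         lr=0.1, weight_decay=0.0)
        assert w[0] == pytest.approx(2.0)

    def test_three_step_trace_on_quadratic_matches_hand_reference(self):
        """f(w) = w^2, lr 0.1, b1 0.9, b2 0.99, no decay, from w=1:
        hand-derived trace 0.9, 0.8, 0.7 with momenta 0.02, 0.0378, 0.053422."""
        w, m = np.array([1.0]), np.array([0.0])
        expected = [(0.9, 0.02), (0.8, 0.0378), (0.7, 0.053422)]
        for w_exp, m_exp in expected:
            g = 2 * w
            w, m = lion_step(w, g, m, lr=0.1, weight_decay=0.0)
            assert w[0] == pytest.approx(w_exp, abs=1e-12)
            assert m[0] == pytest.approx(m_exp, abs=1e-12)

    def test_weight_decay_term(self):
        w, _ = lion_step(np.array([1.0]), np.array([1.0]), np.array([0.0]),
                         lr=0.1, weight_decay=0.1)
        assert w[0] == pytest.approx(1.0 - 0.1 * (1 + 0.1))

    def test_nonfinite_gradient_rejected(self):
        with pytest.raises(FloatingPointError):
            lion_step(np.array([1.0]), np.array([np.nan]), np.array([0.0]))


@pytest.fixture(scope="module")
def separable():
    rng = np.random.default_rng(0)
    n = 400
    x_num = rng.normal(size=(n, 3))
    y = (x_num[:, 0] + x_num[:, 1] > 0).astype(int)
    x_cat = rng.integers(0, 3, size=(n, 1))
    return x_num, x_cat, y


class TestTraining:
    def _model(self, seed=0):
        cfg = ArchitectureConfig(embed_dim=8, n_heads=2, n_self_blocks=1, head_hidden=(16, 8))
        return AttentionClassifier(3, [3], cfg, seed=seed)

    def test_zero_thresholds_stop_after_first_epoch(self, separable):
        x_num, x_cat, y = separable
        th = StoppingThresholds(accuracy=0, precision=0, recall=0,
                                specificity=0, f1=0, auc=0, max_epochs=10)
        res = train_model(self._model(), x_num[:300], x_cat[:300], y[:300],
                          x_num[300:], x_cat[300:], y[300:], thresholds=th, seed=0)
        assert len(res.history) == 1 and res.stopped_early

    def test_unattainable_thresholds_run_to_budget(self, rng):
        x_num = rng.normal(size=(200, 3))
        y = rng.integers(0, 2, size=200)  # pure noise target
        x_cat = rng.integers(0, 3, size=(200, 1))
        th = StoppingThresholds(accuracy=1.0, precision=1.0, recall=1.0,
                                specificity=1.0, f1=1.0, auc=1.0, max_epochs=3)
        res = train_model(self._model(), x_num[:150], x_cat[:150], y[:150],
                          x_num[150:], x_cat[150:], y[150:], thresholds=th, seed=0)
        assert len(res.history) == 3 and not res.stopped_early

    def test_separable_data_reaches_thresholds_within_budget(self, separable):
        x_num, x_cat, y = separable
        th = StoppingThresholds(max_epochs=30)
        res = train_model(self._model(), x_num[:300], x_cat[:300], y[:300],
                          x_num[300:], x_cat[300:], y[300:],
                          thresholds=th, rule=DecisionRule(tau=0.5), lr=3e-3, seed=0)
        assert res.stopped_early

    def test_single_class_training_rejected(self, rng):
        x_num = rng.normal(size=(20, 3))
        x_cat = rng.integers(0, 3, size=(20, 1))
        with pytest.raises(ValueError):
            train_model(self._model(), x_num, x_cat, np.zeros(20, dtype=int),
                        x_num, x_cat, np.zeros(20, dtype=int))

    def test_beats_logistic_baseline_on_interaction_data(self):
        """Seeded regression: on data whose signal is a token-equality
        interaction, the attention model's validation AUC exceeds a
        logistic model on the same (one-hot) features."""
        from sklearn.linear_model import LogisticRegression
        from sklearn.preprocessing import OneHotEncoder

        from strokerisk.metrics import roc_auc

        rng = np.random.default_rng(0)
        n = 1500
        x_num = rng.normal(size=(n, 2))
        cats = rng.integers(0, 4, size=(n, 3))
        y = (cats[:, 0] == cats[:, 1]).astype(int)
        flip = rng.uniform(size=n) < 0.05
        y = np.where(flip, 1 - y, y)
        tr, va = slice(0, 1100), slice(1100, n)
        cfg = ArchitectureConfig(embed_dim=16, n_heads=4, n_self_blocks=2, head_hidden=(32, 16))
        model = AttentionClassifier(2, [4, 4, 4], cfg, seed=0)
        train_model(model, x_num[tr], cats[tr], y[tr], x_num[va], cats[va], y[va],
                    thresholds=StoppingThresholds(max_epochs=20), lr=1e-3, seed=0)
        attn_auc = roc_auc(y[va], model.predict_proba(x_num[va], cats[va])[:, 1])

        enc = OneHotEncoder(sparse_output=False).fit(cats[tr])
        xb = np.hstack([x_num[tr], enc.transform(cats[tr])])
        xv = np.hstack([x_num[va], enc.transform(cats[va])])
        logit = LogisticRegression(max_iter=2000).fit(xb, y[tr])
        base_auc = roc_auc(y[va], logit.predict_proba(xv)[:, 1])
        assert attn_auc > base_auc

    def test_checkpoint_restores_best_validation_auc(self, separable):
        from strokerisk.metrics import roc_auc

        x_num, x_cat, y = separable
        model = self._model()
        th = StoppingThresholds(accuracy=1.0, precision=1.0, recall=1.0,
                                specificity=1.0, f1=1.0, auc=1.0, max_epochs=5)
        res = train_model(model, x_num[:300], x_cat[:300], y[:300],
                          x_num[300:], x_cat[300:], y[300:], thresholds=th, lr=3e-3, seed=0)
        best_logged = max(h["auc"] for h in res.history)
        final = roc_auc(y[300:], model.predict_proba(x_num[300:], x_cat[300:])[:, 1])
        assert final == pytest.approx(best_logged, abs=1e-12)


def test_cross_entropy_matches_manual_value():
    probs = Tensor(np.array([[0.9, 0.1], [0.2, 0.8]]))
    loss = cross_entropy(probs, np.array([0, 1]))
    expected = -(np.log(0.9 + 1e-12) + np.log(0.8 + 1e-12)) / 2
    assert loss.data == pytest.approx(expected)


def test_save_load_round_trip(tmp_path, rng):
    cfg = ArchitectureConfig(embed_dim=8, n_heads=2, n_self_blocks=1)
    model = AttentionClassifier(3, [3, 4], cfg, seed=0)
    x_num = rng.normal(size=(4, 3))
    x_cat = rng.integers(0, 3, size=(4, 2))
    before = model.predict_proba(x_num, x_cat)
    path = tmp_path / "model.npz"
    model.save(path)
    loaded = AttentionClassifier.load(path)
    np.testing.assert_allclose(loaded.predict_proba(x_num, x_cat), before, atol=1e-12)
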