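"""RBM activations, contrastive divergence, stacking, fine-tuning, archives."""

import numpy as np
import pytest
from scipy.special import expit

from prostage.data import Label
from prostage.dbn import (
    DBNClassifier,
    RBMParams,
    TrainingConfig,
    cd_update,
    finetune,
    hidden_activation,
    init_rbm,
    load_classifier,
    predict_proba,
    pretrain,
    save_classifier,
    train_dbn,
    visible_activation,
)


def _zero_rbm(nv=3, nh=4):
    return RBMParams(np.zeros((nv, nh)), np.zeros(nv), np.zeros(nh))


class TestActivations:
    def test_zero_parameters_give_half(self):
        rbm = _zero_rbm()
        assert np.allclose(hidden_activation(rbm, np.ones(3)), 0.5)
        assert np.allclose(visible_activation(rbm, np.ones(4)), 0.5)

    def test_large_bias_saturates(self):
        rbm = RBMParams(np.zeros((2, 2)), np.zeros(2), np.array([50.0, -50.0]))
        h = hidden_activation(rbm, np.array([1.0, 0.0]))
        assert h[0] > 0.999999 and h[1] < 1e-6

    def test_hand_computed_two_by_two(self):
        w = np.array([[1.0, -1.0], [0.5, 2.0]])
        rbm = RBMParams(w, np.array([0.2, -0.3]), np.array([0.1, 0.4]))
        v = np.array([1.0, 0.0])
        expected = expit(np.array([1.0 + 0.1, -1.0 + 0.4]))
        assert np.allclose(hidden_activation(rbm, v), expected)
        h = np.array([0.0, 1.0])
        expected_v = expit(np.array([-1.0 + 0.2, 2.0 - 0.3]))
        assert np.allclose(visible_activation(rbm, h), expected_v)

    def test_symmetric_weights_interchange_roles(self):
        w = np.array([[0.3, -0.7], [-0.7, 1.1]])  # symmetric square
        rbm = RBMParams(w, np.zeros(2), np.zeros(2))
        v = np.array([1.0, 0.5])
        assert np.allclose(hidden_activation(rbm, v), visible_activation(rbm, v))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            hidden_activation(_zero_rbm(), np.ones(5))


class TestCdUpdate:
    def test_zero_learning_rate_is_identity(self, rng):
        rbm = init_rbm(4, 4, rng)
        batch = rng.integers(0, 2, size=(8, 4)).astype(float)
        out = cd_update(rbm, batch, lr=0.0, rng=np.random.default_rng(0))
        assert np.array_equal(out.weights, rbm.weights)
        assert np.array_equal(out.hidden_bias, rbm.hidden_bias)

    def test_deterministic_under_fixed_rng(self, rng):
        rbm = init_rbm(4, 4, rng)
        batch = rng.integers(0, 2, size=(8, 4)).astype(float)
        a = cd_update(rbm, batch, 0.1, rng=np.random.default_rng(7))
        b = cd_update(rbm, batch, 0.1, rng=np.random.default_rng(7))
        assert np.array_equal(a.weights, b.weights)

    def test_empty_batch_rejected(self, rng):
        with pytest.raises(ValueError):
            cd_update(init_rbm(4, 4, rng), np.empty((0, 4)), 0.1)

    def test_reconstruction_error_decreases_on_repeated_pattern(self):
        pattern = np.tile(np.array([1.0, 0.0, 1.0, 1.0, 0.0, 0.0]), (16, 1))
        rng = np.random.default_rng(5)
        rbm = init_rbm(6, 6, rng)

        def recon_err(r):
            v = visible_activation(r, hidden_activation(r, pattern))
            return float(((v - pattern) ** 2).mean())

        initial = recon_err(rbm)
        errs = []
        for _ in range(60):
            rbm = cd_update(rbm, pattern, lr=0.5, rng=rng)
            errs.append(recon_err(rbm))
        assert errs[-1] < initial
        assert errs[-1] < errs[0]

    def test_parameters_stay_finite_on_extreme_patterns(self):
        rng = np.random.default_rng(2)
        rbm = init_rbm(9, 9, rng)
        extremes = np.vstack([np.zeros(9), np.ones(9), np.eye(9)])
        for _ in range(200):
            rbm = cd_update(rbm, extremes, lr=0.1, rng=rng)
        assert np.isfinite(rbm.weights).all()


class TestPretrain:
    def test_zero_epochs_returns_initialised_stack(self, rng):
        data = rng.integers(0, 2, size=(10, 9)).astype(float)
        cfg = TrainingConfig(pretrain_epochs=0, seed=1)
        stack = pretrain(data, None, cfg)
        assert len(stack) == 3
        assert all(np.abs(r.weights).max() < 0.1 for r in stack)  # untrained init
        assert all(np.array_equal(r.visible_bias, np.zeros(9)) for r in stack)

    def test_equal_width_layers_by_default(self, rng):
        data = rng.integers(0, 2, size=(20, 9)).astype(float)
        stack = pretrain(data, None, TrainingConfig(pretrain_epochs=2, seed=0))
        assert [(r.visible_dim, r.hidden_dim) for r in stack] == [(9, 9)] * 3

    def test_deterministic_under_seed(self, rng):
        data = rng.integers(0, 2, size=(20, 8)).astype(float)
        cfg = TrainingConfig(pretrain_epochs=3, seed=4)
        a, b = pretrain(data, None, cfg), pretrain(data, None, cfg)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.weights, rb.weights)

    def test_total_epoch_allocation_splits_budget(self, rng):
        data = rng.integers(0, 2, size=(10, 4)).astype(float)
        cfg = TrainingConfig(pretrain_epochs=4, seed=0, epoch_allocation="total")
        stack = pretrain(data, None, cfg)  # 2+1+1 epochs; just must not error
        assert len(stack) == 3


class TestFinetune:
    def _toy(self, n=300, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.integers(0, 2, size=(n, 9)).astype(float)
        labels = [Label.NOCD if x[0] == 1 else Label.OCD for x in X]
        return X, labels

    def test_separable_toy_reaches_high_training_accuracy(self):
        """Label = first input bit: the fine-tuned network must fit it."""
        X, labels = self._toy()
        model = train_dbn(X, labels, TrainingConfig(seed=0))
        probs = predict_proba(model, X)
        pred = [Label.NOCD if p[1] > p[0] else Label.OCD for p in probs]
        acc = np.mean([a == b for a, b in zip(pred, labels)])
        assert acc >= 0.95

    def test_zero_epochs_leaves_stack_unchanged(self, rng):
        X, labels = self._toy(40)
        stack = pretrain(X, None, TrainingConfig(pretrain_epochs=1, seed=2))
        model = finetune(stack, X, labels, TrainingConfig(pretrain_epochs=1, finetune_epochs=0, seed=2))
        for before, after in zip(stack, model.rbm_layers):
            assert np.array_equal(before.weights, after.weights)
        assert np.abs(model.head_weights).max() < 0.1  # still at init

    def test_deterministic_under_seed(self):
        X, labels = self._toy(60)
        cfg = TrainingConfig(pretrain_epochs=2, finetune_epochs=5, seed=3)
        a = train_dbn(X, labels, cfg)
        b = train_dbn(X, labels, cfg)
        assert np.array_equal(a.head_weights, b.head_weights)
        assert np.array_equal(a.rbm_layers[0].weights, b.rbm_layers[0].weights)

    def test_length_mismatch_rejected(self, rng):
        X, labels = self._toy(10)
        stack = pretrain(X, None, TrainingConfig(pretrain_epochs=0))
        with pytest.raises(ValueError):
            finetune(stack, X, labels[:-1], TrainingConfig())

    def test_freeze_stack_only_moves_head(self):
        X, labels = self._toy(40)
        cfg = TrainingConfig(pretrain_epochs=1, finetune_epochs=5, seed=1, freeze_stack=True)
        stack = pretrain(X, None, cfg)
        model = finetune(stack, X, labels, cfg)
        for before, after in zip(stack, model.rbm_layers):
            assert np.array_equal(before.weights, after.weights)


class TestPredictProba:
    def test_outputs_in_unit_interval(self, rng):
        X, labels = np.ones((5, 9)), [Label.OCD] * 5
        model = train_dbn(X, labels, TrainingConfig(pretrain_epochs=1, finetune_epochs=2, seed=0))
        out = predict_proba(model, X)
        assert ((out >= 0) & (out <= 1)).all()

    def test_zeroed_head_gives_half_half(self, rng):
        stack = [init_rbm(9, 9, rng) for _ in range(3)]
        model = DBNClassifier(
            rbm_layers=tuple(stack),
            head_weights=np.zeros((9, 2)),
            head_bias=np.zeros(2),
            feature_name="initial_psa",
        )
        assert np.allclose(predict_proba(model, np.ones(9)), [0.5, 0.5])

    def test_repeated_calls_identical(self, rng):
        X = rng.integers(0, 2, size=(4, 9)).astype(float)
        model = train_dbn(X, [Label.OCD, Label.NOCD] * 2, TrainingConfig(pretrain_epochs=1, finetune_epochs=2))
        assert np.array_equal(predict_proba(model, X), predict_proba(model, X))


def test_archive_round_trip_is_bit_exact(tmp_path, rng):
    X = rng.integers(0, 2, size=(30, 8)).astype(float)
    labels = [Label.NOCD if x[1] else Label.OCD for x in X]
    model = train_dbn(X, labels, TrainingConfig(pretrain_epochs=2, finetune_epochs=3, seed=8), "clinical_t")
    path = tmp_path / "model.json"
    save_classifier(model, path)
    back = load_classifier(path)
    assert back.feature_name == "clinical_t"
    assert back.config == model.config
    assert np.array_equal(back.head_weights, model.head_weights)
    for a, b in zip(model.rbm_layers, back.rbm_layers):
        assert np.array_equal(a.weights, b.weights)
        assert np.array_equal(a.visible_bias, b.visible_bias)
        assert np.array_equal(a.hidden_bias, b.hidden_bias)
    assert np.array_equal(predict_proba(back, X), predict_proba(model, X))
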