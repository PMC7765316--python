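"""Loss correctness, gradient checks, and training-loop contracts."""

import numpy as np
import pytest

from imuheat import _nn
from imuheat.models import (
    ModelConfig,
    Prediction,
    build_model,
    categorical_cross_entropy,
    predict,
    train,
)

# small but non-trivial configs for each architecture
IMAGE_CFG = dict(kind="convlstm_image", n_classes=3, input_shape=(2, 2, 8, 8),
                 dense_units=8, max_epochs=2, batch_size=4, seed=0)
RAW_CFG = dict(kind="lstm_raw", n_classes=3, input_shape=(6, 5), lstm_units=(8, 8),
               dense_units=8, max_epochs=2, batch_size=4, seed=0)
CONV1D_CFG = dict(kind="convlstm_1d", n_classes=3, input_shape=(8, 12), n_sub=2,
                  dense_units=8, max_epochs=2, batch_size=4, seed=0)
ALL_CFGS = [IMAGE_CFG, RAW_CFG, CONV1D_CFG]


def make_inputs(cfg, n, rng):
    return rng.random((n,) + tuple(cfg["input_shape"]))


class TestCategoricalCrossEntropy:
    def test_uniform_scores_give_log_c(self):
        assert abs(categorical_cross_entropy(np.zeros(13), 5) - np.log(13)) < 1e-12
        assert abs(categorical_cross_entropy(np.full(4, 2.3), 0) - np.log(4)) < 1e-12

    def test_two_class_printed_value(self):
        # s = (1, 0), target 0: L = -ln(e/(e+1))
        expected = -np.log(np.e / (np.e + 1.0))
        assert abs(categorical_cross_entropy(np.array([1.0, 0.0]), 0) - expected) < 1e-9
        assert abs(expected - 0.31326) < 1e-5

    def test_loss_decreases_monotonically_in_target_score(self):
        losses = [
            categorical_cross_entropy(np.array([s, 0.0, 0.0]), 0)
            for s in (0.0, 1.0, 5.0, 20.0, 100.0)
        ]
        assert all(a > b for a, b in zip(losses, losses[1:]))
        assert losses[-1] < 1e-8

    def test_matches_high_precision_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(1000):
            s = rng.normal(scale=5.0, size=rng.integers(2, 20))
            target = int(rng.integers(len(s)))
            sl = np.asarray(s, dtype=np.longdouble)
            oracle = float(-np.log(np.exp(sl[target]) / np.exp(sl).sum()))
            assert abs(categorical_cross_entropy(s, target) - oracle) < 1e-10

    def test_extreme_scores_stay_finite(self):
        assert np.isfinite(categorical_cross_entropy(np.array([1000.0, 0.0]), 1))

    def test_bad_target_rejected(self):
        with pytest.raises(IndexError):
            categorical_cross_entropy(np.zeros(3), 3)


class TestSoftmax:
    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(11)
        p = _nn.softmax(rng.normal(size=(20, 7)) * 10)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(p >= 0)

    def test_invariant_to_constant_shift(self):
        rng = np.random.default_rng(12)
        z = rng.normal(size=(5, 9))
        np.testing.assert_allclose(_nn.softmax(z), _nn.softmax(z + 123.4), atol=1e-6)


class TestGradients:
    @pytest.mark.parametrize("cfg", ALL_CFGS, ids=lambda c: c["kind"])
    def test_autodiff_matches_finite_differences(self, cfg):
        rng = np.random.default_rng(13)
        model = build_model(ModelConfig(**cfg))
        X = make_inputs(cfg, 3, rng)
        y = np.array([0, 1, 2])

        loss = _nn.softmax_cross_entropy(model.forward(X), y)
        loss.backward()
        grads = [p.grad.copy() for p in model.params]

        eps = 1e-6
        rng2 = np.random.default_rng(14)
        for p, g in zip(model.params, grads):
            flat = p.data.reshape(-1)
            for idx in rng2.choice(flat.size, size=min(4, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp = _nn.softmax_cross_entropy(model.forward(X), y).data
                flat[idx] = orig - eps
                lm = _nn.softmax_cross_entropy(model.forward(X), y).data
                flat[idx] = orig
                numeric = (lp - lm) / (2 * eps)
                assert abs(numeric - g.reshape(-1)[idx]) < 1e-6 * max(1.0, abs(numeric))


class TestForwardContracts:
    @pytest.mark.parametrize("cfg", ALL_CFGS, ids=lambda c: c["kind"])
    def test_output_width_and_probability_normalization(self, cfg):
        rng = np.random.default_rng(15)
        model = build_model(ModelConfig(**cfg))
        preds = predict(model, make_inputs(cfg, 4, rng), batch=2)
        assert len(preds) == 4
        for p in preds:
            assert p.p.shape == (cfg["n_classes"],)
            assert abs(p.p.sum() - 1.0) < 1e-6

    def test_batch_invariance(self):
        rng = np.random.default_rng(16)
        cfg = ModelConfig(**IMAGE_CFG)
        model = build_model(cfg)
        X = make_inputs(IMAGE_CFG, 5, rng)
        batched = predict(model, X, batch=5)
        single = [predict(model, X[k : k + 1], batch=1)[0] for k in range(5)]
        for b, s in zip(batched, single):
            np.testing.assert_allclose(b.s, s.s, atol=1e-10)
            assert b.predicted == s.predicted

    def test_tied_probabilities_predict_lowest_index(self):
        cfg = ModelConfig(**IMAGE_CFG)
        model = build_model(cfg)
        for p in model.params:  # zero weights -> all logits equal
            p.data[:] = 0.0
        preds = predict(model, make_inputs(IMAGE_CFG, 2, np.random.default_rng(17)))
        assert all(p.predicted == 0 for p in preds)
        assert all(np.allclose(p.p, 1.0 / cfg.n_classes) for p in preds)

    def test_shape_mismatch_rejected(self):
        model = build_model(ModelConfig(**IMAGE_CFG))
        with pytest.raises(ValueError, match="does not match"):
            predict(model, np.zeros((1, 2, 2, 4, 4)))

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(kind="mlp", n_classes=3, input_shape=(4, 4))
        with pytest.raises(ValueError):
            ModelConfig(kind="lstm_raw", n_classes=1, input_shape=(4, 4))
        with pytest.raises(ValueError):
            ModelConfig(kind="convlstm_image", n_classes=3, input_shape=(4, 4))


def separable_toy_set(rng, n_per_class=12, n_classes=2):
    """Heatmap-like tensors whose active quadrant encodes the class."""
    X, y = [], []
    for c in range(n_classes):
        for _ in range(n_per_class):
            t = np.zeros((2, 2, 8, 8))
            r = slice(0, 4) if c == 0 else slice(4, 8)
            t[:, :, r, r] = rng.random((2, 2, 4, 4))
            X.append(t)
            y.append(c)
    order = rng.permutation(len(X))
    return np.stack(X)[order], np.array(y)[order]


class TestTraining:
    def test_reaches_perfect_accuracy_on_separable_toy_set(self):
        rng = np.random.default_rng(18)
        X, y = separable_toy_set(rng)
        cfg = ModelConfig(kind="convlstm_image", n_classes=2, input_shape=(2, 2, 8, 8),
                          dense_units=8, learning_rate=5e-3, batch_size=8,
                          max_epochs=25, early_stopping_patience=25, seed=1)
        model = build_model(cfg)
        log = train(model, X[:16], y[:16], X[16:], y[16:])
        preds = np.array([p.predicted for p in predict(model, X[:16])])
        assert np.mean(preds == y[:16]) == 1.0
        # loss trends down over the first epochs
        assert log[min(4, len(log) - 1)].train_loss < log[0].train_loss

    def test_fixed_seed_reproduces_training_exactly(self):
        rng = np.random.default_rng(19)
        X, y = separable_toy_set(rng, n_per_class=6)
        cfg = ModelConfig(kind="convlstm_image", n_classes=2, input_shape=(2, 2, 8, 8),
                          dense_units=8, max_epochs=3, batch_size=4, seed=2)
        logs = []
        for _ in range(2):
            model = build_model(cfg)
            logs.append(train(model, X[:8], y[:8], X[8:], y[8:]))
        assert [e.train_loss for e in logs[0]] == [e.train_loss for e in logs[1]]
        assert [e.val_loss for e in logs[0]] == [e.val_loss for e in logs[1]]

    def test_zero_patience_stops_at_first_non_improving_epoch(self):
        rng = np.random.default_rng(20)
        X, y = separable_toy_set(rng, n_per_class=4)
        cfg = ModelConfig(kind="convlstm_image", n_classes=2, input_shape=(2, 2, 8, 8),
                          dense_units=4, learning_rate=0.0,  # loss cannot improve
                          max_epochs=10, early_stopping_patience=0, seed=3)
        model = build_model(cfg)
        log = train(model, X[:4], y[:4], X[4:], y[4:])
        assert len(log) == 2  # epoch 0 sets the baseline; epoch 1 fails to improve
        assert len(log) <= cfg.max_epochs

    def test_empty_sets_rejected(self):
        model = build_model(ModelConfig(**IMAGE_CFG))
        with pytest.raises(ValueError, match="non-empty"):
            train(model, np.zeros((0, 2, 2, 8, 8)), np.zeros(0), np.zeros((0, 2, 2, 8, 8)), np.zeros(0))


class TestSerialization:
    def test_saved_model_reloads_with_identical_predictions(self, tmp_path):
        rng = np.random.default_rng(30)
        from imuheat.models import load_model, save_model, save_training_log

        model = build_model(ModelConfig(**IMAGE_CFG))
        X = make_inputs(IMAGE_CFG, 3, rng)
        path = tmp_path / "model.npz"
        save_model(model, path)
        reloaded = load_model(path)
        a = model.forward(X).data
        b = reloaded.forward(X).data
        np.testing.assert_array_equal(a, b)
        assert reloaded.config == model.config

    def test_training_log_csv_roundtrips_exactly(self, tmp_path):
        import csv

        from imuheat.models import TrainLogEntry, save_training_log

        log = [TrainLogEntry(0, 1.234567890123, 2.0 / 3.0, 0.5),
               TrainLogEntry(1, 0.5, 0.25, 1.0)]
        path = tmp_path / "log.csv"
        save_training_log(log, path)
        with open(path) as fh:
            rows = list(csv.DictReader(fh))
        assert len(rows) == 2
        assert float(rows[0]["val_loss"]) == 2.0 / 3.0
        assert int(rows[1]["epoch"]) == 1
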