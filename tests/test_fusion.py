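"""Softmax head, cross-entropy, Adam training loop, early stopping, and
the dual-path StageModel container."""

import numpy as np
import pytest

from wormstage.fusion import (
    DenseHead,
    StageModel,
    TrainConfig,
    cross_entropy_loss,
    one_hot,
    softmax,
    softmax_predict,
    train_head,
)


class TestSoftmax:
    def test_zero_logits_uniform(self):
        assert np.allclose(softmax(np.zeros(6)), 1 / 6)

    def test_sums_to_one(self):
        rng = np.random.default_rng(0)
        probs = softmax(rng.normal(scale=5, size=(50, 6)))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-12)
        assert np.all((probs > 0) & (probs < 1))

    def test_shift_invariance(self):
        logits = np.array([0.3, -2.0, 5.0, 1.1, 0.0, -0.7])
        assert np.allclose(softmax(logits), softmax(logits + 123.4))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            softmax(np.array([1.0, np.inf]))


class TestCrossEntropy:
    def test_perfect_prediction_zero_loss(self):
        y = one_hot(np.array([3, 1, 6]))
        assert cross_entropy_loss(y, y) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_prediction_ln6(self):
        y = one_hot(np.array([1, 2, 3]))
        pred = np.full((3, 6), 1 / 6)
        assert cross_entropy_loss(y, pred) == pytest.approx(np.log(6), abs=1e-12)

    def test_loss_decreases_toward_truth(self):
        y = one_hot(np.array([1]))
        uniform = np.full((1, 6), 1 / 6)
        better = 0.5 * uniform + 0.5 * y
        assert cross_entropy_loss(y, better) < cross_entropy_loss(y, uniform)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cross_entropy_loss(np.ones((2, 6)), np.ones((3, 6)))


def _separable_data(n=120, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, 4))
    labels = np.where(x[:, 0] + x[:, 1] > 0, 1, 2)
    x[labels == 1] += 2.0
    return x, labels


class TestTraining:
    def test_linearly_separable_reaches_high_accuracy(self):
        x, labels = _separable_data()
        y = one_hot(labels)
        head = DenseHead(4, 32, 6, seed=0)
        cfg = TrainConfig(seed=0, max_epochs=50, early_stop_patience=49, dropout_rate=0.1)
        train_head(head, x, y, x, y, cfg)
        acc = (head.predict_proba(x).argmax(1) + 1 == labels).mean()
        assert acc >= 0.95

    def test_identical_seed_identical_history(self):
        x, labels = _separable_data()
        y = one_hot(labels)
        histories = []
        for _ in range(2):
            head = DenseHead(4, 16, 6, seed=3)
            cfg = TrainConfig(seed=3, max_epochs=20, early_stop_patience=19)
            histories.append(train_head(head, x, y, x, y, cfg))
        assert histories[0].equals(histories[1])

    def test_early_stopping_on_flat_validation(self):
        """With a vanishing learning rate the validation loss never
        improves after epoch 1, so training halts after exactly
        patience + 1 epochs."""
        x, labels = _separable_data(n=40)
        y = one_hot(labels)
        head = DenseHead(4, 8, 6, seed=1)
        cfg = TrainConfig(seed=1, learning_rate=1e-30, max_epochs=100,
                          early_stop_patience=7, dropout_rate=0.0)
        history = train_head(head, x, y, x, y, cfg)
        assert len(history) == cfg.early_stop_patience + 1

    def test_divergence_aborts(self):
        x, labels = _separable_data(n=30)
        y = one_hot(labels)
        head = DenseHead(4, 8, 6, seed=0)
        head.w1[:] = np.inf  # poisoned weights -> non-finite activations
        cfg = TrainConfig(seed=0, max_epochs=5, early_stop_patience=2)
        with pytest.raises((FloatingPointError, ValueError)):
            train_head(head, x, y, x, y, cfg)

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            TrainConfig(early_stop_patience=50, max_epochs=50)
        with pytest.raises(ValueError):
            TrainConfig(dropout_rate=1.0)


class TestStageModel:
    def test_both_paths_disabled_rejected(self):
        with pytest.raises(ValueError):
            StageModel(use_m1=False, use_m2=False)

    def test_fit_predict_roundtrip_on_features(self):
        rng = np.random.default_rng(0)
        n = 180
        labels = rng.integers(1, 7, size=n)
        f2 = labels[:, None] * 10.0 + rng.normal(size=(n, 12))  # informative
        model = StageModel(use_m1=False, use_m2=True)
        f1 = rng.normal(size=(n, model.backbone.feature_length))
        model.fit_features(f1, f2, labels, TrainConfig(seed=0, max_epochs=60))
        probs = model.predict_proba_features(f1, f2)
        assert probs.shape == (n, 6)
        assert np.allclose(probs.sum(axis=1), 1.0)
        assert (probs.argmax(1) + 1 == labels).mean() > 0.8

    def test_save_load_preserves_predictions(self, tmp_path):
        rng = np.random.default_rng(1)
        labels = rng.integers(1, 7, size=120)
        f2 = labels[:, None] + rng.normal(size=(120, 12))
        model = StageModel(use_m1=False, use_m2=True)
        f1 = rng.normal(size=(120, model.backbone.feature_length))
        model.fit_features(f1, f2, labels, TrainConfig(seed=1, max_epochs=30))
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = StageModel.load(path)
        assert np.allclose(
            model.predict_proba_features(f1, f2),
            loaded.predict_proba_features(f1, f2),
        )

    def test_missing_model_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            StageModel.load(tmp_path / "missing.npz")

    def test_predict_stage_full_path(self, desk_config, filter_config):
        """End-to-end single-image inference returns a 6-vector summing to
        one and a hard label."""
        from wormstage.synthetic import generate_worm_image

        rng = np.random.default_rng(0)
        model = StageModel(filter_config=filter_config)
        n = 40
        labels = np.tile(np.arange(1, 7), 7)[:n]
        f1 = rng.normal(size=(n, model.backbone.feature_length))
        f2 = rng.normal(size=(n, 12))
        model.fit_features(f1, f2, labels, TrainConfig(seed=0, max_epochs=30))
        img, _ = generate_worm_image(desk_config, 0.5)
        probs, group = model.predict_stage(img.pixels)
        assert probs.shape == (6,)
        assert probs.sum() == pytest.approx(1.0)
        assert 1 <= group <= 6
        assert group == int(probs.argmax()) + 1

    def test_zeroed_paths_give_prior_prediction(self):
        """With both feature vectors at their training mean (zeros after
        standardization) the head outputs its bias-driven prior — a valid
        probability vector, identical for any such input."""
        rng = np.random.default_rng(2)
        labels = rng.integers(1, 7, size=100)
        model = StageModel(use_m1=True, use_m2=True)
        f1 = rng.normal(size=(100, model.backbone.feature_length))
        f2 = rng.normal(size=(100, 12))
        model.fit_features(f1, f2, labels, TrainConfig(seed=2, max_epochs=30))
        z = model.head.predict_proba(np.zeros((1, model.backbone.feature_length + 12)))
        assert z.shape == (1, 6)
        assert z.sum() == pytest.approx(1.0)


def test_softmax_predict_single_vector():
    head = DenseHead(5, 8, 6, seed=0)
    out = softmax_predict(np.zeros(5), head)
    assert out.shape == (6,)
    assert out.sum() == pytest.approx(1.0)
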