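"""Joint-loss arithmetic and optimization behaviour."""

import numpy as np
import pytest

from conftest import make_labeled_segments, normalized, tiny_model_config
from deepeeg.errors import ConfigurationError, TrainingDivergedError
from deepeeg.models import build_model, instantiate
from deepeeg.preprocess import balance_classes, reshape_for_model
from deepeeg.training import TrainConfig, evaluate, joint_loss, train

RNG = np.random.default_rng(77)


class TestJointLoss:
    def test_perfect_prediction_and_reconstruction_is_zero(self):
        probs = np.array([[1.0, 0.0], [0.0, 1.0]])
        labels = np.array([0, 1])
        x = RNG.random((2, 3, 4, 1))
        loss = joint_loss(probs, labels, x.copy(), x, 1.0)
        assert loss == pytest.approx(0.0, abs=1e-6)

    def test_lambda_zero_is_plain_cross_entropy(self):
        probs = np.array([[0.8, 0.2], [0.3, 0.7]])
        labels = np.array([0, 1])
        junk = RNG.random((2, 5))
        expected = -np.mean([np.log(0.8), np.log(0.7)])
        assert joint_loss(probs, labels, junk, np.zeros_like(junk), 0.0) \
            == pytest.approx(expected)

    def test_uniform_two_class_prediction_is_ln2(self):
        probs = np.full((8, 2), 0.5)
        labels = RNG.integers(0, 2, 8)
        x = RNG.random((8, 2, 2))
        assert joint_loss(probs, labels, x.copy(), x, 1.0) \
            == pytest.approx(np.log(2), abs=1e-9)

    def test_mse_term_weighted(self):
        probs = np.array([[1.0, 0.0]])
        labels = np.array([0])
        recon = np.zeros((1, 4))
        orig = np.ones((1, 4))
        assert joint_loss(probs, labels, recon, orig, 2.5) \
            == pytest.approx(2.5 * 1.0, abs=1e-6)


@pytest.fixture(scope="module")
def small_separable():
    segs = balance_classes(make_labeled_segments(seed=11), seed=0)
    return normalized(segs)


class TestTraining:
    def test_history_has_one_entry_per_epoch(self, small_separable):
        subset = small_separable.subset(np.arange(64))
        model = instantiate(build_model(tiny_model_config(), (4, 64)))
        _, hist = train(model, subset, None,
                        TrainConfig(epochs=2, batch_size=16, seed=0))
        assert len(hist) == 2
        assert all(np.isfinite(hist.loss))

    def test_seed_reproduces_epoch_one_loss(self, small_separable):
        subset = small_separable.subset(np.arange(64))
        cfg = TrainConfig(epochs=1, batch_size=16, seed=5)
        losses = []
        for _ in range(2):
            model = instantiate(build_model(tiny_model_config(seed=5), (4, 64)))
            _, hist = train(model, subset, None, cfg)
            losses.append(hist.loss[0])
        assert losses[0] == losses[1]

    def test_single_class_data_rejected(self, small_separable):
        only_zero = small_separable.subset(small_separable.labels == 0)
        model = instantiate(build_model(tiny_model_config(), (4, 64)))
        with pytest.raises(ConfigurationError, match="both classes"):
            train(model, only_zero, None, TrainConfig(epochs=1))

    def test_gradient_step_reduces_fixed_batch_loss(self, small_separable):
        """One small-lr step on a fixed batch strictly reduces its loss."""
        batch = small_separable.subset(np.arange(16))
        cfg = tiny_model_config(dropout_rate=0.0)
        model = instantiate(build_model(cfg, (4, 64)))
        tc = TrainConfig(optimizer="sgd", learning_rate=1e-5, epochs=1,
                         batch_size=16, seed=0)
        before, _ = evaluate(model, batch, tc)
        train(model, batch, None, tc)
        after, _ = evaluate(model, batch, tc)
        assert after < before

    def test_learns_separable_data(self, small_separable):
        """Seizure windows at 5x amplitude are learned to high accuracy."""
        model = instantiate(build_model(tiny_model_config(seed=1), (4, 64)))
        tc = TrainConfig(epochs=30, batch_size=25, seed=1,
                         learning_rate=1e-3)
        model, hist = train(model, small_separable, None, tc)
        assert hist.loss[-1] <= hist.loss[0]
        _, acc = evaluate(model, small_separable, tc)
        assert acc >= 0.95

    def test_reconstruction_beats_mean_predictor(self, small_separable):
        train_part = small_separable.subset(np.arange(60))
        held_out = small_separable.subset(np.arange(60, 90))
        model = instantiate(build_model(tiny_model_config(seed=2), (4, 64)))
        tc = TrainConfig(epochs=60, batch_size=20, seed=2, learning_rate=3e-3)
        model, _ = train(model, train_part, None, tc)
        x = reshape_for_model(held_out)
        recon = model.reconstruct(x)
        assert np.mean((recon - x) ** 2) < x.var()

    def test_two_phase_mode_runs_pretraining_epochs(self, small_separable):
        subset = small_separable.subset(np.arange(48))
        model = instantiate(build_model(tiny_model_config(), (4, 64)))
        tc = TrainConfig(epochs=4, batch_size=16, seed=0, two_phase=True)
        _, hist = train(model, subset, None, tc)
        assert len(hist) == 4 + 4 // 2

    def test_early_stopping_truncates_history(self, small_separable):
        import dataclasses

        tr = small_separable.subset(np.arange(48))
        # adversarial validation set (flipped labels): val loss must rise
        # as the model learns, so patience runs out well before the budget
        val = small_separable.subset(np.arange(48, 80))
        val = dataclasses.replace(val, labels=1 - val.labels)
        model = instantiate(build_model(tiny_model_config(), (4, 64)))
        tc = TrainConfig(epochs=60, batch_size=16, seed=0, learning_rate=1e-3,
                         early_stop_patience=2, loss_weight_lambda=0.0)
        _, hist = train(model, tr, val, tc)
        assert len(hist) < 60

    def test_stop_at_train_accuracy_halts_after_convergence(self, small_separable):
        model = instantiate(build_model(tiny_model_config(seed=1), (4, 64)))
        tc = TrainConfig(epochs=60, batch_size=25, seed=1, learning_rate=1e-3,
                         stop_at_train_accuracy=0.99)
        model, hist = train(model, small_separable, None, tc)
        assert len(hist) < 60
        _, acc = evaluate(model, small_separable, tc)
        assert acc >= 0.99

    def test_divergence_reported_with_location(self, small_separable):
        subset = small_separable.subset(np.arange(32))
        model = instantiate(build_model(tiny_model_config(), (4, 64)))
        tc = TrainConfig(optimizer="sgd", learning_rate=1e12, epochs=5,
                         batch_size=16, seed=0)
        import warnings

        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            with pytest.raises(TrainingDivergedError, match="epoch"):
                train(model, subset, None, tc)


class TestTrainConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [dict(optimizer="lbfgs"), dict(learning_rate=0.0),
         dict(batch_size=0), dict(loss_weight_lambda=-1.0)],
    )
    def test_invalid_values_rejected(self, kw):
        with pytest.raises(ConfigurationError):
            TrainConfig(**kw)
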