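"""Joint training of reconstruction and classification objectives.

The autoencoder variants are trained single-phase on the combined loss

    L = cross_entropy(y, p) + lambda * MSE(x, x_hat)

with both terms batch-averaged; ``lambda`` (``loss_weight``) defaults
to 1.  The optimizer defaults follow the reference configuration: Adam,
learning rate 1e-4, batch size 50, 40 epochs.  A two-phase mode
(reconstruction-only pretraining before joint training) is available
behind a flag for ablation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, TrainingDivergedError
from .models import JointModel, ModelDescriptor, instantiate
from .nn import (
    cross_entropy_from_probs,
    make_optimizer,
    mean_squared_error,
    softmax_cross_entropy,
)
from .preprocess import SegmentSet, reshape_for_model

__all__ = ["TrainConfig", "TrainHistory", "joint_loss", "train", "evaluate"]

OPTIMIZERS = ("adam", "sgd", "rmsprop", "adadelta")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (defaults: Adam, lr 1e-4, batch 50,
    40 epochs, reconstruction weight 1)."""

    optimizer: str = "adam"
    learning_rate: float = 1e-4
    batch_size: int = 50
    epochs: int = 40
    loss_weight_lambda: float = 1.0
    seed: int = 0
    early_stop_patience: int | None = None
    stop_at_train_accuracy: float | None = None
    two_phase: bool = False

    def __post_init__(self):
        if self.optimizer not in OPTIMIZERS:
            raise ConfigurationError(
                f"unknown optimizer {self.optimizer!r}; choose from {OPTIMIZERS}"
            )
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")
        if self.batch_size < 1 or self.epochs < 0:
            raise ConfigurationError("batch_size >= 1 and epochs >= 0 required")
        if self.loss_weight_lambda < 0:
            raise ConfigurationError("loss_weight_lambda must be >= 0")
        if self.stop_at_train_accuracy is not None and not (
            0 < self.stop_at_train_accuracy <= 1
        ):
            raise ConfigurationError("stop_at_train_accuracy must be in (0, 1]")


@dataclass
class TrainHistory:
    """Per-epoch curves; one entry per completed epoch."""

    loss: list[float] = field(default_factory=list)
    class_loss: list[float] = field(default_factory=list)
    recon_loss: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.loss)

    def as_dict(self) -> dict:
        return {
            "loss": self.loss,
            "class_loss": self.class_loss,
            "recon_loss": self.recon_loss,
            "accuracy": self.accuracy,
            "val_loss": self.val_loss,
            "val_accuracy": self.val_accuracy,
        }


def joint_loss(
    class_probs: np.ndarray,
    labels: np.ndarray,
    reconstruction: np.ndarray | None,
    original: np.ndarray | None,
    loss_weight_lambda: float = 1.0,
) -> float:
    """Combined loss: cross-entropy plus weighted reconstruction MSE.

    ``class_probs`` are probabilities (rows summing to 1); the probability
    of the true class is clamped at 1e-7 so the loss is never infinite.
    With ``loss_weight_lambda`` 0 or no reconstruction, this is plain
    cross-entropy.
    """
    ce = cross_entropy_from_probs(np.asarray(class_probs), np.asarray(labels))
    if reconstruction is None or loss_weight_lambda == 0:
        return ce
    mse, _ = mean_squared_error(
        np.asarray(reconstruction), np.asarray(original)
    )
    return ce + loss_weight_lambda * mse


def _as_model_input(data) -> tuple[np.ndarray, np.ndarray | None]:
    if isinstance(data, SegmentSet):
        return reshape_for_model(data), data.labels
    if isinstance(data, tuple):
        x, y = data
        x = np.asarray(x)
        if x.ndim == 3:
            x = x[..., None]
        return x, np.asarray(y)
    return np.asarray(data), None


def _eval_accuracy(model, x, y, batch_size) -> float:
    """Training-set accuracy without dropout (convergence check)."""
    correct = 0
    for i in range(0, len(x), batch_size):
        logits, _ = model.forward(x[i : i + batch_size], train=False)
        correct += int((logits.argmax(axis=1) == y[i : i + batch_size]).sum())
    return correct / len(x)


def evaluate(
    model: JointModel, segments: SegmentSet, config: TrainConfig
) -> tuple[float, float]:
    """(joint loss, accuracy) of a model on a segment set, without dropout."""
    x, y = _as_model_input(segments)
    x = x.astype(model.dtype)
    losses, correct = [], 0
    lam = config.loss_weight_lambda
    for i in range(0, len(x), config.batch_size):
        xb, yb = x[i : i + config.batch_size], y[i : i + config.batch_size]
        logits, recon = model.forward(xb, train=False)
        ce, probs, _ = softmax_cross_entropy(logits, yb)
        loss = ce
        if recon is not None and lam > 0:
            mse, _ = mean_squared_error(recon, xb)
            loss += lam * mse
        losses.append(loss * len(xb))
        correct += int((probs.argmax(axis=1) == yb).sum())
    n = len(x)
    return float(np.sum(losses) / n), correct / n


def train(
    model: JointModel | ModelDescriptor,
    train_set: SegmentSet,
    val_set: SegmentSet | None,
    config: TrainConfig,
) -> tuple[JointModel, TrainHistory]:
    """Optimize a model on a (normalized) training segment set.

    Deterministic for a fixed ``config.seed`` (up to floating-point
    reduction order).  Raises :class:`TrainingDivergedError` with the
    offending epoch/batch if the loss turns non-finite.
    """
    if isinstance(model, ModelDescriptor):
        model = instantiate(model)
    x, y = _as_model_input(train_set)
    if y is None or len(np.unique(y)) < 2:
        raise ConfigurationError("training data must contain both classes")
    x = x.astype(model.dtype)
    lam = config.loss_weight_lambda if model.decoder is not None else 0.0

    opt = make_optimizer(
        config.optimizer, model.params, model.grads, config.learning_rate
    )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
    history = TrainHistory()

    pretrain = config.epochs // 2 if config.two_phase else 0
    total_epochs = pretrain + config.epochs if config.two_phase else config.epochs

    best_val, patience_left = np.inf, config.early_stop_patience
    best_train_acc, best_weights = -1.0, None
    for epoch in range(total_epochs):
        recon_only = epoch < pretrain
        order = rng.permutation(len(x))
        ep_loss = ep_ce = ep_mse = 0.0
        correct = 0
        for bi, start in enumerate(range(0, len(x), config.batch_size)):
            idx = order[start : start + config.batch_size]
            xb, yb = x[idx], y[idx]
            logits, recon = model.forward(xb, train=True)
            ce, probs, dlogits = softmax_cross_entropy(logits, yb)
            mse, drecon = (
                mean_squared_error(recon, xb) if recon is not None else (0.0, None)
            )
            loss = ce + lam * mse
            if not np.isfinite(loss):
                raise TrainingDivergedError(epoch, bi, loss)
            if recon_only:
                if drecon is None:
                    raise ConfigurationError(
                        "two-phase pretraining requires a decoder"
                    )
                model.backward(np.zeros_like(dlogits), drecon)
            else:
                model.backward(
                    dlogits,
                    None if drecon is None or lam == 0 else lam * drecon,
                )
            opt.step()
            ep_loss += loss * len(xb)
            ep_ce += ce * len(xb)
            ep_mse += mse * len(xb)
            correct += int((probs.argmax(axis=1) == yb).sum())
        n = len(x)
        history.loss.append(ep_loss / n)
        history.class_loss.append(ep_ce / n)
        history.recon_loss.append(ep_mse / n)
        history.accuracy.append(correct / n)
        if config.stop_at_train_accuracy is not None and not recon_only:
            tacc = _eval_accuracy(model, x, y, config.batch_size)
            if tacc > best_train_acc:
                best_train_acc = tacc
                best_weights = model.get_weights()
            if tacc >= config.stop_at_train_accuracy:
                if val_set is not None and len(val_set):
                    vloss, vacc = evaluate(model, val_set, config)
                    history.val_loss.append(vloss)
                    history.val_accuracy.append(vacc)
                break
        if val_set is not None and len(val_set):
            vloss, vacc = evaluate(model, val_set, config)
            history.val_loss.append(vloss)
            history.val_accuracy.append(vacc)
            if config.early_stop_patience is not None and not recon_only:
                if vloss < best_val - 1e-6:
                    best_val, patience_left = vloss, config.early_stop_patience
                else:
                    patience_left -= 1
                    if patience_left <= 0:
                        break
    # under the convergence stop rule, a late epoch can regress (the joint
    # objective occasionally destabilizes a converged classifier); return
    # the best state seen rather than the last
    if best_weights is not None and best_train_acc > _eval_accuracy(
        model, x, y, config.batch_size
    ):
        model.set_weights(best_weights)
    return model, history
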