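"""scikit-learn estimators wrapping the seizure-detection models.

:class:`SegmentScaler` is the two-step normalizer (per-channel z-score,
then global min-max to [0, 1]) as a transformer; :class:`DCAEClassifier`
is the convolutional-autoencoder classifier as a fit/predict estimator.
Both operate on arrays of shape ``(n_segments, n_channels, n_samples)``
and compose with sklearn pipelines and model selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .errors import DegenerateChannelError
from .models import ModelConfig, build_model, instantiate
from .training import TrainConfig, train

__all__ = ["SegmentScaler", "DCAEClassifier"]


def _check_segments(X) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 3:
        raise ValueError(
            f"expected (n_segments, n_channels, n_samples), got shape {X.shape}"
        )
    if not np.all(np.isfinite(X)):
        raise ValueError("input contains NaN or infinite values")
    return X


class SegmentScaler(TransformerMixin, BaseEstimator):
    """Per-channel z-score followed by global min-max scaling to [0, 1].

    Channel moments are computed over the pooled training segments; the
    min-max range over all z-scored training values.  ``transform`` clips
    out-of-range held-out values to [0, 1].
    """

    def fit(self, X, y=None):
        X = _check_segments(X)
        self.mu_ = X.mean(axis=(0, 2))
        self.sigma_ = X.std(axis=(0, 2))
        if np.any(self.sigma_ == 0):
            raise DegenerateChannelError(np.nonzero(self.sigma_ == 0)[0].tolist())
        z = (X - self.mu_[None, :, None]) / self.sigma_[None, :, None]
        self.min_ = float(z.min())
        self.max_ = float(z.max())
        if not self.min_ < self.max_:
            raise ValueError("degenerate value range after z-scoring")
        return self

    def transform(self, X):
        check_is_fitted(self, "mu_")
        X = _check_segments(X)
        z = (X - self.mu_[None, :, None]) / self.sigma_[None, :, None]
        return np.clip((z - self.min_) / (self.max_ - self.min_), 0.0, 1.0)

    def inverse_transform(self, X):
        check_is_fitted(self, "mu_")
        z = np.asarray(X) * (self.max_ - self.min_) + self.min_
        return z * self.sigma_[None, :, None] + self.mu_[None, :, None]


class DCAEClassifier(ClassifierMixin, BaseEstimator):
    """Convolutional-autoencoder seizure classifier with a recurrent head.

    Parameters mirror the reference architecture/training configuration;
    see :mod:`deepeeg.models` and :mod:`deepeeg.training`.  ``head`` is one
    of ``"mlp"``, ``"lstm"``, ``"bilstm"``; ``autoencoder=False`` yields
    the DCNN baseline without a reconstruction objective.

    Inputs are expected min-max scaled to [0, 1] (e.g. by
    :class:`SegmentScaler` in a pipeline); the sigmoid reconstruction
    output lives in that range.

    Attributes (after fit): ``classes_``, ``model_``, ``history_``,
    ``input_hw_``, ``n_parameters_``.
    """

    def __init__(
        self,
        head: str = "bilstm",
        autoencoder: bool = True,
        encoder_filters: tuple = (32, 32, 64, 64),
        decoder_filters: tuple = (64, 32, 32, 1),
        kernel: int = 3,
        pool: int = 2,
        bilstm_units: int = 80,
        dense_units: int = 50,
        dropout_rate: float = 0.75,
        avg_pool_after_dense: bool = False,
        optimizer: str = "adam",
        learning_rate: float = 1e-4,
        batch_size: int = 50,
        epochs: int = 40,
        loss_weight_lambda: float = 1.0,
        early_stop_patience: int | None = None,
        two_phase: bool = False,
        random_state: int = 0,
    ):
        self.head = head
        self.autoencoder = autoencoder
        self.encoder_filters = encoder_filters
        self.decoder_filters = decoder_filters
        self.kernel = kernel
        self.pool = pool
        self.bilstm_units = bilstm_units
        self.dense_units = dense_units
        self.dropout_rate = dropout_rate
        self.avg_pool_after_dense = avg_pool_after_dense
        self.optimizer = optimizer
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.loss_weight_lambda = loss_weight_lambda
        self.early_stop_patience = early_stop_patience
        self.two_phase = two_phase
        self.random_state = random_state

    # -- config assembly ----------------------------------------------------

    def _model_config(self) -> ModelConfig:
        return ModelConfig(
            encoder_filters=tuple(self.encoder_filters),
            decoder_filters=tuple(self.decoder_filters),
            kernel=self.kernel,
            pool=self.pool,
            head=self.head,
            bilstm_units=self.bilstm_units,
            dense_units=self.dense_units,
            dropout_rate=self.dropout_rate,
            autoencoder=self.autoencoder,
            avg_pool_after_dense=self.avg_pool_after_dense,
            seed=self.random_state,
        )

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            optimizer=self.optimizer,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            epochs=self.epochs,
            loss_weight_lambda=self.loss_weight_lambda,
            seed=self.random_state,
            early_stop_patience=self.early_stop_patience,
            two_phase=self.two_phase,
        )

    # -- estimator API ------------------------------------------------------

    def fit(self, X, y):
        X = _check_segments(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(
                f"binary classifier: need exactly 2 classes, got {self.classes_}"
            )
        y_idx = np.searchsorted(self.classes_, y)
        self.input_hw_ = (X.shape[1], X.shape[2])
        descriptor = build_model(self._model_config(), self.input_hw_)
        self.descriptor_ = descriptor
        model, history = train(
            instantiate(descriptor), (X, y_idx), None, self._train_config()
        )
        self.model_ = model
        self.history_ = history
        self.n_parameters_ = model.n_parameters()
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        X = _check_segments(X)
        return self.model_.predict_proba(X[..., None])

    def predict(self, X):
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def reconstruct(self, X):
        """Decoder reconstruction of the inputs (autoencoder variants)."""
        check_is_fitted(self, "model_")
        X = _check_segments(X)
        return self.model_.reconstruct(X[..., None])[..., 0]

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.input_tags.two_d_array = False
        tags.target_tags.required = True
        return tags
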