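"""Classification and reconstruction losses.

Cross-entropy is computed from logits through a numerically stable fused
softmax; probabilities are clamped at 1e-7 so a confidently wrong
prediction yields a large but finite loss.
"""

from __future__ import annotations

import numpy as np

EPS = 1e-7

__all__ = [
    "softmax",
    "softmax_cross_entropy",
    "cross_entropy_from_probs",
    "mean_squared_error",
    "EPS",
]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy and gradient w.r.t. logits.

    Returns ``(loss, probs, dlogits)``; ``dlogits`` is already divided by
    the batch size.
    """
    n = logits.shape[0]
    probs = softmax(logits)
    p_true = np.clip(probs[np.arange(n), labels], EPS, 1.0)
    loss = float(-np.log(p_true).mean())
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    dlogits /= n
    return loss, probs, dlogits


def cross_entropy_from_probs(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean negative log-probability of the true class (clamped)."""
    n = probs.shape[0]
    p_true = np.clip(probs[np.arange(n), labels], EPS, 1.0)
    return float(-np.log(p_true).mean())


def mean_squared_error(prediction: np.ndarray, target: np.ndarray):
    """Element-mean squared error and gradient w.r.t. prediction."""
    diff = prediction - target
    loss = float(np.mean(diff * diff))
    dpred = (2.0 / diff.size) * diff
    return loss, dpred
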