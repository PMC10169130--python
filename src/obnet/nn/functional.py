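"""Loss functions and related numerics on engine tensors."""

from __future__ import annotations

import numpy as np

from .engine import Tensor


def log_softmax(logits: Tensor) -> Tensor:
    """Row-wise log-softmax, shifted by the (detached) row max for stability."""
    m = logits.data.max(axis=1, keepdims=True)
    z = logits - m
    return z - z.exp().sum(axis=1, keepdims=True).log()


def cross_entropy(logits: Tensor, labels: np.ndarray,
                  class_weights: np.ndarray | None = None) -> Tensor:
    """Class-weighted multinomial cross-entropy.

    With weights w the loss is sum_i w_{y_i} * nll_i / sum_i w_{y_i}, which
    reduces to the plain mean when the weights are uniform.
    """
    labels = np.asarray(labels, dtype=int)
    n, k = logits.shape
    logp = log_softmax(logits)
    if class_weights is None:
        w = np.ones(k, dtype=logits.dtype)
    else:
        w = np.asarray(class_weights, dtype=logits.dtype)
    pick = np.zeros((n, k), dtype=logits.dtype)
    pick[np.arange(n), labels] = w[labels]
    denom = float(w[labels].sum())
    return -(logp * pick).sum() * (1.0 / denom)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean elementwise binary cross-entropy on logits (numerically stable)."""
    t = np.asarray(targets, dtype=logits.dtype)
    ax = logits.relu() + (-logits).relu()  # |x|
    elem = logits.relu() - logits * t + (1.0 + (-ax).exp()).log()
    return elem.mean()


def binary_cross_entropy(probs: Tensor, targets: np.ndarray,
                         eps: float = 1e-7) -> Tensor:
    """Mean BCE on probabilities, clipped to [eps, 1-eps]."""
    t = np.asarray(targets, dtype=probs.dtype)
    p = probs.clip(eps, 1.0 - eps)
    return -(t * p.log() + (1.0 - t) * (1.0 - p).log()).mean()


def softmax(logits: np.ndarray) -> np.ndarray:
    """Plain NumPy softmax over the last axis (for evaluation paths)."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)
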