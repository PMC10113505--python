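"""Training losses defined on softmax probabilities.

Every loss maps one-hot targets ``y`` and probability rows ``p`` to a
scalar plus the gradient with respect to ``p``; the network chains that
gradient through the softmax Jacobian.  Definitions follow the common
deep-learning conventions: the hinge family reads targets as +-1 and
averages over classes, Poisson averages ``p - y log p`` over classes, and
KL divergence reduces to cross-entropy minus the (zero, for one-hot)
target entropy.
"""

from __future__ import annotations

import numpy as np

__all__ = ["get_loss", "LOSS_FUNCTIONS", "softmax", "chain_through_softmax"]

_EPS = 1e-12


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def chain_through_softmax(p: np.ndarray, dp: np.ndarray) -> np.ndarray:
    """Gradient w.r.t. logits given gradient w.r.t. probabilities."""
    return p * (dp - (dp * p).sum(axis=1, keepdims=True))


def _categorical_crossentropy(y, p):
    n = y.shape[0]
    value = float(-(y * np.log(p + _EPS)).sum() / n)
    grad = -(y / (p + _EPS)) / n
    return value, grad


def _kl_divergence(y, p):
    n = y.shape[0]
    value = float((y * (np.log(y + _EPS) - np.log(p + _EPS))).sum() / n)
    grad = -(y / (p + _EPS)) / n
    return value, grad


def _poisson(y, p):
    n, c = y.shape
    value = float((p - y * np.log(p + _EPS)).sum() / (n * c))
    grad = (1.0 - y / (p + _EPS)) / (n * c)
    return value, grad


def _hinge(y, p):
    n, c = y.shape
    t = 2.0 * y - 1.0
    margin = 1.0 - t * p
    active = margin > 0
    value = float(np.where(active, margin, 0.0).sum() / (n * c))
    grad = np.where(active, -t, 0.0) / (n * c)
    return value, grad


def _squared_hinge(y, p):
    n, c = y.shape
    t = 2.0 * y - 1.0
    margin = np.maximum(1.0 - t * p, 0.0)
    value = float((margin**2).sum() / (n * c))
    grad = -2.0 * t * margin / (n * c)
    return value, grad


def _categorical_hinge(y, p):
    n = y.shape[0]
    pos = (y * p).sum(axis=1)
    neg = ((1.0 - y) * p).max(axis=1)
    margin = 1.0 + neg - pos
    active = margin > 0
    value = float(np.where(active, margin, 0.0).sum() / n)
    grad = np.zeros_like(p)
    neg_idx = np.argmax(np.where(y > 0, -np.inf, p), axis=1)
    rows = np.arange(n)
    grad[rows, neg_idx] += np.where(active, 1.0, 0.0)
    grad -= y * np.where(active, 1.0, 0.0)[:, None]
    return value, grad / n


LOSS_FUNCTIONS = {
    "categorical_crossentropy": _categorical_crossentropy,
    "kl_divergence": _kl_divergence,
    "poisson": _poisson,
    "hinge": _hinge,
    "squared_hinge": _squared_hinge,
    "categorical_hinge": _categorical_hinge,
}


def get_loss(name: str):
    try:
        return LOSS_FUNCTIONS[name]
    except KeyError:
        raise ValueError(
            f"unknown loss {name!r}; choose from {sorted(LOSS_FUNCTIONS)}"
        ) from None
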