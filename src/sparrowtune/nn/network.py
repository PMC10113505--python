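"""Sequential network: forward/backward, mini-batch training, prediction."""

from __future__ import annotations

from typing import Callable, Optional

import numpy as np

from .layers import Layer
from .losses import chain_through_softmax, get_loss, softmax
from .optimizers import get_optimizer

__all__ = ["NeuralNetwork", "DivergenceError", "one_hot"]


class DivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


def one_hot(y: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((len(y), n_classes))
    out[np.arange(len(y)), y] = 1.0
    return out


class NeuralNetwork:
    """A stack of layers ending in a softmax classification head.

    The final layer must produce one logit per class; ``predict_proba``
    applies the softmax.  ``fit`` trains with the configured loss and
    optimizer on shuffled mini-batches; randomness (shuffling, dropout,
    per-batch augmentation) is drawn from a single generator for seeded
    reproducibility.
    """

    def __init__(self, layers: list, loss: str, optimizer: str, seed=None):
        self.layers = layers
        self.loss_name = loss
        self.optimizer_name = optimizer
        self._loss = get_loss(loss)
        self._optimizer = get_optimizer(optimizer)
        self.rng = (
            seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        )
        self.history: list = []

    # -- parameter bookkeeping --------------------------------------------

    @property
    def n_params(self) -> int:
        return sum(layer.n_params for layer in self.layers)

    @property
    def n_trainable_params(self) -> int:
        return sum(layer.n_params for layer in self.layers if layer.trainable)

    # -- forward / backward ------------------------------------------------

    def _forward_logits(self, x: np.ndarray, training: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training, rng=self.rng)
        return x

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self._forward_logits(np.asarray(x, dtype=float), False))

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(x), axis=1)

    def train_on_batch(self, x: np.ndarray, y_onehot: np.ndarray) -> float:
        logits = self._forward_logits(x, training=True)
        probs = softmax(logits)
        value, dprobs = self._loss(y_onehot, probs)
        if not np.isfinite(value):
            raise DivergenceError(
                f"non-finite {self.loss_name} loss during training"
            )
        grad = chain_through_softmax(probs, dprobs)
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        self._optimizer.start_step()
        for li, layer in enumerate(self.layers):
            if not layer.trainable:
                continue
            for name, param in layer.params.items():
                self._optimizer.update(f"{li}.{name}", param, layer.grads[name])
        return value

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        epochs: int,
        batch_size: int,
        augment_fn: Optional[Callable] = None,
        shuffle: bool = True,
    ) -> list:
        """Train; returns per-epoch mean losses.  ``augment_fn(batch, rng)``
        is applied to each mini-batch when given (on-the-fly augmentation)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=int)
        n_classes = self.layers[-1].params["b"].shape[0]
        yh = one_hot(y, n_classes)
        n = len(x)
        for _ in range(int(epochs)):
            order = self.rng.permutation(n) if shuffle else np.arange(n)
            losses = []
            for start in range(0, n, int(batch_size)):
                idx = order[start : start + int(batch_size)]
                xb = x[idx]
                if augment_fn is not None:
                    xb = augment_fn(xb, self.rng)
                losses.append(self.train_on_batch(xb, yh[idx]))
            self.history.append(float(np.mean(losses)))
        return self.history
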