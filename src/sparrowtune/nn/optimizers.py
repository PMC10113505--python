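"""First-order optimizers with the conventional default settings.

Eleven update rules are provided: plain and Nesterov-momentum SGD, the
Adam family (Adam, AMSGrad, NAdam, AdaMax), the adaptive-accumulator
family (AdaGrad, AdaDelta, RMSProp with and without centering) and
FTRL-proximal.  State (momenta, accumulators) is keyed per parameter
array, created lazily on first update.
"""

from __future__ import annotations

import numpy as np

__all__ = ["get_optimizer", "OPTIMIZER_FACTORIES"]


class _Optimizer:
    def __init__(self, lr: float):
        self.lr = lr
        self.state: dict = {}
        self.t = 0

    def _slot(self, key, like, names):
        if key not in self.state:
            self.state[key] = {n: np.zeros_like(like) for n in names}
        return self.state[key]

    def start_step(self):
        self.t += 1

    def update(self, key, param, grad):  # pragma: no cover
        raise NotImplementedError


class SGD(_Optimizer):
    def __init__(self, lr=0.01, momentum=0.0, nesterov=False):
        super().__init__(lr)
        self.momentum = momentum
        self.nesterov = nesterov

    def update(self, key, param, grad):
        if self.momentum == 0.0:
            param -= self.lr * grad
            return
        s = self._slot(key, param, ["v"])
        s["v"] = self.momentum * s["v"] - self.lr * grad
        if self.nesterov:
            param += self.momentum * s["v"] - self.lr * grad
        else:
            param += s["v"]


class Adam(_Optimizer):
    def __init__(self, lr=0.001, beta1=0.9, beta2=0.999, eps=1e-7, amsgrad=False):
        super().__init__(lr)
        self.beta1, self.beta2, self.eps, self.amsgrad = beta1, beta2, eps, amsgrad

    def update(self, key, param, grad):
        s = self._slot(key, param, ["m", "v", "vhat"])
        s["m"] = self.beta1 * s["m"] + (1 - self.beta1) * grad
        s["v"] = self.beta2 * s["v"] + (1 - self.beta2) * grad**2
        mhat = s["m"] / (1 - self.beta1**self.t)
        if self.amsgrad:
            s["vhat"] = np.maximum(s["vhat"], s["v"])
            vhat = s["vhat"] / (1 - self.beta2**self.t)
        else:
            vhat = s["v"] / (1 - self.beta2**self.t)
        param -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class NAdam(_Optimizer):
    def __init__(self, lr=0.001, beta1=0.9, beta2=0.999, eps=1e-7):
        super().__init__(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps

    def update(self, key, param, grad):
        s = self._slot(key, param, ["m", "v"])
        s["m"] = self.beta1 * s["m"] + (1 - self.beta1) * grad
        s["v"] = self.beta2 * s["v"] + (1 - self.beta2) * grad**2
        mhat = s["m"] / (1 - self.beta1 ** (self.t + 1))
        vhat = s["v"] / (1 - self.beta2**self.t)
        m_bar = self.beta1 * mhat + (1 - self.beta1) * grad / (
            1 - self.beta1**self.t
        )
        param -= self.lr * m_bar / (np.sqrt(vhat) + self.eps)


class AdaMax(_Optimizer):
    def __init__(self, lr=0.001, beta1=0.9, beta2=0.999, eps=1e-7):
        super().__init__(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps

    def update(self, key, param, grad):
        s = self._slot(key, param, ["m", "u"])
        s["m"] = self.beta1 * s["m"] + (1 - self.beta1) * grad
        s["u"] = np.maximum(self.beta2 * s["u"], np.abs(grad))
        param -= (
            self.lr / (1 - self.beta1**self.t) * s["m"] / (s["u"] + self.eps)
        )


class AdaGrad(_Optimizer):
    def __init__(self, lr=0.001, eps=1e-7, initial_accumulator=0.1):
        super().__init__(lr)
        self.eps = eps
        self.initial_accumulator = initial_accumulator

    def update(self, key, param, grad):
        if key not in self.state:
            self.state[key] = {
                "acc": np.full_like(param, self.initial_accumulator)
            }
        s = self.state[key]
        s["acc"] += grad**2
        param -= self.lr * grad / (np.sqrt(s["acc"]) + self.eps)


class AdaDelta(_Optimizer):
    def __init__(self, lr=0.001, rho=0.95, eps=1e-7):
        super().__init__(lr)
        self.rho, self.eps = rho, eps

    def update(self, key, param, grad):
        s = self._slot(key, param, ["acc", "delta_acc"])
        s["acc"] = self.rho * s["acc"] + (1 - self.rho) * grad**2
        step = (
            np.sqrt(s["delta_acc"] + self.eps)
            / np.sqrt(s["acc"] + self.eps)
            * grad
        )
        s["delta_acc"] = self.rho * s["delta_acc"] + (1 - self.rho) * step**2
        param -= self.lr * step


class RMSProp(_Optimizer):
    def __init__(self, lr=0.001, rho=0.9, eps=1e-7, centered=False):
        super().__init__(lr)
        self.rho, self.eps, self.centered = rho, eps, centered

    def update(self, key, param, grad):
        s = self._slot(key, param, ["ms", "mg"])
        s["ms"] = self.rho * s["ms"] + (1 - self.rho) * grad**2
        if self.centered:
            s["mg"] = self.rho * s["mg"] + (1 - self.rho) * grad
            denom = np.sqrt(s["ms"] - s["mg"] ** 2 + self.eps)
        else:
            denom = np.sqrt(s["ms"]) + self.eps
        param -= self.lr * grad / denom


class Ftrl(_Optimizer):
    """FTRL-proximal with power -0.5 learning-rate schedule, l1 = l2 = 0."""

    def __init__(self, lr=0.001, initial_accumulator=0.1, beta=0.0):
        super().__init__(lr)
        self.initial_accumulator = initial_accumulator
        self.beta = beta

    def update(self, key, param, grad):
        if key not in self.state:
            self.state[key] = {
                "n": np.full_like(param, self.initial_accumulator),
                "z": np.zeros_like(param),
            }
        s = self.state[key]
        n_new = s["n"] + grad**2
        sigma = (np.sqrt(n_new) - np.sqrt(s["n"])) / self.lr
        s["z"] += grad - sigma * param
        s["n"] = n_new
        param[...] = -s["z"] / ((self.beta + np.sqrt(s["n"])) / self.lr)


OPTIMIZER_FACTORIES = {
    "sgd": lambda: SGD(lr=0.01),
    "sgd_nesterov": lambda: SGD(lr=0.01, momentum=0.9, nesterov=True),
    "adam": lambda: Adam(),
    "adam_amsgrad": lambda: Adam(amsgrad=True),
    "nadam": lambda: NAdam(),
    "adamax": lambda: AdaMax(),
    "adagrad": lambda: AdaGrad(),
    "adadelta": lambda: AdaDelta(),
    "rmsprop": lambda: RMSProp(),
    "rmsprop_centered": lambda: RMSProp(centered=True),
    "ftrl": lambda: Ftrl(),
}


def get_optimizer(name: str) -> _Optimizer:
    try:
        return OPTIMIZER_FACTORIES[name]()
    except KeyError:
        raise ValueError(
            f"unknown optimizer {name!r}; choose from {sorted(OPTIMIZER_FACTORIES)}"
        ) from None
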