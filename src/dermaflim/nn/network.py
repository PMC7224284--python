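"""Sequential network container, weighted BCE loss and SGD-momentum training."""

from __future__ import annotations

import numpy as np

from .layers import Dropout, Layer

__all__ = ["Sequential", "bce_with_logits", "SGD", "sigmoid"]


def sigmoid(z):
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits, y, weights=None):
    """Class-weighted binary cross-entropy on logits.

    Returns (mean weighted loss, gradient d loss / d logits).
    """
    logits = np.asarray(logits, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=np.float64)
    # stable softplus(z) - y*z
    loss_i = np.maximum(logits, 0) - logits * y + np.log1p(np.exp(-np.abs(logits)))
    p = sigmoid(logits)
    n = y.size
    return float((w * loss_i).mean()), (w * (p - y) / n).astype(np.float32)


class Sequential:
    """A chain of layers ending in a single-logit head.

    ``forward`` returns the pre-sigmoid logit; ``predict_proba`` applies the
    sigmoid. Dropout layers are stochastic whenever ``stochastic=True``
    (training or Monte-Carlo inference) and identity otherwise.
    """

    def __init__(self, layers: list):
        self.layers = layers

    def dropout_layers(self):
        return [l for l in self.layers if isinstance(l, Dropout)]

    def set_dropout_rate(self, rate: float) -> None:
        for l in self.dropout_layers():
            l.rate = rate

    def forward(self, x, train: bool = False, stochastic: bool | None = None, rng=None):
        h = np.asarray(x, dtype=np.float32)
        stoch = train if stochastic is None else stochastic
        for layer in self.layers:
            if isinstance(layer, Dropout):
                h = layer.forward(h, train=stoch, rng=rng)
            else:
                h = layer.forward(h, train=train, rng=rng)
        return h.reshape(-1)

    def backward(self, dlogits):
        g = np.asarray(dlogits, dtype=np.float32).reshape(-1, 1)
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def predict_proba(self, x, mc_dropout: bool = False, rng=None):
        # Monte-Carlo dropout keeps only the dropout masks stochastic;
        # batch-norm and caching stay in inference mode.
        logits = self.forward(x, train=False, stochastic=mc_dropout, rng=rng)
        return sigmoid(logits)

    # -- weights ---------------------------------------------------------
    @staticmethod
    def _arrays(layer) -> list:
        buffers = layer.buffers() if hasattr(layer, "buffers") else []
        return layer.params() + buffers

    def get_weights(self) -> list:
        return [p.copy() for layer in self.layers for p in self._arrays(layer)]

    def set_weights(self, weights: list) -> None:
        i = 0
        for layer in self.layers:
            for p in self._arrays(layer):
                p[...] = weights[i]
                i += 1
        if i != len(weights):
            raise ValueError("weight list does not match architecture")

    def reinit(self, rng) -> None:
        """Draw a fresh random initialization for every parametric layer."""
        for layer in self.layers:
            if hasattr(layer, "reinit"):
                layer.reinit(rng)

    def save(self, path) -> None:
        np.savez(path, *self.get_weights())

    def load(self, path) -> None:
        with np.load(path) as data:
            self.set_weights([data[k] for k in data.files])


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, model: Sequential, lr: float = 0.01, momentum: float = 0.9):
        self.model = model
        self.lr = lr
        self.momentum = momentum
        self._vel = [np.zeros_like(p) for layer in model.layers for p in layer.params()]

    def step(self) -> None:
        i = 0
        for layer in self.model.layers:
            for p, g in zip(layer.params(), layer.grads()):
                self._vel[i] = self.momentum * self._vel[i] - self.lr * g
                p += self._vel[i]
                i += 1


class Adam:
    """Adam optimiser (per-parameter adaptive step sizes).

    Far more reliable than plain SGD when training small CNNs from random
    initialization, where raw gradient magnitudes differ by orders of
    magnitude between the convolutional stack and the head."""

    def __init__(self, model: Sequential, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.model = model
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        params = [p for layer in model.layers for p in layer.params()]
        self._m = [np.zeros_like(p) for p in params]
        self._v = [np.zeros_like(p) for p in params]
        self._t = 0

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        i = 0
        for layer in self.model.layers:
            for p, g in zip(layer.params(), layer.grads()):
                self._m[i] = b1 * self._m[i] + (1 - b1) * g
                self._v[i] = b2 * self._v[i] + (1 - b2) * g * g
                mhat = self._m[i] / (1 - b1**self._t)
                vhat = self._v[i] / (1 - b2**self._t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
                i += 1
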