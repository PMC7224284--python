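"""Minimal CNN building blocks with explicit backward and relevance passes.

Data layout is NCHW float32. Each layer caches what its backward pass needs
during ``forward`` and additionally exposes ``relevance``, the deep Taylor /
LRP propagation step used for interpretability:

* ``zplus`` — positive-weight rule for hidden layers (relevance stays
  non-negative, conserved exactly on bias-free layers),
* ``zb``    — bounded-input rule for the first parametric layer, using the
  known [0, 1] input range,
* max-pooling routes relevance winner-take-all, average-pooling and the
  global pool distribute it proportionally to the (non-negative) inputs,
* ReLU, dropout and reshapes pass relevance through unchanged.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2D",
    "Dense",
    "ReLU",
    "MaxPool2D",
    "AvgPool2D",
    "GlobalAvgPool",
    "Flatten",
    "Dropout",
    "DenseBlock",
]


class Layer:
    """Base layer: stateless unless it has parameters."""

    def params(self) -> list:
        return []

    def grads(self) -> list:
        return []

    def forward(self, x, train: bool = False, rng=None):
        raise NotImplementedError

    def backward(self, gy):
        raise NotImplementedError

    def relevance(self, R, rule: str = "zplus"):
        raise NotImplementedError


def _safe_div(num, den):
    out = np.zeros_like(num)
    np.divide(num, den, out=out, where=den != 0)
    return out


class Conv2D(Layer):
    """3x3 (or kxk) same-padding convolution via im2col."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, bias: bool = True, rng=None):
        rng = rng or np.random.default_rng()
        fan_in = c_in * k * k
        self.W = (rng.standard_normal((c_out, c_in, k, k)) * np.sqrt(2.0 / fan_in)).astype(
            np.float32
        )
        self.b = np.zeros(c_out, dtype=np.float32) if bias else None
        self.k = k
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b) if bias else None
        self._x = None
        self._cols = None

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def grads(self):
        return [self.gW] + ([self.gb] if self.gb is not None else [])

    def reinit(self, rng):
        fan_in = self.W.shape[1] * self.k * self.k
        self.W[...] = (rng.standard_normal(self.W.shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)
        if self.b is not None:
            self.b[...] = 0.0

    def _im2col(self, x):
        n, c, h, w = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        # (n, c, h, w, k, k) -> (n*h*w, c*k*k)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * self.k * self.k)
        return np.ascontiguousarray(cols)

    def _col2im(self, gcols, shape):
        n, c, h, w = shape
        p = self.k // 2
        gxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        g = gcols.reshape(n, h, w, c, self.k, self.k)
        for dy in range(self.k):
            for dx in range(self.k):
                gxp[:, :, dy : dy + h, dx : dx + w] += g[:, :, :, :, dy, dx].transpose(
                    0, 3, 1, 2
                )
        return gxp[:, :, p : p + h, p : p + w]

    def _apply(self, x, W, b=None):
        n, c, h, w = x.shape
        cols = self._im2col(x)
        y = cols @ W.reshape(W.shape[0], -1).T
        if b is not None:
            y += b
        return y.reshape(n, h, w, W.shape[0]).transpose(0, 3, 1, 2), cols

    def _apply_T(self, s, W, shape):
        n, c, h, w = shape
        gcols = s.transpose(0, 2, 3, 1).reshape(n * h * w, W.shape[0]) @ W.reshape(
            W.shape[0], -1
        )
        return self._col2im(gcols, shape)

    def forward(self, x, train=False, rng=None):
        self._x = x
        y, cols = self._apply(x, self.W, self.b)
        self._cols = cols if train else None
        return y

    def backward(self, gy):
        n, co, h, w = gy.shape
        gyf = gy.transpose(0, 2, 3, 1).reshape(n * h * w, co)
        self.gW[...] = (gyf.T @ self._cols).reshape(self.W.shape)
        if self.b is not None:
            self.gb[...] = gyf.sum(axis=0)
        return self._apply_T(gy, self.W, self._x.shape)

    def relevance(self, R, rule="zplus"):
        x = self._x
        if rule == "zplus":
            Wp = np.maximum(self.W, 0.0)
            z, _ = self._apply(x, Wp)
            s = _safe_div(R, z)
            return x * self._apply_T(s, Wp, x.shape)
        if rule == "zb":  # input bounded to [0, 1]; lower bound 0 drops out
            Wn = np.minimum(self.W, 0.0)
            ones = np.ones_like(x)
            z = self._apply(x, self.W)[0] - self._apply(ones, Wn)[0]
            s = _safe_div(R, z)
            return x * self._apply_T(s, self.W, x.shape) - ones * self._apply_T(
                s, Wn, x.shape
            )
        raise ValueError(f"unknown relevance rule {rule!r}")


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, bias: bool = True, rng=None):
        rng = rng or np.random.default_rng()
        self.W = (rng.standard_normal((n_out, n_in)) * np.sqrt(2.0 / n_in)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32) if bias else None
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b) if bias else None
        self._x = None

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def grads(self):
        return [self.gW] + ([self.gb] if self.gb is not None else [])

    def reinit(self, rng):
        self.W[...] = (rng.standard_normal(self.W.shape) * np.sqrt(2.0 / self.W.shape[1])).astype(np.float32)
        if self.b is not None:
            self.b[...] = 0.0

    def forward(self, x, train=False, rng=None):
        self._x = x
        y = x @ self.W.T
        if self.b is not None:
            y += self.b
        return y

    def backward(self, gy):
        self.gW[...] = gy.T @ self._x
        if self.b is not None:
            self.gb[...] = gy.sum(axis=0)
        return gy @ self.W

    def relevance(self, R, rule="zplus"):
        x = self._x
        if rule == "zplus":
            Wp = np.maximum(self.W, 0.0)
            z = x @ Wp.T
            s = _safe_div(R, z)
            return x * (s @ Wp)
        if rule == "zb":
            Wn = np.minimum(self.W, 0.0)
            ones = np.ones_like(x)
            z = x @ self.W.T - ones @ Wn.T
            s = _safe_div(R, z)
            return x * (s @ self.W) - ones * (s @ Wn)
        raise ValueError(f"unknown relevance rule {rule!r}")


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy):
        return gy * self._mask

    def relevance(self, R, rule="zplus"):
        return R  # rectification already reflected in the cached activations


class MaxPool2D(Layer):
    """Non-overlapping max pooling; trailing rows/cols are cropped.

    Backward and relevance route to the window maximum (ties split
    evenly, which keeps the relevance sum conserved)."""

    def __init__(self, k: int = 2):
        self.k = k

    def forward(self, x, train=False, rng=None):
        k = self.k
        n, c, h, w = x.shape
        ho, wo = h // k, w // k
        self._in_shape = x.shape
        xc = x[:, :, : ho * k, : wo * k]
        self._xc = xc
        if k == 2:  # strided-view fast path
            out = np.maximum(
                np.maximum(xc[:, :, 0::2, 0::2], xc[:, :, 0::2, 1::2]),
                np.maximum(xc[:, :, 1::2, 0::2], xc[:, :, 1::2, 1::2]),
            )
        else:
            out = xc.reshape(n, c, ho, k, wo, k).max(axis=(3, 5))
        self._out = out
        return out

    def _scatter(self, vals):
        k = self.k
        n, c, h, w = self._in_shape
        ho, wo = h // k, w // k
        up = np.repeat(np.repeat(self._out, k, axis=2), k, axis=3)
        mask = (self._xc == up).astype(np.float32)
        cnt = mask.reshape(n, c, ho, k, wo, k).sum(axis=(3, 5))
        shared = vals / cnt
        out = np.zeros(self._in_shape, dtype=np.float32)
        out[:, :, : ho * k, : wo * k] = mask * np.repeat(
            np.repeat(shared, k, axis=2), k, axis=3
        )
        return out

    def backward(self, gy):
        return self._scatter(gy)

    def relevance(self, R, rule="zplus"):
        return self._scatter(R)  # winner-take-all routing


class AvgPool2D(Layer):
    """Non-overlapping average pooling (also the input downsampler)."""

    def __init__(self, k: int):
        self.k = k

    def forward(self, x, train=False, rng=None):
        k = self.k
        n, c, h, w = x.shape
        ho, wo = h // k, w // k
        self._in_shape = x.shape
        self._x = x
        return x[:, :, : ho * k, : wo * k].reshape(n, c, ho, k, wo, k).mean(axis=(3, 5))

    def backward(self, gy):
        k = self.k
        n, c, h, w = self._in_shape
        ho, wo = h // k, w // k
        out = np.zeros(self._in_shape, dtype=np.float32)
        out[:, :, : ho * k, : wo * k] = np.repeat(np.repeat(gy, k, axis=2), k, axis=3) / (
            k * k
        )
        return out

    def relevance(self, R, rule="zplus"):
        # proportional redistribution onto the (non-negative) pooled inputs
        k = self.k
        n, c, h, w = self._in_shape
        ho, wo = h // k, w // k
        xc = self._x[:, :, : ho * k, : wo * k]
        sums = xc.reshape(n, c, ho, k, wo, k).sum(axis=(3, 5))
        s = _safe_div(R, sums)
        out = np.zeros(self._in_shape, dtype=np.float32)
        out[:, :, : ho * k, : wo * k] = xc * np.repeat(np.repeat(s, k, axis=2), k, axis=3)
        return out


class GlobalAvgPool(Layer):
    def forward(self, x, train=False, rng=None):
        self._x = x
        return x.mean(axis=(2, 3))

    def backward(self, gy):
        n, c, h, w = self._x.shape
        return np.broadcast_to(gy[:, :, None, None], self._x.shape) / (h * w)

    def relevance(self, R, rule="zplus"):
        sums = self._x.sum(axis=(2, 3))
        s = _safe_div(R, sums)
        return self._x * s[:, :, None, None]


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gy):
        return gy.reshape(self._shape)

    def relevance(self, R, rule="zplus"):
        return R.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout; active in training and, when requested, at
    inference (Monte-Carlo dropout)."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self._mask = None

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("dropout in stochastic mode needs an rng")
        self._mask = (rng.random(x.shape) >= self.rate).astype(np.float32) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, gy):
        return gy if self._mask is None else gy * self._mask

    def relevance(self, R, rule="zplus"):
        return R  # dropout disabled during explanation


class BatchNorm2D(Layer):
    """Per-channel batch normalization with learnable scale and shift.

    Training uses batch statistics and maintains exponential running
    estimates; inference uses the running statistics, making the layer a
    per-channel affine map that relevance propagation folds into the
    preceding convolution.
    """

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.g_gamma = np.zeros_like(self.gamma)
        self.g_beta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.g_gamma, self.g_beta]

    def buffers(self):
        return [self.running_mean, self.running_var]

    def reinit(self, rng):
        self.gamma[...] = 1.0
        self.beta[...] = 0.0
        self.running_mean[...] = 0.0
        self.running_var[...] = 1.0

    def forward(self, x, train=False, rng=None):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean[...] = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var[...] = self.momentum * self.running_var + (1 - self.momentum) * var
            self._n = x.shape[0] * x.shape[2] * x.shape[3]
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps).astype(np.float32)
        self._xhat = (x - mean[None, :, None, None]) / self._std[None, :, None, None]
        return self.gamma[None, :, None, None] * self._xhat + self.beta[None, :, None, None]

    def backward(self, gy):
        xhat, std, n = self._xhat, self._std, self._n
        self.g_gamma[...] = (gy * xhat).sum(axis=(0, 2, 3))
        self.g_beta[...] = gy.sum(axis=(0, 2, 3))
        g = self.gamma[None, :, None, None]
        sum_gy = gy.sum(axis=(0, 2, 3), keepdims=True)
        sum_gy_xhat = (gy * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (g / std[None, :, None, None]) * (gy - sum_gy / n - xhat * sum_gy_xhat / n)

    def inference_scale_shift(self):
        """The (scale, shift) of the eval-mode affine map, for folding."""
        scale = self.gamma / np.sqrt(self.running_var + self.eps)
        shift = self.beta - self.running_mean * scale
        return scale, shift

    def relevance(self, R, rule="zplus"):
        raise NotImplementedError(
            "batch-norm relevance must be folded into the adjacent convolution"
        )


class DenseBlock(Layer):
    """Densely-connected convolutional block: concat(x, relu(bn(conv(x)))).

    The skip concatenation gives each subsequent block direct access to all
    earlier feature maps, the defining trait of densely-connected CNNs.
    For relevance propagation the batch-norm affine map is folded into the
    convolution weights before applying the z+/z^B rule.
    """

    def __init__(self, c_in: int, growth: int, rng=None, batch_norm: bool = True):
        self.conv = Conv2D(c_in, growth, k=3, rng=rng)
        self.bn = BatchNorm2D(growth) if batch_norm else None
        self.relu = ReLU()
        self.c_in = c_in

    def params(self):
        return self.conv.params() + (self.bn.params() if self.bn else [])

    def grads(self):
        return self.conv.grads() + (self.bn.grads() if self.bn else [])

    def buffers(self):
        return self.bn.buffers() if self.bn else []

    def reinit(self, rng):
        self.conv.reinit(rng)
        if self.bn is not None:
            self.bn.reinit(rng)

    def forward(self, x, train=False, rng=None):
        h = self.conv.forward(x, train, rng)
        if self.bn is not None:
            h = self.bn.forward(h, train, rng)
        new = self.relu.forward(h, train, rng)
        return np.concatenate([x, new], axis=1)

    def backward(self, gy):
        g_new = self.relu.backward(gy[:, self.c_in :])
        if self.bn is not None:
            g_new = self.bn.backward(g_new)
        return gy[:, : self.c_in] + self.conv.backward(g_new)

    def relevance(self, R, rule="zplus"):
        R_skip = R[:, : self.c_in]
        R_new = self.relu.relevance(R[:, self.c_in :], rule)
        if self.bn is None:
            return R_skip + self.conv.relevance(R_new, rule)
        # fold the eval-mode batch-norm into the conv weights (z-rules use
        # weights and the cached conv input only; biases are not propagated)
        scale, _ = self.bn.inference_scale_shift()
        orig_W = self.conv.W
        try:
            self.conv.W = orig_W * scale[:, None, None, None]
            R_conv = self.conv.relevance(R_new, rule)
        finally:
            self.conv.W = orig_W
        return R_skip + R_conv
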