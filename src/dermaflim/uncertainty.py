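"""Variational (Monte-Carlo) dropout uncertainty estimation.

Dropout is kept active at inference and the network is called repeatedly;
the per-call output probabilities approximate samples from a Bayesian
posterior predictive. The prediction is their mean and the uncertainty their
standard deviation (sample, n-1 denominator). The same per-call predictions
also yield confidence intervals for any downstream performance metric: the
metric is evaluated once per call and summarised as mean +/- SD and a
2.5-97.5 percentile interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn.layers import Dropout
from .nn.network import sigmoid

__all__ = ["DropoutEnsemble", "MetricInterval", "predict_with_dropout", "metric_confidence"]


@dataclass
class DropoutEnsemble:
    """Per-call probabilities of shape (n_calls, n_samples) with their
    mean and sample standard deviation over calls."""

    probabilities: np.ndarray
    mean: np.ndarray
    std: np.ndarray
    n_calls: int


@dataclass(frozen=True)
class MetricInterval:
    mean: float
    sd: float
    ci_low: float
    ci_high: float

    def __str__(self) -> str:  # publication-style "value +/- SD"
        return f"{self.mean:.3f} ± {self.sd:.3f}"


def predict_with_dropout(model, x, n_calls: int = 50, seed: int = 0) -> DropoutEnsemble:
    """Run ``n_calls`` stochastic forward passes with dropout active.

    ``x`` is a batch in NCHW layout. Deterministic for a fixed seed; with a
    dropout rate of 0 every call is identical and the ensemble SD is exactly
    zero.
    """
    if n_calls < 1:
        raise ValueError("n_calls must be >= 1")
    if not model.dropout_layers():
        raise ValueError("model has no dropout layer to sample")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD0]))
    # Layers before the first dropout are deterministic across calls, so
    # the backbone runs once and only the stochastic head is repeated.
    # Identical to n_calls full passes (the rng is consumed only by
    # dropout masks), just cheaper.
    split = next(
        i for i, layer in enumerate(model.layers) if isinstance(layer, Dropout)
    )
    h = np.asarray(x, dtype=np.float32)
    for layer in model.layers[:split]:
        h = layer.forward(h, train=False)
    probs = []
    for _ in range(n_calls):
        z = h
        for layer in model.layers[split:]:
            if isinstance(layer, Dropout):
                z = layer.forward(z, train=True, rng=rng)
            else:
                z = layer.forward(z, train=False)
        probs.append(sigmoid(z.reshape(-1)))
    probs = np.stack(probs)
    std = probs.std(axis=0, ddof=1) if n_calls > 1 else np.zeros(probs.shape[1])
    return DropoutEnsemble(
        probabilities=probs, mean=probs.mean(axis=0), std=std, n_calls=n_calls
    )


def metric_confidence(per_call_predictions, labels, metrics: dict) -> dict:
    """Metric confidence from the multiple model calls.

    Each metric in ``metrics`` (name -> callable(labels, predictions)) is
    evaluated once per dropout call; the per-call values are summarised as
    mean +/- sample SD and the 2.5-97.5 percentile interval.
    """
    per_call = np.asarray(per_call_predictions, dtype=float)
    if per_call.ndim != 2 or per_call.shape[0] < 2:
        raise ValueError("need per-call predictions of shape (n_calls >= 2, n_samples)")
    labels = np.asarray(labels)
    out = {}
    for name, fn in metrics.items():
        vals = np.array([fn(labels, per_call[c]) for c in range(per_call.shape[0])], dtype=float)
        lo, hi = np.percentile(vals, [2.5, 97.5])
        out[name] = MetricInterval(
            mean=float(vals.mean()),
            sd=float(vals.std(ddof=1)),
            ci_low=float(lo),
            ci_high=float(hi),
        )
    return out
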