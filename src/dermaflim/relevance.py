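"""Deep Taylor decomposition: pixel-wise relevance of the cascade's decision.

The classifier's pre-sigmoid logit for the predicted class is decomposed
into per-pixel contributions by propagating relevance backwards through the
network: the positive-weight (z+) rule in hidden layers and the
bounded-input (z^B) rule at the first parametric layer (channels live in
[0, 1]). Max-pooling routes relevance winner-take-all, average pooling
proportionally to its inputs; dropout is disabled during explanation.

On bias-free ReLU networks the propagation is conservative: the per-pixel
relevances sum to the explained logit. Layer biases absorb part of the
relevance; the resulting leakage is logged, never silently renormalised.

Rendering helpers turn a relevance map into the two publication views: a
semi-transparent heatmap over the AF-intensity image, and a per-modality RGB
composite (red = mean lifetime, green = a1/a2 ratio, blue = AF intensity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .nn.layers import Conv2D, Dense, DenseBlock
from .patches import MPTPatch

log = logging.getLogger(__name__)

__all__ = [
    "RelevanceMap",
    "deep_taylor_relevance",
    "propagate_relevance",
    "modality_contributions",
    "overlay_heatmap",
]

# fixed publication color assignment for the modality composite
_MODALITY_RGB = {1: 0, 2: 1, 0: 2}  # channel tau_m -> R, ratio -> G, intensity -> B


@dataclass
class RelevanceMap:
    """Per-pixel, per-channel relevance with conservation bookkeeping."""

    per_pixel: np.ndarray  # (H, W, 3), non-negative
    per_channel_total: np.ndarray  # (3,) channel-wise sums
    output_score: float  # the explained pre-sigmoid logit (magnitude)
    predicted_class: int  # 1 = positive (gate fired / AD), 0 = negative
    conservation_residual: float  # (sum relevance - output) / output


def propagate_relevance(model, x, input_rule: str = "zb") -> tuple:
    """Backward relevance pass through an already-forwarded model.

    ``x`` is one NCHW sample batch. Returns (relevance NCHW, explained
    logit magnitude, predicted class). The explained quantity is the logit
    evidence for the predicted class, so it is non-negative by construction
    (the head's sign is flipped for negative predictions).
    """
    logit = float(model.forward(x, train=False)[0])
    predicted = int(logit >= 0)
    head = model.layers[-1]
    if predicted == 0:
        # explain the evidence for the negative class: negate the head
        head.W = -head.W
        if head.b is not None:
            head.b = -head.b
        score = -logit
    else:
        score = logit
    try:
        model.forward(x, train=False)  # re-cache activations under the flip
        parametric = [l for l in model.layers if isinstance(l, (Conv2D, Dense, DenseBlock))]
        first_parametric = parametric[0] if parametric else None
        R = np.array([[max(score, 0.0)]], dtype=np.float32)
        for layer in reversed(model.layers):
            rule = "zplus"
            if layer is first_parametric and input_rule == "zb":
                rule = "zb"
            R = layer.relevance(R, rule=rule)
    finally:
        if predicted == 0:
            head.W = -head.W
            if head.b is not None:
                head.b = -head.b
    return R, score, predicted


def deep_taylor_relevance(model, patch, input_rule: str = "zb") -> RelevanceMap:
    """Explain the model's decision on one patch.

    Parameters
    ----------
    model : Sequential
        A trained cascade stage (dropout is bypassed during explanation).
    patch : MPTPatch or (H, W, 3) array
        The input to explain.
    input_rule : 'zb' or 'zplus'
        Rule applied at the first parametric layer; 'zb' exploits the known
        [0, 1] channel bounds.
    """
    pixels = patch.pixels if isinstance(patch, MPTPatch) else np.asarray(patch, np.float32)
    x = pixels.transpose(2, 0, 1)[None].astype(np.float32)
    R, score, predicted = propagate_relevance(model, x, input_rule)
    per_pixel = np.maximum(R[0].transpose(1, 2, 0), 0.0)
    total = float(per_pixel.sum())
    residual = (total - score) / score if score > 0 else 0.0
    if abs(residual) > 1e-3:
        log.info("relevance leakage: %.2f%% of the output absorbed by biases",
                 -100.0 * residual)
    return RelevanceMap(
        per_pixel=per_pixel,
        per_channel_total=per_pixel.sum(axis=(0, 1)),
        output_score=score,
        predicted_class=predicted,
        conservation_residual=float(residual),
    )


def modality_contributions(rmap: RelevanceMap, smooth_px: float = 5.0) -> np.ndarray:
    """Render per-modality relevance into the fixed RGB assignment.

    Red carries the mean-lifetime channel, green the a1/a2 ratio, blue the
    AF intensity. Each modality's relevance is smoothed (display only) and
    the composite normalised to the overall maximum; an all-zero map renders
    all black.
    """
    rgb = np.zeros_like(rmap.per_pixel)
    for chan, color in _MODALITY_RGB.items():
        rgb[..., color] = gaussian_filter(rmap.per_pixel[..., chan], smooth_px)
    peak = rgb.max()
    if peak > 0:
        rgb /= peak
    return rgb


def overlay_heatmap(patch, rmap: RelevanceMap, colormap: str = "inferno") -> np.ndarray:
    """AF-intensity grayscale base with a semi-transparent relevance overlay.

    The overlay alpha is proportional to the normalised relevance magnitude
    (summed over channels), so irrelevant regions show the raw intensity
    image and maximally relevant ones the full colormap."""
    import matplotlib

    pixels = patch.pixels if isinstance(patch, MPTPatch) else np.asarray(patch, np.float32)
    if pixels.shape[:2] != rmap.per_pixel.shape[:2]:
        raise ValueError("patch and relevance map shapes differ")
    base = np.repeat(pixels[..., :1], 3, axis=-1)  # grayscale AF intensity
    mag = rmap.per_pixel.sum(axis=-1)
    peak = mag.max()
    alpha = (mag / peak)[..., None] if peak > 0 else np.zeros_like(mag)[..., None]
    colors = matplotlib.colormaps[colormap](mag / peak if peak > 0 else mag)[..., :3]
    return (1.0 - alpha) * base + alpha * colors
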