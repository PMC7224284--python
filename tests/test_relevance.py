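"""Deep Taylor decomposition: conservation, closed forms, renderings."""

import numpy as np
import pytest

from dermaflim.nn import (
    SGD,
    AvgPool2D,
    Conv2D,
    Dense,
    DenseBlock,
    Dropout,
    Flatten,
    GlobalAvgPool,
    MaxPool2D,
    ReLU,
    Sequential,
    bce_with_logits,
)
from dermaflim.patches import MPTPatch
from dermaflim.relevance import (
    RelevanceMap,
    deep_taylor_relevance,
    modality_contributions,
    overlay_heatmap,
    propagate_relevance,
)


class TestClosedForm:
    def test_single_positive_linear_layer(self, rng):
        """For one bias-free layer with positive weights, the z+ rule gives
        R_i = w_i x_i / sum_j w_j x_j * output exactly."""
        layer = Dense(4, 1, bias=False, rng=rng)
        layer.W[...] = np.abs(layer.W)
        net = Sequential([Flatten(), layer])
        x = rng.random((1, 4, 1, 1)).astype(np.float32)
        R, score, _ = propagate_relevance(net, x, input_rule="zplus")
        w = layer.W.ravel()
        xf = x.ravel()
        expected = w * xf / (w * xf).sum() * score
        np.testing.assert_allclose(R.ravel(), expected, rtol=1e-5)
        assert R.sum() == pytest.approx(score, rel=1e-6)

    def test_all_zero_input_gives_zero_relevance(self, rng):
        net = Sequential([Flatten(), Dense(4, 1, bias=False, rng=rng)])
        x = np.zeros((1, 4, 1, 1), dtype=np.float32)
        R, _, _ = propagate_relevance(net, x, input_rule="zplus")
        assert np.all(R == 0)


def random_bias_free_net(rng):
    """A random bias-free conv/pool/ReLU network with a single-logit head."""
    layers = [
        Conv2D(3, 5, bias=False, rng=rng),
        ReLU(),
        MaxPool2D(2),
        Conv2D(5, 4, bias=False, rng=rng),
        ReLU(),
        GlobalAvgPool(),
        Dense(4, 1, bias=False, rng=rng),
    ]
    return Sequential(layers)


def test_conservation_on_random_bias_free_relu_nets():
    """Total input relevance equals the explained logit within 1e-4
    relative, over 20 random bias-free ReLU networks."""
    rng = np.random.default_rng(777)
    for _ in range(20):
        net = random_bias_free_net(rng)
        x = rng.random((1, 3, 12, 12)).astype(np.float32)
        R, score, _ = propagate_relevance(net, x, input_rule="zplus")
        if score == 0.0:
            continue
        assert R.sum() == pytest.approx(score, rel=1e-4)
        assert np.all(R >= 0)


def test_conservation_holds_for_negative_logits(rng):
    """When the prediction is the negative class, the propagated quantity is
    the (positive) evidence for that class."""
    found = False
    for _ in range(10):
        net = random_bias_free_net(rng)
        x = rng.random((1, 3, 12, 12)).astype(np.float32)
        logit = float(net.forward(x)[0])
        if logit < 0:
            R, score, predicted = propagate_relevance(net, x, input_rule="zplus")
            assert predicted == 0
            assert score == pytest.approx(-logit)
            assert R.sum() == pytest.approx(score, rel=1e-4)
            found = True
    assert found


def test_zb_rule_conserves_through_bounded_input(rng):
    net = Sequential(
        [
            Conv2D(3, 4, bias=False, rng=rng),
            ReLU(),
            GlobalAvgPool(),
            Dense(4, 1, bias=False, rng=rng),
        ]
    )
    x = rng.random((1, 3, 8, 8)).astype(np.float32)
    R, score, _ = propagate_relevance(net, x, input_rule="zb")
    if score > 0:
        assert R.sum() == pytest.approx(score, rel=1e-3)


def test_dense_block_relevance_conserves(rng):
    net = Sequential(
        [
            DenseBlock(3, 4, rng=rng, batch_norm=False),
            GlobalAvgPool(),
            Dense(7, 1, bias=False, rng=rng),
        ]
    )
    net.layers[0].conv.b[...] = 0.0
    x = rng.random((1, 3, 8, 8)).astype(np.float32)
    R, score, _ = propagate_relevance(net, x, input_rule="zplus")
    if score > 0:
        assert R.sum() == pytest.approx(score, rel=1e-4)


def _relevance_map(rng, per_pixel):
    per_pixel = np.asarray(per_pixel, dtype=np.float32)
    return RelevanceMap(
        per_pixel=per_pixel,
        per_channel_total=per_pixel.sum(axis=(0, 1)),
        output_score=float(per_pixel.sum()),
        predicted_class=1,
        conservation_residual=0.0,
    )


class TestModalityContributions:
    def test_intensity_only_renders_pure_blue(self, rng):
        per_pixel = np.zeros((32, 32, 3))
        per_pixel[..., 0] = rng.random((32, 32))  # all relevance on AF intensity
        rgb = modality_contributions(_relevance_map(rng, per_pixel), smooth_px=1.0)
        assert rgb[..., 2].max() > 0  # blue carries intensity
        assert rgb[..., 0].max() == 0 and rgb[..., 1].max() == 0

    def test_equal_channels_render_gray(self, rng):
        per_pixel = np.ones((16, 16, 3))
        rgb = modality_contributions(_relevance_map(rng, per_pixel), smooth_px=1.0)
        np.testing.assert_allclose(rgb[..., 0], rgb[..., 1])
        np.testing.assert_allclose(rgb[..., 1], rgb[..., 2])

    def test_channel_totals_keep_their_ratio(self, rng):
        per_pixel = np.zeros((16, 16, 3))
        per_pixel[..., 0] = 0.2
        per_pixel[..., 1] = 0.3
        per_pixel[..., 2] = 0.5
        rgb = modality_contributions(_relevance_map(rng, per_pixel), smooth_px=0.0)
        sums = rgb.sum(axis=(0, 1))
        # channel -> color: tau_m(1)->R, ratio(2)->G, intensity(0)->B
        np.testing.assert_allclose(sums / sums.sum(), [0.3, 0.5, 0.2], atol=1e-5)

    def test_all_zero_map_renders_black(self, rng):
        rgb = modality_contributions(_relevance_map(rng, np.zeros((8, 8, 3))))
        assert np.all(rgb == 0)


class TestOverlay:
    def _patch(self, rng):
        return MPTPatch(pixels=rng.random((200, 200, 3)).astype(np.float32))

    def test_zero_relevance_returns_base_image(self, rng):
        patch = self._patch(rng)
        rmap = _relevance_map(rng, np.zeros((200, 200, 3)))
        out = overlay_heatmap(patch, rmap)
        np.testing.assert_allclose(out, np.repeat(patch.pixels[..., :1], 3, axis=-1))

    def test_uniform_relevance_is_fully_colormapped(self, rng):
        patch = self._patch(rng)
        rmap = _relevance_map(rng, np.ones((200, 200, 3)))
        out = overlay_heatmap(patch, rmap)
        ref = out[0, 0]
        np.testing.assert_allclose(out, np.broadcast_to(ref, out.shape), atol=1e-6)

    def test_deterministic(self, rng):
        patch = self._patch(rng)
        rmap = _relevance_map(rng, rng.random((200, 200, 3)))
        np.testing.assert_array_equal(overlay_heatmap(patch, rmap), overlay_heatmap(patch, rmap))

    def test_shape_mismatch_rejected(self, rng):
        patch = self._patch(rng)
        with pytest.raises(ValueError):
            overlay_heatmap(patch, _relevance_map(rng, np.zeros((64, 64, 3))))


def test_relevance_localizes_class_evidence(rng):
    """On inputs whose class signal lives in one quadrant, a trained model's
    relevance mass concentrates there (>= 60%)."""
    layers = [
        AvgPool2D(2),
        DenseBlock(3, 4, rng=rng),
        MaxPool2D(2),
        GlobalAvgPool(),
        Dense(7, 4, rng=rng),
        ReLU(),
        Dropout(0.0),
        Dense(4, 1, rng=rng),
    ]
    net = Sequential(layers)
    n = 24
    X = rng.uniform(0, 0.2, (2 * n, 3, 40, 40)).astype(np.float32)
    y = np.array([1.0] * n + [0.0] * n, dtype=np.float32)
    X[:n, :, :20, :20] += 0.7  # signal quadrant for the positive class
    opt = SGD(net, lr=0.3, momentum=0.9)
    for _ in range(60):
        logits = net.forward(X, train=True, rng=rng)
        _, dlog = bce_with_logits(logits, y)
        net.backward(dlog)
        opt.step()
    acc = ((net.predict_proba(X) >= 0.5) == y.astype(bool)).mean()
    assert acc >= 0.95
    pos = X[:4]
    for i in range(4):
        rmap = deep_taylor_relevance(net, pos[i].transpose(1, 2, 0))
        total = rmap.per_pixel.sum()
        in_quadrant = rmap.per_pixel[:20, :20].sum()
        assert in_quadrant / total >= 0.60
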