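"""Grad-CAM localization: formula equivalence, gradients, and sanity."""

import numpy as np
import pytest

from cpcnn import _tensor as T
from cpcnn import nn
from cpcnn.backbone import TierConfig, build_tier
from cpcnn.weakloc import (
    LocalizationMap,
    compute_gradcam,
    localize,
    localize_batch,
    normalize_map,
)


def explicit_loop_gradcam(features, gradient):
    """Independent oracle: channel weights by explicit spatial-mean loops,
    then the weighted channel sum and ReLU, all element by element."""
    h, w, c = features.shape
    alphas = []
    for i in range(c):
        total = 0.0
        for yy in range(h):
            for xx in range(w):
                total += gradient[yy, xx, i]
        alphas.append(total / (h * w))
    out = np.zeros((h, w))
    for yy in range(h):
        for xx in range(w):
            s = 0.0
            for i in range(c):
                s += alphas[i] * features[yy, xx, i]
            out[yy, xx] = max(s, 0.0)
    return out


class TestComputeGradcam:
    def test_constant_gradient_scales_features(self, rng):
        f = rng.random((4, 6, 1))
        g = np.full((4, 6, 1), 0.5)
        assert np.allclose(compute_gradcam(f, g), 0.5 * f[..., 0])

    def test_negative_gradients_yield_zero_map(self, rng):
        f = rng.random((4, 4, 3))  # non-negative features
        g = -rng.random((4, 4, 3)) - 0.1
        assert np.all(compute_gradcam(f, g) == 0)

    def test_worked_two_channel_example(self):
        # alpha = (0.5, 0): the second channel's gradient averages to zero
        f = np.stack([[[1, 0], [0, 1]], [[0, 2], [0, 0]]], axis=-1)
        g = np.stack([[[0.5, 0.5], [0.5, 0.5]], [[1, -1], [1, -1]]], axis=-1)
        assert np.allclose(compute_gradcam(f, g), [[0.5, 0.0], [0.0, 0.5]])

    def test_matches_explicit_loop_oracle(self, rng):
        worst = 0.0
        for _ in range(100):
            h, w, c = rng.integers(1, 9, 3)
            f = rng.normal(size=(h, w, c))
            g = rng.normal(size=(h, w, c))
            worst = max(worst, np.abs(
                compute_gradcam(f, g) - explicit_loop_gradcam(f, g)).max())
        assert worst < 1e-5

    def test_linearity_in_features(self, rng):
        f = rng.random((5, 5, 4))
        g = rng.normal(size=(5, 5, 4))
        base = compute_gradcam(f, g)
        assert np.allclose(compute_gradcam(3.0 * f, g), 3.0 * base, atol=1e-5)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="differ"):
            compute_gradcam(rng.random((4, 4, 2)), rng.random((4, 4, 3)))


class TestLocalizationMap:
    def test_all_zero_map_normalizes_to_zero(self):
        loc = LocalizationMap.from_native(np.zeros((5, 10)), (20, 40))
        assert np.all(loc.values == 0)

    def test_peak_invariant_under_upsampling(self, rng):
        # a distinct peak (clearly above the noise floor) must stay within
        # one native-cell radius after 8x bilinear upsampling
        for _ in range(10):
            native = 0.5 * rng.random((4, 8)).astype(np.float32)
            ny, nx = rng.integers(0, 4), rng.integers(0, 8)
            native[ny, nx] = 1.0
            loc = LocalizationMap.from_native(native, (32, 64))
            py, px = loc.peak
            assert abs(py / 8 - ny) <= 1.0 and abs(px / 8 - nx) <= 1.0

    def test_native_normalization_contract(self, rng):
        native = rng.random((5, 10)) + 0.1
        norm = normalize_map(native)
        assert norm.max() == pytest.approx(1.0, abs=1e-6)
        assert norm.min() >= 0.0
        loc = LocalizationMap.from_native(native, (10, 20))
        assert loc.values.min() >= 0.0 and loc.values.max() <= 1.0


class TestLocalize:
    def test_localize_returns_image_sized_normalized_map(self, rng):
        net = build_tier(TierConfig("primary").tiny()).eval()
        loc, scores = localize(net, rng.random((80, 160), dtype=np.float32))
        assert loc.values.shape == (80, 160)
        assert loc.values.min() >= 0 and loc.values.max() <= 1
        assert scores.probabilities.shape == (1, 2)

    def test_forced_class_index_recorded(self, rng):
        net = build_tier(TierConfig("primary").tiny()).eval()
        maps, _ = localize_batch(net, rng.random((2, 32, 64), dtype=np.float32),
                                 class_index=1)
        assert all(m.class_index == 1 for m in maps)

    def test_secondary_tier_rejected(self):
        net = build_tier(TierConfig("secondary").tiny())
        with pytest.raises(ValueError, match="classification head"):
            localize(net, np.zeros((32, 64), np.float32))

    def test_toy_classifier_peak_inside_bright_square(self):
        """A two-conv classifier trained to detect a bright square should
        place its Grad-CAM peak inside the square."""
        rng = np.random.default_rng(0)
        n, h, w = 40, 16, 32
        images = rng.normal(0.2, 0.05, (n, h, w, 1)).astype(np.float32)
        labels = np.array([i % 2 for i in range(n)])
        squares = []
        for i in range(n):
            if labels[i]:
                y0, x0 = rng.integers(2, h - 6), rng.integers(2, w - 6)
                images[i, y0:y0 + 4, x0:x0 + 4, 0] += 0.8
                squares.append((y0, x0))
            else:
                squares.append(None)
        conv1 = nn.Conv2d(1, 4, 3, padding=1, rng=np.random.default_rng(1))
        conv2 = nn.Conv2d(4, 4, 3, padding=1, rng=np.random.default_rng(2))
        head = nn.Linear(4, 2, rng=np.random.default_rng(3))
        params = list(conv1.parameters()) + list(conv2.parameters()) + list(head.parameters())
        opt = nn.SGD(params, lr=0.1, momentum=0.9)

        def forward(x):
            feat = T.relu(conv2(T.relu(conv1(x))))
            return feat, head(T.gap2d(feat))

        for _ in range(60):
            feat, logits = forward(T.Tensor(images))
            loss, _ = T.softmax_cross_entropy(logits, labels)
            loss.backward()
            opt.step()
        assert float(loss.data) < 0.2

        hits = 0
        positives = [i for i in range(n) if labels[i]]
        for i in positives:
            x = T.Tensor(images[i:i + 1])
            feat, logits = forward(x)
            seed = np.zeros((1, 2), np.float32)
            seed[0, 1] = 1.0
            logits.backward(seed)
            cam = compute_gradcam(feat.data[0], feat.grad[0])
            py, px = np.unravel_index(cam.argmax(), cam.shape)
            y0, x0 = squares[i]
            if y0 - 1 <= py <= y0 + 4 and x0 - 1 <= px <= x0 + 4:
                hits += 1
        assert hits / len(positives) >= 0.8


def double_precision_tail(net):
    """Independent float64 reimplementation of the tier tail from the
    ``block_3`` tap to the injury logit (block_4 bottleneck in evaluation
    mode, global average pooling, linear head), reading the same weights
    but sharing no code with the engine's convolution path."""
    unit = net.block_4.layers[0]
    fc = net.fc

    def conv1x1(x, w):
        return np.einsum("nhwc,co->nhwo", x, w[0, 0].astype(np.float64))

    def conv3x3_s2(x, w):
        n, h, wd, c = x.shape
        xp = np.zeros((n, h + 2, wd + 2, c))
        xp[:, 1:-1, 1:-1, :] = x
        oh, ow = (h + 2 - 3) // 2 + 1, (wd + 2 - 3) // 2 + 1
        out = np.zeros((n, oh, ow, w.shape[-1]))
        for ki in range(3):
            for kj in range(3):
                out += np.einsum(
                    "nhwc,co->nhwo",
                    xp[:, ki:ki + 2 * oh:2, kj:kj + 2 * ow:2, :],
                    w[ki, kj].astype(np.float64),
                )
        return out

    def bn(x, m):
        scale = (m.gamma.data / np.sqrt(m.running_var + m.eps)).astype(np.float64)
        shift = (m.beta.data - m.running_mean * scale).astype(np.float64)
        return x * scale + shift

    def logit(v):
        y = np.maximum(bn(conv1x1(v, unit.conv1.weight.data), unit.bn1), 0)
        y = np.maximum(bn(conv3x3_s2(y, unit.conv2.weight.data), unit.bn2), 0)
        y = bn(conv1x1(y, unit.conv3.weight.data), unit.bn3)
        s = bn(conv1x1(v[:, ::2, ::2, :], unit.short_conv.weight.data),
               unit.short_bn)
        z = np.maximum(y + s, 0)
        g = z.mean(axis=(1, 2))
        return (g @ fc.weight.data.T.astype(np.float64) + fc.bias.data)[0, 1]

    return logit


class TestHookGradient:
    def test_autodiff_matches_finite_differences_at_hook(self, rng):
        """d(logit_1)/d(block_3 tap) via the tape vs double-precision
        central differences through an independent tail implementation."""
        cfg = TierConfig("primary", width_multiplier=0.25,
                         block_repeats=(1, 1, 1, 1), gradcam_hook="block_3")
        net = build_tier(cfg).eval()
        x = rng.random((1, 32, 64, 1), dtype=np.float32)
        _, scores = net.forward(T.Tensor(x))
        seed = np.zeros((1, 2), np.float32)
        seed[0, 1] = 1.0
        scores.logits.backward(seed)
        tap = net.hook_tensor("block_3")
        grad = tap.grad.astype(np.float64)
        base = tap.data.astype(np.float64)
        logit = double_precision_tail(net)

        eps = 1e-5
        for pos in [tuple(rng.integers(0, s) for s in base.shape)
                    for _ in range(12)]:
            plus, minus = base.copy(), base.copy()
            plus[pos] += eps
            minus[pos] -= eps
            fd = (logit(plus) - logit(minus)) / (2 * eps)
            assert float(grad[pos]) == pytest.approx(fd, rel=1e-3, abs=1e-6)
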