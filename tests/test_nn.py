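"""NumPy NN engine: gradient correctness, shapes, optimization sanity."""

import numpy as np
import pytest
from scipy import ndimage
from scipy.ndimage import gaussian_filter

from cellstack3d import nn
from cellstack3d.models import (
    build_depth_classifier,
    build_encoder_decoder,
    build_resnet_detector,
)


def _numeric_grad_check(model, x, y, loss_fn, rng, n_probes=6, eps=1e-4, tol=2e-3):
    # float64 probes keep finite differences clear of float32 rounding,
    # and the small eps keeps them clear of ReLU kinks
    x = x.astype(np.float64)
    out = model.forward(x)
    _, g = loss_fn(out, y)
    for p in model.params():
        p.grad[...] = 0.0
    model.backward(g)
    for p in model.params():
        v = p.value
        for _ in range(n_probes):
            idx = tuple(rng.integers(0, s) for s in v.shape)
            old = v[idx]
            v[idx] = old + eps
            lp = loss_fn(model.forward(x), y)[0]
            v[idx] = old - eps
            lm = loss_fn(model.forward(x), y)[0]
            v[idx] = old
            num = (lp - lm) / (2 * eps)
            assert p.grad[idx] == pytest.approx(num, abs=tol, rel=tol)


class TestGradients:
    def test_conv_dense_softmax(self, rng):
        g = np.random.Generator(np.random.PCG64(0))
        model = nn.Sequential(
            nn.Conv2d(1, 4, stride=2, rng=g),
            nn.ReLU(),
            nn.Flatten(),
            nn.Dense(4 * 5 * 5, 7, rng=g),
        )
        x = rng.standard_normal((3, 1, 9, 9)).astype(np.float32)
        y = rng.integers(0, 7, 3)
        _numeric_grad_check(model, x, y, nn.softmax_cross_entropy, rng)

    @pytest.mark.parametrize("output_padding", [0, 1])
    def test_transposed_conv_mse(self, rng, output_padding):
        g = np.random.Generator(np.random.PCG64(1))
        model = nn.Sequential(
            nn.Conv2d(1, 3, stride=2, rng=g),
            nn.ReLU(),
            nn.ConvTranspose2d(3, 2, output_padding=output_padding, rng=g),
            nn.Sigmoid(),
        )
        x = rng.standard_normal((2, 1, 9, 9)).astype(np.float32)
        out = model.forward(x)
        y = rng.uniform(0.2, 0.8, out.shape).astype(np.float32)
        _numeric_grad_check(model, x, y, nn.mse_loss, rng)

    def test_residual_block_bce(self, rng):
        g = np.random.Generator(np.random.PCG64(2))
        model = nn.Sequential(
            nn.Conv2d(1, 3, rng=g),
            nn.ResidualBlock(3, rng=g),
            nn.Conv2d(3, 1, rng=g),
            nn.Sigmoid(),
        )
        x = rng.standard_normal((2, 1, 7, 7)).astype(np.float32)
        y = (rng.random((2, 1, 7, 7)) > 0.5).astype(np.float32)
        _numeric_grad_check(model, x, y, nn.bce_loss, rng)


class TestConvForward:
    def test_conv_matches_scipy_correlate(self, rng):
        """Independent oracle: stride-1 conv equals scipy correlation."""
        g = np.random.Generator(np.random.PCG64(3))
        conv = nn.Conv2d(2, 3, k=3, stride=1, pad=1, rng=g)
        x = rng.standard_normal((1, 2, 11, 11)).astype(np.float32)
        out = conv.forward(x)
        w = conv.w.value.reshape(3, 2, 3, 3)
        for f in range(3):
            expected = sum(
                ndimage.correlate(
                    x[0, c].astype(np.float64), w[f, c].astype(np.float64),
                    mode="constant",
                )
                for c in range(2)
            ) + conv.b.value[f]
            np.testing.assert_allclose(out[0, f], expected, rtol=1e-4, atol=1e-5)

    def test_transposed_conv_is_conv_adjoint(self, rng):
        """<conv(x), y> == <x, conv_T(y)> when weights are shared."""
        g = np.random.Generator(np.random.PCG64(4))
        conv = nn.Conv2d(1, 3, stride=2, rng=g)
        tconv = nn.ConvTranspose2d(3, 1, stride=2, output_padding=0, rng=g)
        tconv.w.value = conv.w.value.reshape(3, 9).copy()  # share kernels
        tconv.b.value[...] = 0.0
        conv.b.value[...] = 0.0
        x = rng.standard_normal((1, 1, 9, 9)).astype(np.float64)
        y = rng.standard_normal((1, 3, 5, 5)).astype(np.float64)
        lhs = float((conv.forward(x) * y).sum())
        rhs = float((x * tconv.forward(y)).sum())
        assert lhs == pytest.approx(rhs, rel=1e-5)


class TestArchitectures:
    @pytest.mark.parametrize(
        "builder,in_shape,out_shape",
        [
            (lambda: build_depth_classifier(0), (2, 1, 51, 51), (2, 20)),
            (lambda: build_encoder_decoder(1, 1, final_sigmoid=False), (2, 1, 51, 51), (2, 1, 51, 51)),
            (lambda: build_encoder_decoder(2, 4), (2, 2, 51, 51), (2, 4, 51, 51)),
            (lambda: build_resnet_detector(2, channels=6, n_blocks=1), (2, 2, 51, 51), (2, 4, 51, 51)),
        ],
    )
    def test_shapes(self, builder, in_shape, out_shape, rng):
        model = builder()
        out = model.forward(rng.standard_normal(in_shape).astype(np.float32))
        assert out.shape == out_shape

    def test_sigmoid_outputs_bounded(self, rng):
        model = build_encoder_decoder(1, 4)
        out = model.forward(rng.standard_normal((2, 1, 51, 51)).astype(np.float32))
        assert out.min() >= 0 and out.max() <= 1

    @pytest.mark.parametrize(
        "name", ["classifier", "encoder_decoder", "resnet"]
    )
    def test_capacity_overfits_16_samples(self, name, rng):
        """Each architecture can drive training loss near zero on 16 samples."""
        if name == "classifier":
            model = build_depth_classifier(0)
            x = rng.standard_normal((16, 1, 51, 51)).astype(np.float32)
            y = rng.integers(0, 20, 16)
            hist = nn.fit(model, x, y, nn.softmax_cross_entropy,
                          epochs=30, batch_size=8, lr=1e-3, seed=0)
            assert hist[-1] < 0.05
        elif name == "encoder_decoder":
            # smooth targets: the strided encoder is a bottleneck, so the
            # memorization check uses fields it can actually represent
            model = build_encoder_decoder(1, 1, channels=(8, 16, 32), final_sigmoid=False)
            x = np.stack(
                [gaussian_filter(rng.standard_normal((51, 51)), 4) for _ in range(16)]
            )[:, None].astype(np.float32)
            x /= x.std()
            y = (x * 0.5 + 0.1).astype(np.float32)
            hist = nn.fit(model, x, y, nn.mse_loss,
                          epochs=100, batch_size=8, lr=3e-3, seed=0)
            assert hist[-1] < 0.01
        else:
            model = build_resnet_detector(1, channels=8, n_blocks=1)
            x = np.stack(
                [gaussian_filter(rng.standard_normal((51, 51)), 4) for _ in range(16)]
            )[:, None].astype(np.float32)
            x /= x.std()
            y = (x > 0).repeat(4, axis=1).astype(np.float32)
            hist = nn.fit(model, x, y, nn.bce_loss,
                          epochs=40, batch_size=8, lr=3e-3, seed=0)
            assert hist[-1] < 0.1

    def test_training_reproducible(self, rng):
        x = rng.standard_normal((32, 1, 51, 51)).astype(np.float32)
        y = rng.integers(0, 20, 32)
        runs = []
        for _ in range(2):
            model = build_depth_classifier(7)
            nn.fit(model, x, y, nn.softmax_cross_entropy,
                   epochs=2, batch_size=8, lr=1e-3, seed=7)
            runs.append([p.value.copy() for p in model.params()])
        for a, b in zip(*runs):
            np.testing.assert_array_equal(a, b)

    def test_loss_decreases(self, rng):
        model = build_depth_classifier(0)
        x = rng.standard_normal((64, 1, 51, 51)).astype(np.float32)
        y = rng.integers(0, 2, 64) * 19
        hist = nn.fit(model, x, y, nn.softmax_cross_entropy,
                      epochs=8, batch_size=16, lr=1e-3, seed=0)
        assert hist[-1] < hist[0]
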