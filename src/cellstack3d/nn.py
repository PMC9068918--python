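"""Minimal NumPy neural-network engine.

Implements exactly the pieces the reconstruction networks need:
strided convolution (im2col + GEMM), transposed convolution
(zero-stuffing + convolution), dense layers, ReLU/sigmoid, residual
blocks, the three task losses and an Adam optimizer, all with manual
backpropagation in float32.  Layouts follow the NCHW convention.

Everything is seeded through explicit ``numpy.random.Generator``
instances, so training is bit-reproducible on a given platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32


@dataclass
class Param:
    value: np.ndarray
    grad: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.grad = np.zeros_like(self.value)


# ---------------------------------------------------------------------------
# conv primitives (shared by Conv2d and ConvTranspose2d)


def _conv_fwd(x, w, b, stride, pad):
    """x: (N,C,H,W); w: (F, C*k*k); pad: ((pt,pb),(pl,pr)).

    Patches are kept in (N, C*k*k, oh*ow) layout so both the forward
    GEMM and the backward scatter stay contiguous.
    """
    n, c, _, _ = x.shape
    k = int(np.sqrt(w.shape[1] // c))
    xp = np.pad(x, ((0, 0), (0, 0), pad[0], pad[1]))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    oh, ow = win.shape[2], win.shape[3]
    cols = np.ascontiguousarray(win.transpose(0, 1, 4, 5, 2, 3)).reshape(
        n, c * k * k, oh * ow
    )
    out = np.matmul(w, cols) + b[:, None]  # (N, F, oh*ow)
    return out.reshape(n, -1, oh, ow), cols, (oh, ow, k)


def _conv_bwd(gout, w, cols, x_shape, stride, pad, dims):
    """Gradient of _conv_fwd w.r.t. x, w, b."""
    n, c, h, wdt = x_shape
    oh, ow, k = dims
    g = gout.reshape(n, gout.shape[1], oh * ow)
    dw = np.tensordot(g, cols, axes=([0, 2], [0, 2]))
    db = g.sum(axis=(0, 2))
    dcols = np.matmul(w.T, g).reshape(n, c, k, k, oh, ow)
    hp = h + pad[0][0] + pad[0][1]
    wp = wdt + pad[1][0] + pad[1][1]
    dxp = np.zeros((n, c, hp, wp), dtype=gout.dtype)
    for ki in range(k):
        for kj in range(k):
            dxp[
                :, :, ki : ki + stride * oh : stride, kj : kj + stride * ow : stride
            ] += dcols[:, :, ki, kj]
    dx = dxp[:, :, pad[0][0] : hp - pad[0][1], pad[1][0] : wp - pad[1][1]]
    return dx, dw, db


def _he_init(rng, fan_in, shape):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(F32)


# ---------------------------------------------------------------------------
# layers


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    def __init__(self, cin, cout, k=3, stride=1, pad=1, *, rng):
        self.cin, self.k, self.stride, self.pad = cin, k, stride, pad
        self.w = Param(_he_init(rng, cin * k * k, (cout, cin * k * k)))
        self.b = Param(np.zeros(cout, dtype=F32))

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        self._xshape = x.shape
        p = ((self.pad, self.pad), (self.pad, self.pad))
        out, self._cols, self._dims = _conv_fwd(x, self.w.value, self.b.value, self.stride, p)
        return out

    def backward(self, gout):
        p = ((self.pad, self.pad), (self.pad, self.pad))
        dx, dw, db = _conv_bwd(
            gout, self.w.value, self._cols, self._xshape, self.stride, p, self._dims
        )
        self.w.grad += dw
        self.b.grad += db
        return dx


class ConvTranspose2d(Layer):
    """Transposed convolution — the adjoint of a strided convolution.

    Forward scatters ``W^T x`` patches into the upsampled output
    (col2im); backward gathers patches from the output gradient (im2col)
    so every GEMM runs at the small, pre-upsampling spatial size.
    ``output_padding`` adds rows/columns on the bottom/right so odd input
    sizes (51 -> 26 -> 13 -> 7) round-trip exactly through the decoder.
    """

    def __init__(self, cin, cout, k=3, stride=2, pad=1, output_padding=0, *, rng):
        self.cout, self.k, self.stride, self.pad = cout, k, stride, pad
        self.op = output_padding
        # stored like the matching forward conv: (cin, cout*k*k)
        self.w = Param(_he_init(rng, cin * k * k, (cin, cout * k * k)))
        self.b = Param(np.zeros(cout, dtype=F32))

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        n, cin, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        oh = (h - 1) * s - 2 * p + k + self.op
        ow = (w - 1) * s - 2 * p + k + self.op
        self._x = x.reshape(n, cin, h * w)
        cols = np.matmul(self.w.value.T, self._x).reshape(n, self.cout, k, k, h, w)
        outp = np.zeros((n, self.cout, oh + 2 * p, ow + 2 * p), dtype=x.dtype)
        for ki in range(k):
            for kj in range(k):
                outp[:, :, ki : ki + s * h : s, kj : kj + s * w : s] += cols[:, :, ki, kj]
        out = outp[:, :, p : p + oh, p : p + ow]
        self._hw = (h, w)
        return out + self.b.value[None, :, None, None]

    def backward(self, gout):
        n = gout.shape[0]
        k, s, p = self.k, self.stride, self.pad
        h, w = self._hw
        gp = np.pad(gout, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(gp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        win = win[:, :, :h, :w]  # output_padding windows beyond the input grid
        cols = np.ascontiguousarray(win.transpose(0, 1, 4, 5, 2, 3)).reshape(
            n, self.cout * k * k, h * w
        )
        self.w.grad += np.tensordot(self._x, cols, axes=([0, 2], [0, 2]))
        self.b.grad += gout.sum(axis=(0, 2, 3))
        return np.matmul(self.w.value, cols).reshape(n, -1, h, w)


class Dense(Layer):
    def __init__(self, nin, nout, *, rng):
        self.w = Param(_he_init(rng, nin, (nout, nin)))
        self.b = Param(np.zeros(nout, dtype=F32))

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, gout):
        self.w.grad += gout.T @ self._x
        self.b.grad += gout.sum(axis=0)
        return gout @ self.w.value


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gout):
        return gout.reshape(self._shape)


class ReLU(Layer):
    def forward(self, x):
        self._m = x > 0
        return np.where(self._m, x, 0)

    def backward(self, gout):
        return np.where(self._m, gout, 0)


class Sigmoid(Layer):
    def forward(self, x):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._y

    def backward(self, gout):
        return gout * self._y * (1.0 - self._y)


class ResidualBlock(Layer):
    """Two 3x3 convolutions with an identity skip: y = relu(x + f(x))."""

    def __init__(self, channels, *, rng):
        self.c1 = Conv2d(channels, channels, rng=rng)
        self.r1 = ReLU()
        self.c2 = Conv2d(channels, channels, rng=rng)
        self.r2 = ReLU()

    def params(self):
        return self.c1.params() + self.c2.params()

    def forward(self, x):
        y = self.c2.forward(self.r1.forward(self.c1.forward(x)))
        return self.r2.forward(x + y)

    def backward(self, gout):
        g = self.r2.backward(gout)
        gy = self.c1.backward(self.r1.backward(self.c2.backward(g)))
        return g + gy


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, gout):
        for l in reversed(self.layers):
            gout = l.backward(gout)
        return gout


# ---------------------------------------------------------------------------
# losses: each returns (scalar loss, gradient w.r.t. the network output)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = -np.log(p[np.arange(n), labels] + 1e-12).mean()
    g = p
    g[np.arange(n), labels] -= 1.0
    return float(loss), (g / n).astype(F32)


def mse_loss(pred: np.ndarray, target: np.ndarray):
    d = pred - target
    return float(np.mean(d * d)), (2.0 * d / d.size).astype(F32)


def bce_loss(prob: np.ndarray, target: np.ndarray):
    """Binary cross-entropy on probabilities (sigmoid outputs)."""
    eps = 1e-7
    p = np.clip(prob, eps, 1.0 - eps)
    loss = float(-np.mean(target * np.log(p) + (1.0 - target) * np.log(1.0 - p)))
    g = ((p - target) / (p * (1.0 - p))) / p.size
    return loss, g.astype(F32)


# ---------------------------------------------------------------------------
# optimizer and training loop


class Adam:
    def __init__(self, params: list[Param], lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0


def fit(
    model: Sequential,
    x: np.ndarray,
    y: np.ndarray,
    loss_fn,
    *,
    epochs: int,
    batch_size: int,
    lr: float,
    seed: int,
    verbose: bool = False,
) -> list[float]:
    """Mini-batch Adam training; returns the per-epoch mean loss history."""
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    opt = Adam(model.params(), lr=lr)
    n = x.shape[0]
    history: list[float] = []
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            opt.zero_grad()
            out = model.forward(x[idx])
            loss, g = loss_fn(out, y[idx])
            model.backward(g)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
        if verbose:
            print(f"epoch {epoch + 1}/{epochs}  loss {history[-1]:.5f}")
    return history


def predict_batched(model: Sequential, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
    outs = [model.forward(x[i : i + batch_size]) for i in range(0, x.shape[0], batch_size)]
    return np.concatenate(outs, axis=0)
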