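"""Minimal CPU neural-network layers with explicit backpropagation.

Implements exactly the pieces the pipeline's three networks need — 3x3
convolutions (im2col/BLAS), batch normalization, ReLU, 2x2 max pooling,
global average pooling and dense layers — in numpy, so training runs on a
single core at float32 BLAS throughput.  Layers follow a forward/backward
protocol; ``Sequential`` chains them; parameters carry their own gradients.

Spatial tensors use channels-last (N, H, W, C) layout: im2col windows and
the col2im scatter in the convolution backward pass are then contiguous,
which is what makes CPU training fast enough for desk-scale experiments.

Determinism: given the same seed, input order and thread count, forward and
backward passes are bit-reproducible (pure numpy, no atomics).
"""

from __future__ import annotations

from typing import List, Sequence

import numpy as np


class Param:
    """A trainable tensor and its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    def params(self) -> List[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Conv2d(Layer):
    """kxk convolution with zero padding on (N, H, W, C) tensors."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int = 3,
        stride: int = 1,
        pad: int | None = None,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        rng = rng or np.random.default_rng()
        self.in_ch, self.out_ch, self.k, self.stride = in_ch, out_ch, kernel, stride
        self.pad = kernel // 2 if pad is None else pad
        fan_in = in_ch * kernel * kernel
        # weight rows follow the im2col window layout: (k, k, in_ch)
        self.W = Param(_he_init(rng, (fan_in, out_ch), fan_in, dtype))
        self.b = Param(np.zeros(out_ch, dtype=dtype))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=True):
        from ._kernels import im2col

        p, k, s = self.pad, self.k, self.stride
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        n, hp, wp, c = xp.shape
        ho = (hp - k) // s + 1
        wo = (wp - k) // s + 1
        col = im2col(xp, ho, wo, k, s)
        self._col, self._xp_shape, self._dims = col, xp.shape, (n, ho, wo)
        out = col @ self.W.value + self.b.value
        return out.reshape(n, ho, wo, self.out_ch)

    def backward(self, dout):
        from ._kernels import col2im

        n, ho, wo = self._dims
        k, s, p = self.k, self.stride, self.pad
        _, hp, wp, c = self._xp_shape
        dflat = dout.reshape(n * ho * wo, self.out_ch)
        self.W.grad += self._col.T @ dflat
        self.b.grad += dflat.sum(axis=0)
        dcol = dflat @ self.W.value.T
        dxp = col2im(dcol, self._xp_shape, ho, wo, k, s)
        self._col = None
        return dxp[:, p : hp - p, p : wp - p, :] if p else dxp


class BatchNorm2d(Layer):
    """Per-channel batch normalization over (N, H, W) with running statistics."""

    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1, dtype=np.float32):
        self.eps, self.momentum = eps, momentum
        self.gamma = Param(np.ones(ch, dtype=dtype))
        self.beta = Param(np.zeros(ch, dtype=dtype))
        self.run_mean = np.zeros(ch, dtype=np.float64)
        self.run_var = np.ones(ch, dtype=np.float64)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=True):
        shp = x.shape
        x2 = x.reshape(-1, shp[-1])
        if train:
            mean = x2.mean(axis=0)
            # E[x^2] - E[x]^2 via a BLAS reduction; clamp rounding residue
            sq = np.einsum("ic,ic->c", x2, x2) / x2.shape[0]
            var = np.maximum(sq - mean * mean, 0)
            m = self.momentum
            self.run_mean = (1 - m) * self.run_mean + m * mean.astype(np.float64)
            self.run_var = (1 - m) * self.run_var + m * var.astype(np.float64)
        else:
            mean = self.run_mean.astype(x.dtype)
            var = self.run_var.astype(x.dtype)
        inv = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
        xhat = (x2 - mean.astype(x.dtype)) * inv
        if train:
            self._xhat, self._inv, self._shape = xhat, inv, shp
        return (xhat * self.gamma.value + self.beta.value).reshape(shp)

    def backward(self, dout):
        xhat, inv = self._xhat, self._inv
        d2 = dout.reshape(-1, dout.shape[-1])
        self.gamma.grad += np.einsum("ic,ic->c", d2, xhat)
        self.beta.grad += d2.sum(axis=0)
        dxhat = d2 * self.gamma.value
        dx = (
            dxhat
            - dxhat.mean(axis=0)
            - xhat * (dxhat * xhat).mean(axis=0)
        ) * inv
        self._xhat = None
        return dx.astype(dout.dtype).reshape(self._shape)


class ReLU(Layer):
    def forward(self, x, train=True):
        self._m = x > 0
        return x * self._m

    def backward(self, dout):
        return dout * self._m


class MaxPool2d(Layer):
    """2x2 max pooling with stride 2 (trailing odd row/col dropped)."""

    def forward(self, x, train=True):
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        xt = x[:, : 2 * h2, : 2 * w2, :].reshape(n, h2, 2, w2, 2, c)
        out = xt.max(axis=(2, 4))
        self._mask = xt == out[:, :, None, :, None, :]
        self._shape = x.shape
        return out

    def backward(self, dout):
        n, h, w, c = self._shape
        h2, w2 = h // 2, w // 2
        d = self._mask * dout[:, :, None, :, None, :]
        # ties split the gradient evenly (rare with continuous activations)
        d = d / np.maximum(self._mask.sum(axis=(2, 4), keepdims=True), 1)
        dx = np.zeros(self._shape, dtype=dout.dtype)
        dx[:, : 2 * h2, : 2 * w2, :] = d.reshape(n, 2 * h2, 2 * w2, c)
        self._mask = None
        return dx


class GlobalAvgPool(Layer):
    """Adaptive average pooling to 1x1, flattened to (N, C)."""

    def forward(self, x, train=True):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout):
        n, h, w, c = self._shape
        return np.broadcast_to(
            dout[:, None, None, :] / (h * w), self._shape
        ).astype(dout.dtype).copy()


class Flatten(Layer):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng or np.random.default_rng()
        self.W = Param(_he_init(rng, (n_in, n_out), n_in, dtype))
        self.b = Param(np.zeros(n_out, dtype=dtype))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=True):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout):
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        dx = dout @ self.W.value.T
        self._x = None
        return dx


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train=True):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, dout):
        for l in reversed(self.layers):
            dout = l.backward(dout)
        return dout


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over the batch; returns (loss, dlogits)."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = len(labels)
    loss = float(-np.log(np.maximum(p[np.arange(n), labels], 1e-30)).mean())
    d = p.copy()
    d[np.arange(n), labels] -= 1.0
    return loss, (d / n).astype(logits.dtype)


class Adam:
    """Adam with (coupled) L2 weight decay added to the gradient."""

    def __init__(
        self,
        params: Sequence[Param],
        lr: float = 1e-3,
        betas=(0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = list(params)
        self.lr, self.eps, self.weight_decay = lr, eps, weight_decay
        self.b1, self.b2 = betas
        self.t = 0
        self.m = [np.zeros_like(p.value, dtype=np.float64) for p in self.params]
        self.v = [np.zeros_like(p.value, dtype=np.float64) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad.astype(np.float64)
            if self.weight_decay:
                g = g + self.weight_decay * p.value.astype(np.float64)
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            upd = self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            p.value -= upd.astype(p.value.dtype)
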