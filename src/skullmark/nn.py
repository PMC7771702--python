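"""Minimal CPU neural-network engine.

A small, deterministic numpy engine providing exactly the layers the
two-stage pipeline needs: 2-D convolution and transposed convolution,
batch normalisation, ReLU, a linear head, global average pooling, Adam,
and mean-squared-error loss.  Forward and backward passes are written
explicitly; convolutions are evaluated as k*k shifted channel matmuls
(BLAS-backed ``tensordot``), which is the fastest pure-numpy formulation
at the small widths used here.  Everything is float32 and every random
draw goes through an injected :class:`numpy.random.Generator`, so runs
are bit-reproducible given a seed.

Layout convention: activations are ``(N, C, H, W)``.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np

from .errors import InvalidInputError


class Param:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


class Layer:
    """Base layer: ``forward(x, train)`` caches what ``backward`` needs."""

    def params(self) -> List[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """k x k convolution, 'same'-style padding ``(k-1)//2`` unless given."""

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 pad: Optional[int] = None, rng: Optional[np.random.Generator] = None,
                 zero_init: bool = False):
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        self.pad = (k - 1) // 2 if pad is None else pad
        if zero_init:
            w = np.zeros((cout, cin, k, k), dtype=np.float32)
        else:
            rng = rng or np.random.default_rng(0)
            std = np.sqrt(2.0 / (cin * k * k))  # He initialisation
            w = (rng.standard_normal((cout, cin, k, k)) * std).astype(np.float32)
        self.W = Param(w)
        self.b = Param(np.zeros(cout, dtype=np.float32))
        self._xp: Optional[np.ndarray] = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=True):
        if x.shape[1] != self.cin:
            raise InvalidInputError(f"expected {self.cin} input channels, got {x.shape[1]}")
        N, _, H, Wd = x.shape
        p, s, k = self.pad, self.stride, self.k
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        Ho = (H + 2 * p - k) // s + 1
        Wo = (Wd + 2 * p - k) // s + 1
        acc = np.zeros((N, Ho, Wo, self.cout), dtype=np.float32)
        Wv = self.W.value
        for ki in range(k):
            for kj in range(k):
                xs = xp[:, :, ki:ki + s * Ho:s, kj:kj + s * Wo:s]
                acc += np.tensordot(xs, Wv[:, :, ki, kj], axes=([1], [1]))
        self._xp, self._xshape = xp, x.shape
        return np.ascontiguousarray(acc.transpose(0, 3, 1, 2)) + self.b.value[None, :, None, None]

    def backward(self, dy):
        xp = self._xp
        N, _, Ho, Wo = dy.shape
        p, s, k = self.pad, self.stride, self.k
        dyt = np.ascontiguousarray(dy.transpose(0, 2, 3, 1))
        self.b.grad += dy.sum(axis=(0, 2, 3))
        dxp = np.zeros_like(xp)
        Wv = self.W.value
        for ki in range(k):
            for kj in range(k):
                xs = xp[:, :, ki:ki + s * Ho:s, kj:kj + s * Wo:s]
                self.W.grad[:, :, ki, kj] += np.tensordot(
                    dyt, xs, axes=([0, 1, 2], [0, 2, 3]))
                g = np.tensordot(dyt, Wv[:, :, ki, kj], axes=([3], [0]))
                dxp[:, :, ki:ki + s * Ho:s, kj:kj + s * Wo:s] += g.transpose(0, 3, 1, 2)
        if p:
            H, Wd = self._xshape[2], self._xshape[3]
            return np.ascontiguousarray(dxp[:, :, p:p + H, p:p + Wd])
        return dxp


class ConvTranspose2d(Layer):
    """Stride-2 3x3 transposed convolution doubling the spatial size.

    Output size is ``(H-1)*stride - 2*pad + k + output_padding``; the
    defaults (k=3, stride=2, pad=1, output_padding=1) give exactly 2H.
    """

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 2,
                 pad: int = 1, output_padding: int = 1,
                 rng: Optional[np.random.Generator] = None):
        self.cin, self.cout, self.k = cin, cout, k
        self.stride, self.pad, self.opad = stride, pad, output_padding
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (cin * k * k))
        self.W = Param((rng.standard_normal((cin, cout, k, k)) * std).astype(np.float32))
        self.b = Param(np.zeros(cout, dtype=np.float32))

    def params(self):
        return [self.W, self.b]

    def out_size(self, n: int) -> int:
        return (n - 1) * self.stride - 2 * self.pad + self.k + self.opad

    def forward(self, x, train=True):
        if x.shape[1] != self.cin:
            raise InvalidInputError(f"expected {self.cin} input channels, got {x.shape[1]}")
        N, _, H, Wd = x.shape
        s, p, k = self.stride, self.pad, self.k
        Ho, Wo = self.out_size(H), self.out_size(Wd)
        canvas = np.zeros((N, self.cout, Ho + 2 * p, Wo + 2 * p), dtype=np.float32)
        Wv = self.W.value
        for ki in range(k):
            for kj in range(k):
                contrib = np.tensordot(x, Wv[:, :, ki, kj], axes=([1], [0]))
                canvas[:, :, ki:ki + s * H:s, kj:kj + s * Wd:s] += contrib.transpose(0, 3, 1, 2)
        self._x = x
        y = canvas[:, :, p:p + Ho, p:p + Wo] if p else canvas
        return np.ascontiguousarray(y) + self.b.value[None, :, None, None]

    def backward(self, dy):
        x = self._x
        N, _, H, Wd = x.shape
        s, p, k = self.stride, self.pad, self.k
        Ho, Wo = self.out_size(H), self.out_size(Wd)
        self.b.grad += dy.sum(axis=(0, 2, 3))
        dyp = np.zeros((N, self.cout, Ho + 2 * p, Wo + 2 * p), dtype=np.float32)
        dyp[:, :, p:p + Ho, p:p + Wo] = dy
        dx = np.zeros_like(x)
        Wv = self.W.value
        for ki in range(k):
            for kj in range(k):
                ds = dyp[:, :, ki:ki + s * H:s, kj:kj + s * Wd:s]
                self.W.grad[:, :, ki, kj] += np.tensordot(
                    x, ds, axes=([0, 2, 3], [0, 2, 3]))
                dx += np.tensordot(ds, Wv[:, :, ki, kj], axes=([1], [1])).transpose(0, 3, 1, 2)
        return dx


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.c, self.momentum, self.eps = c, momentum, eps
        self.gamma = Param(np.ones(c, dtype=np.float32))
        self.beta = Param(np.zeros(c, dtype=np.float32))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(np.float32)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std, train)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, dy):
        xhat, inv_std, train = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma.value[None, :, None, None]
        if not train:
            return dxhat * inv_std[None, :, None, None]
        N, _, H, W = dy.shape
        m = N * H * W
        sum_dxhat = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (inv_std[None, :, None, None] / m) * (
            m * dxhat - sum_dxhat - xhat * sum_dxhat_xhat)


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0).astype(np.float32)


class Linear(Layer):
    def __init__(self, din: int, dout: int, rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / din)
        self.W = Param((rng.standard_normal((dout, din)) * std).astype(np.float32))
        self.b = Param(np.zeros(dout, dtype=np.float32))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=True):
        self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, dy):
        self.W.grad += dy.T @ self._x
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value


class Flatten(Layer):
    """(N, C, H, W) -> (N, C*H*W)."""

    def forward(self, x, train=True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C)."""

    def forward(self, x, train=True):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        N, C, H, W = self._shape
        return np.broadcast_to(dy[:, :, None, None] / (H * W), self._shape).astype(np.float32).copy()


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train=True):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


# ---- loss and optimiser ------------------------------------------------

def mse_loss(pred: np.ndarray, target: np.ndarray) -> Tuple[float, np.ndarray]:
    """Mean squared error over every element; returns (loss, d loss/d pred)."""
    if pred.shape != target.shape:
        raise InvalidInputError(f"shape mismatch {pred.shape} vs {target.shape}")
    diff = pred.astype(np.float64) - target.astype(np.float64)
    loss = float(np.mean(diff**2))
    return loss, ((2.0 / diff.size) * diff).astype(np.float32)


class Adam:
    """Adam with the standard bias-corrected moments (lr default 0.001)."""

    def __init__(self, params: Sequence[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad * p.grad
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


# ---- (de)serialisation helpers ----------------------------------------

def flatten(layers: Sequence[Layer]) -> List[Layer]:
    """Recursively expand Sequential containers into atomic layers."""
    out: List[Layer] = []
    for l in layers:
        if isinstance(l, Sequential):
            out.extend(flatten(l.layers))
        else:
            out.append(l)
    return out


def get_state(layers: Sequence[Layer]) -> List[np.ndarray]:
    """Flat, ordered list of parameter and batch-norm running-stat arrays."""
    state: List[np.ndarray] = []
    for l in flatten(layers):
        for p in l.params():
            state.append(p.value.copy())
        if isinstance(l, BatchNorm2d):
            state.append(l.running_mean.copy())
            state.append(l.running_var.copy())
    return state


def set_state(layers: Sequence[Layer], state: Sequence[np.ndarray]) -> None:
    it = iter(state)
    for l in flatten(layers):
        for p in l.params():
            p.value = np.ascontiguousarray(next(it), dtype=np.float32)
        if isinstance(l, BatchNorm2d):
            l.running_mean = np.ascontiguousarray(next(it), dtype=np.float32)
            l.running_var = np.ascontiguousarray(next(it), dtype=np.float32)
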