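"""Minimal pure-numpy CNN building blocks with explicit backpropagation.

The toolkit's networks are small enough (tens of channels, 64--128 px
frames) that a compact numpy implementation trains them in minutes on one
CPU.  Convolutions are computed as nine shifted tensor contractions (one
per 3x3 tap) over a padded input, which keeps both the forward and the
backward pass allocation-light; every layer caches exactly what its
backward pass needs.

Gradient correctness is pinned down by finite-difference checks in the
test suite rather than by an autograd framework.
"""

from __future__ import annotations

import math
from typing import List, Optional, Tuple

import numpy as np

#: Working dtype for all layer math.  float32 is the training default;
#: tests switch to float64 for finite-difference gradient checks.
DTYPE = np.float32


class Param:
    """A learnable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


class Layer:
    def params(self) -> List[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    """2-D convolution, kernel 1 or 3, stride 1 or 2, 'same'-style padding."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3,
                 stride: int = 1, rng: Optional[np.random.Generator] = None,
                 bias: bool = True):
        if kernel not in (1, 3):
            raise ValueError("kernel must be 1 or 3")
        if stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * kernel * kernel
        std = math.sqrt(2.0 / fan_in)  # He init for (leaky) ReLU stacks
        self.w = Param(rng.normal(0.0, std, (out_ch, in_ch, kernel, kernel)))
        self.b = Param(np.zeros(out_ch)) if bias else None
        self.kernel = kernel
        self.stride = stride
        self.pad = kernel // 2
        self._xp: Optional[np.ndarray] = None
        self._xshape: Optional[Tuple[int, ...]] = None

    def params(self) -> List[Param]:
        return [self.w] + ([self.b] if self.b is not None else [])

    def _out_hw(self, h: int, w: int) -> Tuple[int, int]:
        k, s, p = self.kernel, self.stride, self.pad
        return (h + 2 * p - k) // s + 1, (w + 2 * p - k) // s + 1

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        k, s, p = self.kernel, self.stride, self.pad
        ho, wo = self._out_hw(h, w)
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        out = np.zeros((self.w.value.shape[0], n, ho, wo), dtype=DTYPE)
        for ki in range(k):
            for kj in range(k):
                view = xp[:, :, ki:ki + s * ho:s, kj:kj + s * wo:s]
                # (Co,Ci) x (N,Ci,Ho,Wo) -> (Co,N,Ho,Wo)
                out += np.tensordot(self.w.value[:, :, ki, kj], view,
                                    axes=([1], [1]))
        out = np.ascontiguousarray(out.transpose(1, 0, 2, 3))
        if self.b is not None:
            out += self.b.value[None, :, None, None]
        self._xp, self._xshape = xp, x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xp, (n, c, h, w) = self._xp, self._xshape
        k, s, p = self.kernel, self.stride, self.pad
        ho, wo = dout.shape[2], dout.shape[3]
        if self.b is not None:
            self.b.grad += dout.sum(axis=(0, 2, 3))
        dxp = np.zeros_like(xp)
        for ki in range(k):
            for kj in range(k):
                view = xp[:, :, ki:ki + s * ho:s, kj:kj + s * wo:s]
                # dW: (N,Co,Ho,Wo) x (N,Ci,Ho,Wo) -> (Co,Ci)
                self.w.grad[:, :, ki, kj] += np.tensordot(
                    dout, view, axes=([0, 2, 3], [0, 2, 3]))
                # dx: (Ci,Co) x (N,Co,Ho,Wo) -> (Ci,N,Ho,Wo)
                t = np.tensordot(self.w.value[:, :, ki, kj], dout,
                                 axes=([0], [1]))
                dxp[:, :, ki:ki + s * ho:s, kj:kj + s * wo:s] += \
                    t.transpose(1, 0, 2, 3)
        self._xp = None
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class BatchNorm2d(Layer):
    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Param(np.ones(ch))
        self.beta = Param(np.zeros(ch))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(ch, dtype=DTYPE)
        self.running_var = np.ones(ch, dtype=DTYPE)
        self._cache = None

    def params(self) -> List[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
        xhat = xhat.astype(DTYPE)
        self._cache = (xhat, invstd.astype(DTYPE), train)
        return self.gamma.value[None, :, None, None] * xhat + \
            self.beta.value[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, invstd, train = self._cache
        self._cache = None
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma.value[None, :, None, None]
        if not train:
            return dxhat * invstd[None, :, None, None]
        n, c, h, w = dout.shape
        m = n * h * w
        sum_d = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        sum_dx = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (invstd[None, :, None, None] / m) * \
            (m * dxhat - sum_d - xhat * sum_dx)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01):
        self.slope = slope
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        mask, self._mask = self._mask, None
        return np.where(mask, dout, self.slope * dout)


class UpsampleNearest2(Layer):
    """Nearest-neighbour x2 spatial upsampling."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h2, w2 = dout.shape
        return dout.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))


class ConvBNAct(Layer):
    """Convolution + batch normalisation + LeakyReLU, the recurring block."""

    def __init__(self, in_ch: int, out_ch: int, stride: int = 1,
                 rng: Optional[np.random.Generator] = None,
                 slope: float = 0.01):
        self.conv = Conv2d(in_ch, out_ch, kernel=3, stride=stride,
                           rng=rng, bias=False)
        self.bn = BatchNorm2d(out_ch)
        self.act = LeakyReLU(slope)

    def params(self) -> List[Param]:
        return self.conv.params() + self.bn.params()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.act.forward(
            self.bn.forward(self.conv.forward(x, train), train), train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return self.conv.backward(self.bn.backward(self.act.backward(dout)))


class Adam:
    """Adam optimiser over a flat parameter list."""

    def __init__(self, params: List[Param], lr: float = 1e-3,
                 betas: Tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.b1) * (p.grad - m)
            v += (1.0 - self.b2) * (p.grad ** 2 - v)
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
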