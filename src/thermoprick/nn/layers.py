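"""Minimal CPU neural-network layers with hand-written backpropagation.

All arrays are float32 in NCHW layout.  Each layer caches what its backward
pass needs during ``forward`` and returns the input gradient from
``backward``.  Randomness (weight init, dropout) is driven exclusively by
``numpy.random.Generator`` instances, so training is bitwise reproducible
for a fixed seed.

Convolutions use im2col + one BLAS GEMM per layer; the col2im scatter in the
backward pass is unrolled over the kernel offsets (k*k strided adds) instead
of per-pixel indexing, which keeps training on half-size forearm images
practical on a single core.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Parameter:
    __slots__ = ("value", "grad", "decay")

    def __init__(self, value: np.ndarray, decay: bool = True):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)
        # decay=False exempts biases and norm scales from weight decay
        self.decay = decay


class Layer:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> List[Parameter]:
        return []


def _he_init(rng: np.random.Generator, shape: Tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d(Layer):
    """3x3 (or kxk) convolution, stride 1, zero same-padding.

    Works on the zero-padded image's *flattened* pixel buffer: for each
    kernel offset the needed neighbours form one contiguous slice of that
    buffer, so the layer is k*k strided BLAS GEMMs with no im2col gather at
    all.  Because the padding lives inside the buffer, edge pixels see
    exact zeros — the decomposition is exact, not toroidal.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int = 3,
                 rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.pad = kernel // 2
        fan_in = in_channels * kernel * kernel
        self.weight = Parameter(
            _he_init(rng, (out_channels, in_channels, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32), decay=False)
        self._xp: Optional[np.ndarray] = None

    def _offsets(self, wp: int):
        k, p = self.kernel, self.pad
        for i in range(k):
            for j in range(k):
                yield i, j, (i - p) * wp + (j - p)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        p = self.pad
        hp, wp = h + 2 * p, w + 2 * p
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        xf = xp.reshape(n, c, hp * wp)
        out = np.zeros((n, self.out_channels, hp * wp), dtype=np.float32)
        length = hp * wp
        for i, j, off in self._offsets(wp):
            a, b = max(0, -off), length - max(0, off)
            out[:, :, a:b] += np.matmul(self.weight.value[:, :, i, j],
                                        xf[:, :, a + off:b + off])
        out = out.reshape(n, self.out_channels, hp, wp)[:, :, p:p + h, p:p + w]
        out = np.ascontiguousarray(out)
        out += self.bias.value[None, :, None, None]
        if train:
            self._xp = xf
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, _, h, w = dout.shape
        p = self.pad
        hp, wp = h + 2 * p, w + 2 * p
        length = hp * wp
        dpad = np.zeros((n, self.out_channels, hp, wp), dtype=np.float32)
        dpad[:, :, p:p + h, p:p + w] = dout
        df = dpad.reshape(n, self.out_channels, length)
        xf = self._xp
        dxf = np.zeros((n, self.in_channels, length), dtype=np.float32)
        for i, j, off in self._offsets(wp):
            a, b = max(0, -off), length - max(0, off)
            src = xf[:, :, a + off:b + off]
            dw = np.matmul(df[:, :, a:b], src.transpose(0, 2, 1))
            self.weight.grad[:, :, i, j] += dw.sum(axis=0)
            dxf[:, :, a + off:b + off] += np.matmul(
                self.weight.value[:, :, i, j].T, df[:, :, a:b])
        self.bias.grad += dout.sum(axis=(0, 2, 3))
        self._xp = None
        dxp = dxf.reshape(n, self.in_channels, hp, wp)
        return np.ascontiguousarray(dxp[:, :, p:p + h, p:p + w])

    def parameters(self) -> List[Parameter]:
        return [self.weight, self.bias]


class BatchNorm2d(Layer):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels, dtype=np.float32), decay=False)
        self.beta = Parameter(np.zeros(channels, dtype=np.float32), decay=False)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._xhat: Optional[np.ndarray] = None
        self._inv_std: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        xhat = xhat.astype(np.float32)
        if train:
            self._xhat = xhat
            self._inv_std = inv_std.astype(np.float32)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._xhat, self._inv_std
        n_eff = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma.value[None, :, None, None]
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        dx = (inv_std[None, :, None, None] / n_eff) * (
            n_eff * dxhat - s1 - xhat * s2
        )
        self._xhat = None
        return dx.astype(np.float32)

    def parameters(self) -> List[Parameter]:
        return [self.gamma, self.beta]


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01):
        self.slope = slope
        self._mask: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        mask = x > 0
        if train:
            self._mask = mask
        return np.where(mask, x, self.slope * x)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, self.slope * dout)


class ReLU(LeakyReLU):
    def __init__(self) -> None:
        super().__init__(slope=0.0)


class AvgPool2d(Layer):
    """Average pooling, no padding (kernel 3, stride 2 in the classifier)."""

    def __init__(self, kernel: int = 3, stride: int = 2):
        self.kernel = kernel
        self.stride = stride
        self._x_shape: Optional[Tuple[int, ...]] = None

    @staticmethod
    def out_size(n: int, kernel: int = 3, stride: int = 2) -> int:
        return (n - kernel) // stride + 1

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k, s = self.kernel, self.stride
        win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        if train:
            self._x_shape = x.shape
        return win.mean(axis=(4, 5)).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        k, s = self.kernel, self.stride
        n, c, ho, wo = dout.shape
        dx = np.zeros(self._x_shape, dtype=np.float32)
        g = dout / (k * k)
        for i in range(k):
            for j in range(k):
                dx[:, :, i:i + s * ho:s, j:j + s * wo:s] += g
        return dx


class MaxPool2x2(Layer):
    """2x2 max pooling with stride 2; input spatial dims must be even."""

    def __init__(self) -> None:
        self._idx: Optional[np.ndarray] = None
        self._x_shape: Optional[Tuple[int, ...]] = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2x2 requires even spatial dims")
        v = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        v = v.reshape(n, c, h // 2, w // 2, 4)
        idx = v.argmax(axis=-1)
        out = np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx = idx
            self._x_shape = x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._x_shape
        dv = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(dv, self._idx[..., None], dout[..., None], axis=-1)
        dv = dv.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dv.reshape(n, c, h, w)


class Upsample2x(Layer):
    """Nearest-neighbour x2 upsampling."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng()
        self.weight = Parameter(_he_init(rng, (out_features, in_features), in_features))
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32), decay=False)
        self._x: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.weight.grad += dout.T @ self._x
        self.bias.grad += dout.sum(axis=0)
        self._x = None
        return dout @ self.weight.value

    def parameters(self) -> List[Parameter]:
        return [self.weight, self.bias]


class Dropout(Layer):
    """Inverted dropout; identity in inference mode."""

    def __init__(self, p: float = 0.5, rng: Optional[np.random.Generator] = None):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng or np.random.default_rng()
        self._mask: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.p == 0.0:
            return x
        self._mask = (self.rng.random(x.shape) >= self.p).astype(np.float32) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        out = dout * self._mask
        self._mask = None
        return out


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def parameters(self) -> List[Parameter]:
        return [p for layer in self.layers for p in layer.parameters()]
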