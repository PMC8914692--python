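"""Minimal numpy neural-network layers with hand-written backpropagation.

Layers operate on ``(N, C, H, W)`` activations (or ``(N, D)`` for linear
layers) in float64.  Each module caches whatever its backward pass needs
during ``forward``; a module instance must therefore be applied exactly
once per forward pass before ``backward`` is called, which matches the
single-image, single-pass structure of the detector.
"""

from __future__ import annotations

import numpy as np


class Param:
    __slots__ = ("value", "grad", "m", "v", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)
        self.m = np.zeros_like(self.value)
        self.v = np.zeros_like(self.value)
        self.name = name


class Module:
    def params(self) -> list[Param]:
        out: list[Param] = []
        for attr in self.__dict__.values():
            if isinstance(attr, Param):
                out.append(attr)
            elif isinstance(attr, Module):
                out.extend(attr.params())
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        out.extend(item.params())
        return out

    def forward(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError

    def __call__(self, x):
        return self.forward(x)


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    """3x3 / 1x1 stride-1 convolution via im2col.

    ``pad`` defaults to "same" padding for odd kernels.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, pad: int | None = None):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.k = kernel_size
        self.pad = (kernel_size // 2) if pad is None else pad
        fan_in = in_channels * kernel_size * kernel_size
        self.W = Param(_he_init(rng, (out_channels, fan_in), fan_in))
        self.b = Param(np.zeros(out_channels))
        self._cols = None
        self._xshape = None

    def _im2col(self, x: np.ndarray) -> tuple[np.ndarray, int, int]:
        n, c, h, w = x.shape
        p, k = self.pad, self.k
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        ho, wo = win.shape[2], win.shape[3]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
        return np.ascontiguousarray(cols), ho, wo

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols, ho, wo = self._im2col(x)
        self._cols = cols
        self._xshape = x.shape
        out = cols @ self.W.value.T + self.b.value
        n = x.shape[0]
        return out.reshape(n, ho, wo, self.out_channels).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, co, ho, wo = dout.shape
        dmat = dout.transpose(0, 2, 3, 1).reshape(-1, co)
        self.W.grad += dmat.T @ self._cols
        self.b.grad += dmat.sum(axis=0)
        # dx as a full correlation of dout with the flipped, transposed kernel
        k = self.k
        Wt = self.W.value.reshape(co, self.in_channels, k, k)
        Wflip = Wt[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (Cin, Cout, k, k)
        pad_back = k - 1 - self.pad
        dp = np.pad(dout, ((0, 0), (0, 0), (pad_back, pad_back),
                           (pad_back, pad_back)))
        win = np.lib.stride_tricks.sliding_window_view(dp, (k, k), axis=(2, 3))
        hi, wi = win.shape[2], win.shape[3]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * hi * wi, co * k * k)
        dx = cols @ Wflip.reshape(self.in_channels, -1).T
        dx = dx.reshape(n, hi, wi, self.in_channels).transpose(0, 3, 1, 2)
        assert dx.shape == self._xshape
        return dx


class ReLU(Module):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2x2(Module):
    """2x2 max pooling with ceil-mode padding (-inf) for odd sizes."""

    def forward(self, x):
        n, c, h, w = x.shape
        self._in_shape = x.shape
        ph, pw = (-h) % 2, (-w) % 2
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)),
                       constant_values=-np.inf)
        ho, wo = x.shape[2] // 2, x.shape[3] // 2
        xr = x.reshape(n, c, ho, 2, wo, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, ho, wo, 4)
        self._arg = xr.argmax(axis=-1)
        self._padded_shape = (n, c, ho * 2, wo * 2)
        return xr.max(axis=-1)

    def backward(self, dout):
        n, c, ho, wo = dout.shape
        dxr = np.zeros((n, c, ho, wo, 4))
        np.put_along_axis(dxr, self._arg[..., None], dout[..., None], axis=-1)
        dx = dxr.reshape(n, c, ho, wo, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        dx = dx.reshape(self._padded_shape)
        h, w = self._in_shape[2], self._in_shape[3]
        return dx[:, :, :h, :w]


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator):
        self.W = Param(_he_init(rng, (out_features, in_features), in_features))
        self.b = Param(np.zeros(out_features))

    def forward(self, x):
        self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, dout):
        self.W.grad += dout.T @ self._x
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value


class GlobalAvgPool(Module):
    """(N, C, H, W) -> (N, C) spatial mean."""

    def forward(self, x):
        self._in_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._in_shape
        return np.broadcast_to(dout[:, :, None, None], self._in_shape) / (h * w)


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.modules = list(modules)

    def forward(self, x):
        for m in self.modules:
            x = m(x)
        return x

    def backward(self, dout):
        for m in reversed(self.modules):
            dout = m.backward(dout)
        return dout


class ResidualBlock(Module):
    """y = relu(x + conv(relu(conv(x)))) at constant channel width."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.conv1 = Conv2d(channels, channels, 3, rng)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(channels, channels, 3, rng)
        self.relu_out = ReLU()

    def forward(self, x):
        y = self.conv2(self.relu1(self.conv1(x)))
        return self.relu_out(x + y)

    def backward(self, dout):
        d = self.relu_out.backward(dout)
        dy = self.conv1.backward(self.relu1.backward(self.conv2.backward(d)))
        return d + dy


class Bottleneck(Module):
    """ResNet-style bottleneck: 1x1 reduce, 3x3, 1x1 expand, skip."""

    def __init__(self, in_channels: int, mid_channels: int, out_channels: int,
                 rng: np.random.Generator):
        self.conv1 = Conv2d(in_channels, mid_channels, 1, rng)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(mid_channels, mid_channels, 3, rng)
        self.relu2 = ReLU()
        self.conv3 = Conv2d(mid_channels, out_channels, 1, rng)
        self.proj = (Conv2d(in_channels, out_channels, 1, rng)
                     if in_channels != out_channels else None)
        self.relu_out = ReLU()

    def forward(self, x):
        y = self.conv3(self.relu2(self.conv2(self.relu1(self.conv1(x)))))
        skip = self.proj(x) if self.proj is not None else x
        return self.relu_out(skip + y)

    def backward(self, dout):
        d = self.relu_out.backward(dout)
        dy = self.conv1.backward(self.relu1.backward(self.conv2.backward(
            self.relu2.backward(self.conv3.backward(d)))))
        dskip = self.proj.backward(d) if self.proj is not None else d
        return dskip + dy


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class Adam:
    def __init__(self, params: list[Param], lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p in self.params:
            p.m = b1 * p.m + (1 - b1) * p.grad
            p.v = b2 * p.v + (1 - b2) * p.grad * p.grad
            mhat = p.m / (1 - b1 ** self.t)
            vhat = p.v / (1 - b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
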