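"""Minimal neural-network layer framework on numpy.

Each layer implements ``forward(x)`` (caching what its backward pass needs)
and ``backward(dout)`` returning the gradient w.r.t. its input while
accumulating parameter gradients. Convolutions are specialized: 1x1
convolutions are channel matmuls, depthwise convolutions iterate over kernel
taps with strided slicing, and the general case uses im2col. All arrays are
float64; shapes follow the (N, C, H, W) convention.
"""

from __future__ import annotations

import numpy as np

_GRAD_STACK = [True]


def grad_enabled() -> bool:
    return _GRAD_STACK[-1]


class no_grad:
    """Context manager: forward passes skip backward caches (saves memory)."""

    def __enter__(self):
        _GRAD_STACK.append(False)
        return self

    def __exit__(self, *exc):
        _GRAD_STACK.pop()
        return False


class Parameter:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("data", "grad", "trainable", "name")

    def __init__(self, data: np.ndarray, name: str = "", trainable: bool = True):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = np.zeros_like(self.data)
        self.trainable = trainable
        self.name = name

    @property
    def size(self) -> int:
        return self.data.size


class Module:
    """Base class: parameter discovery, train/eval mode, call = forward."""

    def __init__(self) -> None:
        self.training = True

    def modules(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item

    def parameters(self) -> list[Parameter]:
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        out.append(item)
        return out

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Parameter]]:
        out = []
        for k, v in self.__dict__.items():
            path = f"{prefix}{k}"
            if isinstance(v, Parameter):
                out.append((path, v))
            elif isinstance(v, Module):
                out.extend(v.named_parameters(path + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(f"{path}.{i}."))
                    elif isinstance(item, Parameter):
                        out.append((f"{path}.{i}", item))
        return out

    def train(self, flag: bool = True) -> "Module":
        self.training = flag
        for m in self.modules():
            m.train(flag)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def freeze(self) -> None:
        for p in self.parameters():
            p.trainable = False

    def n_parameters(self, trainable_only: bool = True) -> int:
        return sum(p.size for p in self.parameters()
                   if p.trainable or not trainable_only)

    def __call__(self, x):
        return self.forward(x)

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - abstract
        raise NotImplementedError


# ---------------------------------------------------------------- init helpers

def he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


# -------------------------------------------------------------------- layers

class Conv2d(Module):
    """2-D convolution (cross-correlation) with optional groups and bias.

    Weight shape is (out_channels, in_channels // groups, k, k). Three code
    paths: 1x1 stride-1 (matmul), depthwise (groups == in == out, tap loop),
    and general im2col (groups == 1).
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, groups: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError("channels must be divisible by groups")
        self.in_channels, self.out_channels = in_channels, out_channels
        self.k, self.stride, self.padding, self.groups = kernel_size, stride, padding, groups
        rng = rng or np.random.default_rng(0)
        fan_in = (in_channels // groups) * kernel_size ** 2
        self.weight = Parameter(
            he_normal(rng, (out_channels, in_channels // groups, kernel_size, kernel_size), fan_in))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self._cache = None

    @property
    def _depthwise(self) -> bool:
        return self.groups == self.in_channels == self.out_channels

    def _out_hw(self, h: int, w: int) -> tuple[int, int]:
        return ((h + 2 * self.padding - self.k) // self.stride + 1,
                (w + 2 * self.padding - self.k) // self.stride + 1)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {c}")
        if self.k == 1 and self.stride == 1 and self.padding == 0 and self.groups == 1:
            wmat = self.weight.data.reshape(self.out_channels, self.in_channels)
            y = np.einsum("oc,nchw->nohw", wmat, x, optimize=True)
            self._cache = ("pointwise", x) if grad_enabled() else None
        elif self._depthwise:
            xp = np.pad(x, ((0, 0), (0, 0), (self.padding,) * 2, (self.padding,) * 2))
            ho, wo = self._out_hw(h, w)
            y = np.zeros((n, c, ho, wo))
            s = self.stride
            for u in range(self.k):
                for v in range(self.k):
                    patch = xp[:, :, u:u + s * ho:s, v:v + s * wo:s]
                    y += patch * self.weight.data[:, 0, u, v][None, :, None, None]
            self._cache = ("depthwise", xp, x.shape) if grad_enabled() else None
        else:
            if self.groups != 1:
                raise NotImplementedError("grouped non-depthwise convolution")
            xp = np.pad(x, ((0, 0), (0, 0), (self.padding,) * 2, (self.padding,) * 2))
            ho, wo = self._out_hw(h, w)
            cols = np.empty((n, c * self.k * self.k, ho * wo))
            s = self.stride
            idx = 0
            for ci in range(c):
                for u in range(self.k):
                    for v in range(self.k):
                        cols[:, idx] = xp[:, ci, u:u + s * ho:s, v:v + s * wo:s].reshape(n, -1)
                        idx += 1
            wmat = self.weight.data.reshape(self.out_channels, -1)
            y = (wmat @ cols).reshape(n, self.out_channels, ho, wo)
            self._cache = ("im2col", cols, x.shape) if grad_enabled() else None
        if self.bias is not None:
            y += self.bias.data[None, :, None, None]
        return y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        kind = self._cache[0]
        if self.bias is not None:
            self.bias.grad += dout.sum(axis=(0, 2, 3))
        if kind == "pointwise":
            _, x = self._cache
            wmat = self.weight.data.reshape(self.out_channels, self.in_channels)
            self.weight.grad += np.einsum(
                "nohw,nchw->oc", dout, x, optimize=True).reshape(self.weight.data.shape)
            return np.einsum("oc,nohw->nchw", wmat, dout, optimize=True)
        if kind == "depthwise":
            _, xp, xshape = self._cache
            n, c, h, w = xshape
            ho, wo = dout.shape[2], dout.shape[3]
            s = self.stride
            dxp = np.zeros_like(xp)
            for u in range(self.k):
                for v in range(self.k):
                    patch = xp[:, :, u:u + s * ho:s, v:v + s * wo:s]
                    self.weight.grad[:, 0, u, v] += (dout * patch).sum(axis=(0, 2, 3))
                    dxp[:, :, u:u + s * ho:s, v:v + s * wo:s] += \
                        dout * self.weight.data[:, 0, u, v][None, :, None, None]
            p = self.padding
            return dxp[:, :, p:p + h, p:p + w] if p else dxp
        # im2col
        _, cols, xshape = self._cache
        n, c, h, w = xshape
        ho, wo = dout.shape[2], dout.shape[3]
        dflat = dout.reshape(n, self.out_channels, -1)
        wmat = self.weight.data.reshape(self.out_channels, -1)
        self.weight.grad += np.einsum(
            "nop,nkp->ok", dflat, cols, optimize=True).reshape(self.weight.data.shape)
        dcols = np.einsum("ok,nop->nkp", wmat, dflat, optimize=True)
        dxp = np.zeros((n, c, h + 2 * self.padding, w + 2 * self.padding))
        s = self.stride
        idx = 0
        for ci in range(c):
            for u in range(self.k):
                for v in range(self.k):
                    dxp[:, ci, u:u + s * ho:s, v:v + s * wo:s] += dcols[:, idx].reshape(n, ho, wo)
                    idx += 1
        p = self.padding
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class Conv1d(Module):
    """1-D convolution over the channel axis of a (N, C) descriptor.

    Used by the ECA-style attention block: input (N, C) is treated as a
    length-C signal with one channel; zero padding keeps the length.
    """

    def __init__(self, kernel_size: int, bias: bool = False,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")
        self.k = kernel_size
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(he_normal(rng, (kernel_size,), kernel_size))
        self.bias = Parameter(np.zeros(1)) if bias else None
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        pad = self.k // 2
        xp = np.pad(x, ((0, 0), (pad, pad)))
        n, c = x.shape
        y = np.zeros_like(x)
        for u in range(self.k):
            y += self.weight.data[u] * xp[:, u:u + c]
        if self.bias is not None:
            y += self.bias.data[0]
        self._cache = (xp, x.shape) if grad_enabled() else None
        return y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xp, (n, c) = self._cache
        pad = self.k // 2
        dxp = np.zeros_like(xp)
        for u in range(self.k):
            self.weight.grad[u] += (dout * xp[:, u:u + c]).sum()
            dxp[:, u:u + c] += self.weight.data[u] * dout
        if self.bias is not None:
            self.bias.grad += dout.sum()
        return dxp[:, pad:pad + c]


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(
            glorot_uniform(rng, (out_features, in_features), in_features, out_features))
        self.bias = Parameter(np.zeros(out_features)) if bias else None
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x if grad_enabled() else None
        y = x @ self.weight.data.T
        if self.bias is not None:
            y += self.bias.data
        return y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.weight.grad += dout.T @ self._x
        if self.bias is not None:
            self.bias.grad += dout.sum(axis=0)
        return dout @ self.weight.data


class _BatchNorm(Module):
    """Shared train/eval batch-normalization logic; axes differ per subclass."""

    axes: tuple[int, ...]

    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def _shape(self, x: np.ndarray) -> tuple:
        s = [1] * x.ndim
        s[1] = x.shape[1]
        return tuple(s)

    def forward(self, x: np.ndarray) -> np.ndarray:
        shp = self._shape(x)
        if self.training:
            mean = x.mean(axis=self.axes)
            var = x.var(axis=self.axes)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean
            self.running_var = (1 - m) * self.running_var + m * var
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shp)) / std.reshape(shp)
        self._cache = (xhat, std, shp) if grad_enabled() else None
        return self.gamma.data.reshape(shp) * xhat + self.beta.data.reshape(shp)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, std, shp = self._cache
        self.gamma.grad += (dout * xhat).sum(axis=self.axes)
        self.beta.grad += dout.sum(axis=self.axes)
        if not self.training:
            return dout * (self.gamma.data / std).reshape(shp)
        m = float(np.prod([dout.shape[a] for a in self.axes]))
        dxhat = dout * self.gamma.data.reshape(shp)
        mean_dxhat = dxhat.mean(axis=self.axes).reshape(shp)
        mean_dxhat_xhat = (dxhat * xhat).mean(axis=self.axes).reshape(shp)
        return (dxhat - mean_dxhat - xhat * mean_dxhat_xhat) / std.reshape(shp)


class BatchNorm2d(_BatchNorm):
    axes = (0, 2, 3)


class BatchNorm1d(_BatchNorm):
    axes = (0,)


class ReLU(Module):
    def forward(self, x):
        if not grad_enabled():
            return np.where(x > 0, x, 0.0)
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout):
        return dout * self._mask


class ReLU6(Module):
    """min(max(x, 0), 6) — the clipped rectifier used throughout MobileNetV2."""

    def forward(self, x):
        if grad_enabled():
            self._mask = (x > 0) & (x < 6.0)
        return np.clip(x, 0.0, 6.0)

    def backward(self, dout):
        return dout * self._mask


class Sigmoid(Module):
    def forward(self, x):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dout):
        return dout * self._y * (1.0 - self._y)


class Dropout(Module):
    """Inverted dropout with an owned seeded generator (reproducible runs)."""

    def __init__(self, p: float, seed: int = 0):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.seed = seed
        self.rng = np.random.default_rng(seed)
        self._mask = None

    def reseed(self, seed: int) -> None:
        self.seed = seed
        self.rng = np.random.default_rng(seed)

    def forward(self, x):
        if not self.training or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Flatten(Module):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits)
    eps = 1e-12
    loss = -np.log(p[np.arange(n), labels] + eps).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), dlogits / n
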