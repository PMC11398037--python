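"""Attention blocks: parallel-CBAM (ICBAM), serial CBAM, SE and ECA.

The central block here combines channel attention

    M_c(F) = sigmoid( MLP(avgpool(F)) + MLP(maxpool(F)) )

(one shared two-layer bottleneck MLP applied to the global average- and
max-pooled channel descriptors) with spatial attention

    M_s(F) = sigmoid( pointwise_1x1( depthwise_7x7( [F_avg ; F_max] ) ) )

(per-pixel channel mean and max stacked into a 2-channel map, filtered by a
depthwise-separable 7x7 convolution). In the parallel variant both maps are
computed from the *original* input and applied multiplicatively in one shot:

    F2 = M_c(F) * M_s(F) * F

whereas the classic serial CBAM first re-weights by channel attention and
then computes spatial attention on the already re-weighted features. The
parallel wiring makes the result independent of the order in which the two
attention maps are evaluated; the serial one is not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import Conv1d, Conv2d, Module, Parameter, glorot_uniform


@dataclass
class IcbamConfig:
    """Shape of the attention block: channel count, MLP bottleneck, kernel."""

    channels: int = 1280
    reduction: int = 16
    spatial_kernel: int = 7

    def __post_init__(self) -> None:
        if self.channels < 1 or self.channels // self.reduction < 1:
            raise ValueError("channels/reduction must be >= 1")
        if self.spatial_kernel % 2 == 0:
            raise ValueError("spatial_kernel must be odd")


class ChannelAttention(Module):
    """Shared-MLP channel attention over global average and max pooling."""

    def __init__(self, channels: int, reduction: int = 16,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        hidden = channels // reduction
        self.w0 = Parameter(glorot_uniform(rng, (hidden, channels), channels, hidden))
        self.b0 = Parameter(np.zeros(hidden))
        self.w1 = Parameter(glorot_uniform(rng, (channels, hidden), hidden, channels))
        self.b1 = Parameter(np.zeros(channels))
        self._cache = None

    def _mlp(self, v: np.ndarray):
        h_pre = v @ self.w0.data.T + self.b0.data
        h = np.maximum(h_pre, 0.0)
        return v, h_pre, h, h @ self.w1.data.T + self.b1.data

    def _mlp_backward(self, cache, dout: np.ndarray) -> np.ndarray:
        v, h_pre, h, _ = cache
        self.w1.grad += dout.T @ h
        self.b1.grad += dout.sum(axis=0)
        dh = (dout @ self.w1.data) * (h_pre > 0)
        self.w0.grad += dh.T @ v
        self.b0.grad += dh.sum(axis=0)
        return dh @ self.w0.data

    def forward(self, f: np.ndarray) -> np.ndarray:
        """(N, C, H, W) -> channel weights (N, C, 1, 1) in (0, 1)."""
        n, c, h, w = f.shape
        avg = f.mean(axis=(2, 3))
        flat = f.reshape(n, c, -1)
        argmax = flat.argmax(axis=2)
        mx = np.take_along_axis(flat, argmax[:, :, None], axis=2)[:, :, 0]
        cache_avg = self._mlp(avg)
        cache_max = self._mlp(mx)
        s = cache_avg[3] + cache_max[3]
        mc = 1.0 / (1.0 + np.exp(-s))
        self._cache = (cache_avg, cache_max, mc, argmax, f.shape)
        return mc[:, :, None, None]

    def backward(self, dmc: np.ndarray) -> np.ndarray:
        """Gradient w.r.t. the block input, from d(M_c) of shape (N, C, 1, 1)."""
        cache_avg, cache_max, mc, argmax, fshape = self._cache
        n, c, h, w = fshape
        ds = dmc[:, :, 0, 0] * mc * (1.0 - mc)
        davg = self._mlp_backward(cache_avg, ds)
        dmx = self._mlp_backward(cache_max, ds)
        df = np.broadcast_to(davg[:, :, None, None] / (h * w), fshape).copy()
        dflat = df.reshape(n, c, -1)
        np.put_along_axis(dflat, argmax[:, :, None],
                          np.take_along_axis(dflat, argmax[:, :, None], axis=2)
                          + dmx[:, :, None], axis=2)
        return df


class SpatialAttention(Module):
    """Spatial attention over the per-pixel channel mean/max 2-channel stack.

    ``separable=True`` uses a depthwise 7x7 (groups=2) followed by a 1x1
    pointwise convolution; ``separable=False`` is the classic single dense
    7x7 convolution from serial CBAM.
    """

    def __init__(self, kernel_size: int = 7, separable: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        pad = kernel_size // 2
        if separable:
            self.depthwise = Conv2d(2, 2, kernel_size, padding=pad, groups=2, rng=rng)
            self.pointwise = Conv2d(2, 1, 1, rng=rng)
        else:
            self.depthwise = None
            self.pointwise = Conv2d(2, 1, kernel_size, padding=pad, rng=rng)
        self._cache = None

    def forward(self, f: np.ndarray) -> np.ndarray:
        """(N, C, H, W) -> spatial weights (N, 1, H, W) in (0, 1)."""
        n, c, h, w = f.shape
        avg = f.mean(axis=1, keepdims=True)
        argmax = f.argmax(axis=1)
        mx = np.take_along_axis(f, argmax[:, None], axis=1)
        stack = np.concatenate([avg, mx], axis=1)
        z = stack
        if self.depthwise is not None:
            z = self.depthwise(z)
        z = self.pointwise(z)
        ms = 1.0 / (1.0 + np.exp(-z))
        self._cache = (ms, argmax, f.shape)
        return ms

    def backward(self, dms: np.ndarray) -> np.ndarray:
        ms, argmax, fshape = self._cache
        n, c, h, w = fshape
        dz = dms * ms * (1.0 - ms)
        dstack = self.pointwise.backward(dz)
        if self.depthwise is not None:
            dstack = self.depthwise.backward(dstack)
        df = np.broadcast_to(dstack[:, 0:1] / c, fshape).copy()
        np.put_along_axis(df, argmax[:, None],
                          np.take_along_axis(df, argmax[:, None], axis=1)
                          + dstack[:, 1:2], axis=1)
        return df


class ICBAM(Module):
    """Parallel channel + spatial attention: F2 = M_c(F) * M_s(F) * F."""

    def __init__(self, config: IcbamConfig, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.config = config
        self.channel = ChannelAttention(config.channels, config.reduction, rng)
        self.spatial = SpatialAttention(config.spatial_kernel, separable=True, rng=rng)
        self._cache = None

    def forward(self, f: np.ndarray) -> np.ndarray:
        if f.shape[1] != self.config.channels:
            raise ValueError(f"expected {self.config.channels} channels, got {f.shape[1]}")
        mc = self.channel(f)   # computed from the original F ...
        ms = self.spatial(f)   # ... both of them (parallel topology)
        self._cache = (f, mc, ms)
        return mc * ms * f

    def backward(self, dout: np.ndarray) -> np.ndarray:
        f, mc, ms = self._cache
        df = dout * mc * ms
        dmc = (dout * ms * f).sum(axis=(2, 3), keepdims=True)
        dms = (dout * mc * f).sum(axis=1, keepdims=True)
        df += self.channel.backward(dmc)
        df += self.spatial.backward(dms)
        return df


class CBAM(Module):
    """Serial reference: channel attention first, spatial attention second."""

    def __init__(self, config: IcbamConfig, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.config = config
        self.channel = ChannelAttention(config.channels, config.reduction, rng)
        self.spatial = SpatialAttention(config.spatial_kernel, separable=False, rng=rng)
        self._cache = None

    def forward(self, f: np.ndarray) -> np.ndarray:
        mc = self.channel(f)
        f1 = mc * f
        ms = self.spatial(f1)  # computed from the re-weighted features
        self._cache = (f, mc, f1, ms)
        return ms * f1

    def backward(self, dout: np.ndarray) -> np.ndarray:
        f, mc, f1, ms = self._cache
        df1 = dout * ms
        dms = (dout * f1).sum(axis=1, keepdims=True)
        df1 += self.spatial.backward(dms)
        df = df1 * mc
        dmc = (df1 * f).sum(axis=(2, 3), keepdims=True)
        df += self.channel.backward(dmc)
        return df


class SEBlock(Module):
    """Squeeze-and-excitation: channel attention from average pooling only."""

    def __init__(self, channels: int, reduction: int = 16,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        hidden = channels // reduction
        self.w0 = Parameter(glorot_uniform(rng, (hidden, channels), channels, hidden))
        self.b0 = Parameter(np.zeros(hidden))
        self.w1 = Parameter(glorot_uniform(rng, (channels, hidden), hidden, channels))
        self.b1 = Parameter(np.zeros(channels))
        self._cache = None

    def forward(self, f: np.ndarray) -> np.ndarray:
        n, c, h, w = f.shape
        v = f.mean(axis=(2, 3))
        h_pre = v @ self.w0.data.T + self.b0.data
        hid = np.maximum(h_pre, 0.0)
        s = hid @ self.w1.data.T + self.b1.data
        mc = 1.0 / (1.0 + np.exp(-s))
        self._cache = (f, v, h_pre, hid, mc)
        return f * mc[:, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        f, v, h_pre, hid, mc = self._cache
        n, c, h, w = f.shape
        df = dout * mc[:, :, None, None]
        dmc = (dout * f).sum(axis=(2, 3))
        ds = dmc * mc * (1.0 - mc)
        self.w1.grad += ds.T @ hid
        self.b1.grad += ds.sum(axis=0)
        dhid = (ds @ self.w1.data) * (h_pre > 0)
        self.w0.grad += dhid.T @ v
        self.b0.grad += dhid.sum(axis=0)
        dv = dhid @ self.w0.data
        df += dv[:, :, None, None] / (h * w)
        return df


class ECABlock(Module):
    """Efficient channel attention: a k-tap 1-D convolution over channels."""

    def __init__(self, channels: int, kernel_size: int | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if kernel_size is None:
            # adaptive kernel: nearest odd to log2(C)/2 + 1/2
            t = int(abs(np.log2(channels) / 2.0 + 0.5))
            kernel_size = t if t % 2 else t + 1
        self.conv = Conv1d(kernel_size, bias=False, rng=rng)
        self._cache = None

    def forward(self, f: np.ndarray) -> np.ndarray:
        n, c, h, w = f.shape
        v = f.mean(axis=(2, 3))
        s = self.conv(v)
        mc = 1.0 / (1.0 + np.exp(-s))
        self._cache = (f, mc)
        return f * mc[:, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        f, mc = self._cache
        n, c, h, w = f.shape
        df = dout * mc[:, :, None, None]
        dmc = (dout * f).sum(axis=(2, 3))
        dv = self.conv.backward(dmc * mc * (1.0 - mc))
        df += dv[:, :, None, None] / (h * w)
        return df


def make_attention(kind: str, config: IcbamConfig,
                   rng: np.random.Generator | None = None) -> Module | None:
    """Build an attention block by name: icbam, cbam, se, eca or none."""
    kind = kind.lower()
    if kind == "icbam":
        return ICBAM(config, rng)
    if kind == "cbam":
        return CBAM(config, rng)
    if kind == "se":
        return SEBlock(config.channels, config.reduction, rng)
    if kind == "eca":
        return ECABlock(config.channels, rng=rng)
    if kind == "none":
        return None
    raise ValueError(f"unknown attention kind {kind!r}")
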