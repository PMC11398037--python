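"""MobileNetV2-style feature extractor.

The standard width-1.0 inverted-residual stack: a stride-2 stem, seven
bottleneck stages with expansion factors (1, 6, ...), and a final 1x1
expansion to 1280 channels, for an overall stride of 32. Each inverted
residual expands with a pointwise convolution, filters with a depthwise 3x3,
and projects back down through a linear (non-activated) bottleneck, with a
shortcut connection whenever the block preserves shape. All activations are
ReLU6.

The stem accepts any number of input channels; gait templates are single
channel, and a 3-channel stem is used only when loading weights pretrained
on RGB images (the gray template is then replicated across channels).
"""

from __future__ import annotations

import numpy as np

from .layers import BatchNorm2d, Conv2d, Module, ReLU6, Sequential

# (expansion t, output channels c, repeats n, first stride s)
INVERTED_RESIDUAL_SETTINGS = [
    (1, 16, 1, 1),
    (6, 24, 2, 2),
    (6, 32, 3, 2),
    (6, 64, 4, 2),
    (6, 96, 3, 1),
    (6, 160, 3, 2),
    (6, 320, 1, 1),
]
LAST_CHANNELS = 1280


def _make_divisible(v: float, divisor: int = 8) -> int:
    new_v = max(divisor, int(v + divisor / 2) // divisor * divisor)
    if new_v < 0.9 * v:
        new_v += divisor
    return new_v


def conv_bn_relu6(in_ch: int, out_ch: int, k: int, stride: int, groups: int,
                  rng: np.random.Generator) -> Sequential:
    return Sequential(
        Conv2d(in_ch, out_ch, k, stride=stride, padding=k // 2, groups=groups,
               bias=False, rng=rng),
        BatchNorm2d(out_ch),
        ReLU6(),
    )


class InvertedResidual(Module):
    """expand (1x1) -> depthwise 3x3 -> linear project (1x1), with shortcut."""

    def __init__(self, in_ch: int, out_ch: int, stride: int, expand: int,
                 rng: np.random.Generator):
        super().__init__()
        hidden = in_ch * expand
        self.use_shortcut = stride == 1 and in_ch == out_ch
        layers = []
        if expand != 1:
            layers.append(conv_bn_relu6(in_ch, hidden, 1, 1, 1, rng))
        layers.append(conv_bn_relu6(hidden, hidden, 3, stride, hidden, rng))
        layers.append(Sequential(
            Conv2d(hidden, out_ch, 1, bias=False, rng=rng),
            BatchNorm2d(out_ch),
        ))
        self.body = Sequential(*layers)

    def forward(self, x):
        y = self.body(x)
        return x + y if self.use_shortcut else y

    def backward(self, dout):
        dx = self.body.backward(dout)
        return dx + dout if self.use_shortcut else dx


class MobileNetV2Features(Module):
    """The convolutional feature stack; output (N, 1280, H/32, W/32)."""

    def __init__(self, in_channels: int = 1, width: float = 1.0,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        ch = _make_divisible(32 * width)
        blocks: list[Module] = [conv_bn_relu6(in_channels, ch, 3, 2, 1, rng)]
        for t, c, n, s in INVERTED_RESIDUAL_SETTINGS:
            out_ch = _make_divisible(c * width)
            for i in range(n):
                blocks.append(InvertedResidual(ch, out_ch, s if i == 0 else 1, t, rng))
                ch = out_ch
        self.out_channels = _make_divisible(LAST_CHANNELS * max(1.0, width))
        blocks.append(conv_bn_relu6(ch, self.out_channels, 1, 1, 1, rng))
        self.blocks = blocks

    def forward(self, x):
        for b in self.blocks:
            x = b(x)
        return x

    def backward(self, dout):
        for b in reversed(self.blocks):
            dout = b.backward(dout)
        return dout
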