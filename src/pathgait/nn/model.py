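"""The dual-branch lightweight gait classifier.

One shared MobileNetV2-style backbone feeds two branches: the convolutional
branch passes its 1280-channel feature map straight through, and the
attention branch re-weights the same map with the parallel attention block.
The branches are fused elementwise (sum by default, concatenation behind a
flag) and classified by a customized head that replaces global average
pooling with a depthwise-separable convolution — so the head can *learn*
per-location weights instead of treating the center and corners of the
feature map alike:

    DSC (depthwise 3x3 -> pointwise to 32 ch) -> flatten -> dense(256)
    -> batch norm -> ReLU -> dropout -> dense(n_classes) -> softmax

A shared backbone and sum fusion keep the trainable parameter budget at
~3.01 M for 256x256 input (5 classes) and ~2.89 M for 224x224 — only the
flatten-to-dense weight matrix depends on the input resolution.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .attention import IcbamConfig, make_attention
from .backbone import MobileNetV2Features
from .layers import (BatchNorm1d, Conv2d, Dropout, Flatten, Linear, Module,
                     ReLU, Sequential, softmax)


@dataclass
class ModelConfig:
    """Architecture hyperparameters of the full classifier."""

    input_size: int = 256
    in_channels: int = 1
    n_classes: int = 5
    backbone_width: float = 1.0
    icbam: IcbamConfig = field(default_factory=IcbamConfig)
    attention: str = "icbam"          # icbam | cbam | se | eca | none
    fusion: str = "sum"               # sum | concat
    head_pointwise_channels: int = 32
    head_dense_units: int = 256
    dropout: float = 0.2
    pretrained: bool = False
    freeze_backbone: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_size % 32:
            raise ValueError("input_size must be divisible by 32")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.fusion not in ("sum", "concat"):
            raise ValueError("fusion must be 'sum' or 'concat'")


def build_backbone(config: ModelConfig,
                   rng: np.random.Generator | None = None) -> MobileNetV2Features:
    """The shared feature extractor (stride 32, 1280 output channels)."""
    if config.pretrained:
        raise ValueError(
            "no pretrained weight file available in offline mode; pass "
            "pretrained=False (--no-pretrained) or use apply_transfer_learning "
            "with a local weight file")
    return MobileNetV2Features(config.in_channels, config.backbone_width, rng)


class GaitRecognitionModel(Module):
    """Dual-branch classifier over fused-energy-image inputs."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.backbone = build_backbone(config, rng)
        self.attention = make_attention(config.attention, config.icbam, rng)
        c = self.backbone.out_channels
        if config.fusion == "concat" and self.attention is not None:
            c = 2 * c
        spatial = config.input_size // 32
        flat = config.head_pointwise_channels * spatial * spatial
        self.head = Sequential(
            Conv2d(c, c, 3, padding=1, groups=c, rng=rng),            # depthwise
            Conv2d(c, config.head_pointwise_channels, 1, rng=rng),    # pointwise
            Flatten(),
            Linear(flat, config.head_dense_units, rng=rng),
            BatchNorm1d(config.head_dense_units),
            ReLU(),
            Dropout(config.dropout, seed=config.seed + 1),
            Linear(config.head_dense_units, config.n_classes, rng=rng),
        )
        if config.freeze_backbone:
            self.backbone.freeze()
        self._fused_from_features = False

    # -- split forward so frozen-backbone training can cache features --------

    def extract_features(self, x: np.ndarray) -> np.ndarray:
        """Backbone feature map (N, 1280, s, s) from images (N, C, H, W)."""
        if x.ndim != 4 or x.shape[1] != self.config.in_channels:
            raise ValueError("expected (N, %d, H, W) input" % self.config.in_channels)
        return self.backbone(x)

    def head_forward(self, features: np.ndarray) -> np.ndarray:
        """Branch fusion + classification head; returns logits (N, n_classes)."""
        if self.attention is None:
            fused = features
        else:
            att = self.attention(features)
            if self.config.fusion == "sum":
                fused = features + att
            else:
                fused = np.concatenate([features, att], axis=1)
        return self.head(fused)

    def head_backward(self, dlogits: np.ndarray) -> np.ndarray:
        """Backprop through head + fusion + attention; returns d(features)."""
        dfused = self.head.backward(dlogits)
        if self.attention is None:
            return dfused
        if self.config.fusion == "sum":
            datt = dfused
            dfeat = dfused.copy()
        else:
            c = self.backbone.out_channels
            dfeat, datt = dfused[:, :c].copy(), dfused[:, c:]
        dfeat += self.attention.backward(datt)
        return dfeat

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Logits for a batch of images."""
        return self.head_forward(self.extract_features(x))

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        dfeat = self.head_backward(dlogits)
        if any(p.trainable for p in self.backbone.parameters()):
            return self.backbone.backward(dfeat)
        return dfeat

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Softmax class probabilities."""
        return softmax(self.forward(x))


def build_model(config: ModelConfig | None = None, **overrides) -> GaitRecognitionModel:
    """Construct the full classifier from a config (or keyword overrides)."""
    if config is None:
        config = ModelConfig(**overrides)
    elif overrides:
        config = ModelConfig(**{**asdict_config(config), **overrides})
    return GaitRecognitionModel(config)


def asdict_config(config: ModelConfig) -> dict:
    d = asdict(config)
    return d


def count_parameters(model: Module, trainable_only: bool = True) -> int:
    """Exact count of scalar parameters (optionally trainable only)."""
    return model.n_parameters(trainable_only=trainable_only)


def save_weights(model: Module, path: str | Path, config: ModelConfig | None = None) -> None:
    """Save parameters as an .npz archive with a JSON config sidecar."""
    path = Path(path)
    arrays = {name: p.data for name, p in model.named_parameters()}
    np.savez(path, **arrays)
    if config is not None:
        d = asdict_config(config)
        d["icbam"] = asdict(config.icbam) if not isinstance(d["icbam"], dict) else d["icbam"]
        Path(str(path) + ".json").write_text(json.dumps(d, indent=2))


def load_weights(model: Module, path: str | Path, prefix: str = "",
                 strict: bool = True) -> list[str]:
    """Load parameters from an .npz archive; returns names that were loaded.

    Raises on shape mismatch, listing the offending layers.
    """
    with np.load(Path(path)) as data:
        available = dict(data.items())
    loaded, mismatched = [], []
    for name, p in model.named_parameters():
        key = prefix + name
        if key not in available:
            if strict:
                mismatched.append(f"{key}: missing")
            continue
        arr = available[key]
        if arr.shape != p.data.shape:
            mismatched.append(f"{key}: file {arr.shape} vs model {p.data.shape}")
            continue
        p.data[...] = arr
        loaded.append(key)
    if mismatched:
        raise ValueError("weight load mismatch:\n  " + "\n  ".join(mismatched))
    return loaded


def apply_transfer_learning(model: GaitRecognitionModel,
                            weights_source: str | Path) -> GaitRecognitionModel:
    """Load backbone weights from an .npz file and freeze them.

    The attention block and head keep their fresh initialization and stay
    trainable — the transfer-learning recipe of loading generic convolutional
    features and retraining only the new layers.
    """
    with np.load(Path(weights_source)) as data:
        available = dict(data.items())
    mismatched, n_loaded = [], 0
    for name, p in model.backbone.named_parameters("backbone."):
        if name not in available:
            mismatched.append(f"{name}: missing from {weights_source}")
            continue
        arr = available[name]
        if arr.shape != p.data.shape:
            mismatched.append(f"{name}: file {arr.shape} vs model {p.data.shape}")
            continue
        p.data[...] = arr
        n_loaded += 1
    if mismatched:
        raise ValueError("backbone weight mismatch:\n  " + "\n  ".join(mismatched))
    if n_loaded == 0:
        raise ValueError(f"no backbone weights found in {weights_source}")
    model.backbone.freeze()
    return model
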