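"""Classifier architecture: parameter budgets, shapes, freezing, serialization."""

import numpy as np
import pytest

from pathgait.nn.attention import IcbamConfig
from pathgait.nn.layers import Linear, no_grad, softmax
from pathgait.nn.model import (ModelConfig, apply_transfer_learning, build_backbone,
                               build_model, count_parameters, load_weights,
                               save_weights)
from pathgait.nn.optim import Adam


@pytest.fixture(scope="module")
def model256():
    return build_model(ModelConfig(input_size=256, n_classes=5, seed=0))


def test_full_model_parameter_budget_256(model256):
    """Dual-branch model at 256x256 input: ~3.01 M trainable parameters."""
    n = count_parameters(model256)
    assert round(n / 1e6, 2) == 3.01


def test_full_model_parameter_budget_224():
    """Same architecture at 224x224: ~2.89 M (only the flatten->dense changes)."""
    n = count_parameters(build_model(ModelConfig(input_size=224, n_classes=5)))
    assert round(n / 1e6, 2) == 2.89


def test_budget_difference_is_flatten_dense_only(model256):
    n256 = count_parameters(model256)
    n224 = count_parameters(build_model(ModelConfig(input_size=224)))
    # head_pointwise_channels * (8*8 - 7*7) * head_dense_units
    assert n256 - n224 == 32 * (64 - 49) * 256


def test_backbone_parameter_count():
    cfg = ModelConfig(input_size=256)
    backbone = build_backbone(cfg, np.random.default_rng(0))
    assert round(backbone.n_parameters() / 1e6, 3) == 2.223
    # 3-channel stem adds exactly 2 * 3*3*32 weights over the 1-channel stem
    from pathgait.nn.backbone import MobileNetV2Features
    assert MobileNetV2Features(3).n_parameters() - backbone.n_parameters() == 576


@pytest.mark.parametrize("size,spatial", [(256, 8), (224, 7)])
def test_feature_map_stride_32(size, spatial):
    model = build_model(ModelConfig(input_size=size, seed=1))
    x = np.zeros((1, 1, size, size))
    with no_grad():
        feats = model.extract_features(x)
    assert feats.shape == (1, 1280, spatial, spatial)


def test_forward_gives_probability_simplex(model256, rng):
    x = rng.random((2, 1, 256, 256))
    model256.eval()
    with no_grad():
        probs = model256.predict_proba(x)
    assert probs.shape == (2, 5)
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
    assert (probs >= 0).all()


def test_zeroed_attention_scales_features_by_1_25(model256, rng):
    """With all attention parameters zero, fused = F + 0.25 F = 1.25 F."""
    saved = [p.data.copy() for p in model256.attention.parameters()]
    for p in model256.attention.parameters():
        p.data[...] = 0.0
    feats = rng.normal(size=(1, 1280, 8, 8))
    with no_grad():
        att = model256.attention(feats)
    assert np.allclose(att, 0.25 * feats)
    for p, s in zip(model256.attention.parameters(), saved):
        p.data[...] = s


def test_count_parameters_dense_example():
    layer = Linear(10, 5)
    assert layer.n_parameters() == 55


def test_frozen_backbone_excluded_from_trainable_count(model256):
    model = build_model(ModelConfig(input_size=256, freeze_backbone=True, seed=2))
    total = count_parameters(model, trainable_only=False)
    trainable = count_parameters(model, trainable_only=True)
    assert total == count_parameters(model256)
    assert total - trainable == model.backbone.n_parameters(trainable_only=False)


def test_transfer_learning_freezes_backbone(tmp_path):
    donor = build_model(ModelConfig(input_size=64, seed=3))
    save_weights(donor, tmp_path / "donor.npz")
    model = build_model(ModelConfig(input_size=64, seed=4))
    apply_transfer_learning(model, tmp_path / "donor.npz")
    for name, p in model.backbone.named_parameters("backbone."):
        assert not p.trainable
    # a gradient step must not move any backbone parameter
    before = [p.data.copy() for p in model.backbone.parameters()]
    x = np.random.default_rng(0).random((2, 1, 64, 64))
    logits = model.forward(x)
    from pathgait.nn.layers import softmax_cross_entropy
    _, dlogits = softmax_cross_entropy(logits, np.array([0, 1]))
    model.zero_grad()
    model.backward(dlogits)
    Adam(model.parameters(), lr=0.1).step()
    for b, p in zip(before, model.backbone.parameters()):
        assert np.array_equal(b, p.data)


def test_weight_roundtrip_and_mismatch_error(tmp_path):
    cfg = ModelConfig(input_size=64, seed=5)
    model = build_model(cfg)
    save_weights(model, tmp_path / "ckpt.npz", cfg)
    clone = build_model(ModelConfig(input_size=64, seed=6))
    load_weights(clone, tmp_path / "ckpt.npz")
    for (na, pa), (nb, pb) in zip(model.named_parameters(), clone.named_parameters()):
        assert na == nb and np.array_equal(pa.data, pb.data)
    other = build_model(ModelConfig(input_size=96, seed=7))
    with pytest.raises(ValueError, match="mismatch"):
        load_weights(other, tmp_path / "ckpt.npz")


def test_pretrained_without_weight_file_errors():
    with pytest.raises(ValueError, match="no pretrained weight file"):
        build_model(ModelConfig(pretrained=True))


def test_eval_forward_is_deterministic(model256, rng):
    x = rng.random((1, 1, 256, 256))
    model256.eval()
    with no_grad():
        a = model256.forward(x)
        b = model256.forward(x)
    assert np.array_equal(a, b)


def test_attention_variant_budgets():
    """SE/CBAM variants match the ICBAM budget to 2 decimals; ECA is 0.21 M lighter."""
    counts = {}
    for kind in ("icbam", "cbam", "se", "eca"):
        m = build_model(ModelConfig(input_size=256, attention=kind, seed=8))
        counts[kind] = count_parameters(m)
    assert round(counts["icbam"] / 1e6, 2) == 3.01
    assert round(counts["se"] / 1e6, 2) == 3.01
    assert round(counts["cbam"] / 1e6, 2) == 3.01
    assert round(counts["eca"] / 1e6, 2) == 2.80
    assert round((counts["icbam"] - counts["eca"]) / 1e6, 2) == 0.21


def test_config_validation():
    with pytest.raises(ValueError, match="divisible by 32"):
        ModelConfig(input_size=200)
    with pytest.raises(ValueError, match="n_classes"):
        ModelConfig(n_classes=1)
    with pytest.raises(ValueError, match="dropout"):
        ModelConfig(dropout=1.0)
    with pytest.raises(ValueError, match="reduction"):
        IcbamConfig(channels=8, reduction=16)
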