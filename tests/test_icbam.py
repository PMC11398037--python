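"""Attention blocks: closed-form identities, oracles, parallel-vs-serial."""

import numpy as np
import pytest

from pathgait.nn.attention import (CBAM, ECABlock, ICBAM, IcbamConfig, SEBlock,
                                   make_attention)


def zero_params(module):
    for p in module.parameters():
        p.data[...] = 0.0
    return module


@pytest.fixture()
def small_cfg():
    return IcbamConfig(channels=4, reduction=2, spatial_kernel=7)


def test_zero_parameters_give_quarter_identity(small_cfg, rng):
    """sigma(0) = 0.5 for both maps, so F2 = 0.5 * 0.5 * F exactly."""
    block = zero_params(ICBAM(small_cfg))
    f = rng.normal(size=(2, 4, 6, 5))
    assert np.allclose(block(f), 0.25 * f, atol=0, rtol=0)


def test_zero_input_gives_zero_output(small_cfg):
    block = ICBAM(small_cfg, rng=np.random.default_rng(3))
    f = np.zeros((1, 4, 5, 5))
    assert not block(f).any()


def test_output_composes_from_submodules(small_cfg, rng):
    block = ICBAM(small_cfg, rng=np.random.default_rng(7))
    f = rng.normal(size=(3, 4, 5, 6))
    out = block(f)
    mc = block.channel(f)
    ms = block.spatial(f)
    assert np.allclose(out, mc * ms * f)


@pytest.mark.parametrize("shape", [(1, 4, 1, 1), (2, 4, 3, 9), (1, 4, 17, 2)])
def test_shape_preserved(small_cfg, shape, rng):
    block = ICBAM(small_cfg, rng=np.random.default_rng(1))
    f = rng.normal(size=shape)
    assert block(f).shape == shape


def test_attenuation_bound(small_cfg, rng):
    """Attention weights lie in (0,1): |F2| <= |F| everywhere."""
    block = ICBAM(small_cfg, rng=np.random.default_rng(2))
    f = rng.normal(size=(2, 4, 8, 8)) * 5
    assert (np.abs(block(f)) <= np.abs(f) + 1e-12).all()


def test_channel_attention_matches_loop_oracle(small_cfg, rng):
    block = ICBAM(small_cfg, rng=np.random.default_rng(5))
    ca = block.channel
    f = rng.normal(size=(2, 4, 3, 5))
    got = ca(f)[:, :, 0, 0]
    w0, b0, w1, b1 = ca.w0.data, ca.b0.data, ca.w1.data, ca.b1.data

    def mlp(v):
        h = np.maximum(w0 @ v + b0, 0.0)
        return w1 @ h + b1

    for n in range(f.shape[0]):
        avg = np.array([f[n, c].mean() for c in range(4)])
        mx = np.array([f[n, c].max() for c in range(4)])
        s = mlp(avg) + mlp(mx)
        expected = 1.0 / (1.0 + np.exp(-s))
        assert np.allclose(got[n], expected)


def test_channel_attention_constant_input_doubles_descriptor(small_cfg, rng):
    """Constant-per-channel maps make avgpool == maxpool, so M_c = sigma(2 MLP(v))."""
    block = ICBAM(small_cfg, rng=np.random.default_rng(8))
    ca = block.channel
    v = rng.normal(size=4)
    f = np.broadcast_to(v[None, :, None, None], (1, 4, 6, 6)).copy()
    h = np.maximum(ca.w0.data @ v + ca.b0.data, 0.0)
    s = 2.0 * (ca.w1.data @ h + ca.b1.data)
    assert np.allclose(ca(f)[0, :, 0, 0], 1.0 / (1.0 + np.exp(-s)))


def test_spatial_attention_direct_convolution_oracle(rng):
    """1-channel 8x8 map checked against explicit padded convolution loops."""
    cfg = IcbamConfig(channels=1, reduction=1, spatial_kernel=7)
    block = ICBAM(cfg, rng=np.random.default_rng(4))
    sa = block.spatial
    f = rng.normal(size=(1, 1, 8, 8))
    got = sa(f)[0, 0]
    avg = f[0].mean(axis=0)
    mx = f[0].max(axis=0)
    stack = np.stack([avg, mx])
    dw_w, dw_b = sa.depthwise.weight.data, sa.depthwise.bias.data
    pw_w, pw_b = sa.pointwise.weight.data, sa.pointwise.bias.data
    padded = np.pad(stack, ((0, 0), (3, 3), (3, 3)))
    z = np.zeros((2, 8, 8))
    for c in range(2):
        for i in range(8):
            for j in range(8):
                acc = 0.0
                for u in range(7):
                    for v in range(7):
                        acc += dw_w[c, 0, u, v] * padded[c, i + u, j + v]
                z[c, i, j] = acc + dw_b[c]
    s = pw_w[0, 0, 0, 0] * z[0] + pw_w[0, 1, 0, 0] * z[1] + pw_b[0]
    assert np.allclose(got, 1.0 / (1.0 + np.exp(-s)))


def test_spatial_attention_peaks_at_bright_pixel():
    cfg = IcbamConfig(channels=1, reduction=1, spatial_kernel=7)
    block = ICBAM(cfg, rng=np.random.default_rng(0))
    sa = block.spatial
    # identity-like weights: center tap of the depthwise kernel, positive pointwise
    for p in sa.parameters():
        p.data[...] = 0.0
    sa.depthwise.weight.data[:, 0, 3, 3] = 1.0
    sa.pointwise.weight.data[...] = 1.0
    f = np.zeros((1, 1, 8, 8))
    f[0, 0, 2, 6] = 10.0
    ms = sa(f)[0, 0]
    assert np.unravel_index(ms.argmax(), ms.shape) == (2, 6)


def test_parallel_is_order_invariant_serial_is_not(small_cfg, rng):
    """Swapping evaluation order never changes ICBAM; serial CBAM differs."""
    f = rng.normal(size=(2, 4, 6, 6))
    par = ICBAM(small_cfg, rng=np.random.default_rng(11))
    mc_first = par.channel(f) * par.spatial(f) * f
    ms_first = par.spatial(f) * par.channel(f) * f
    assert np.allclose(par(f), mc_first)
    assert np.allclose(mc_first, ms_first)

    ser = CBAM(small_cfg, rng=np.random.default_rng(11))
    # same channel MLP weights as the parallel block for a fair comparison
    for p_par, p_ser in zip(par.channel.parameters(), ser.channel.parameters()):
        p_ser.data[...] = p_par.data
    out_serial = ser(f)
    # serial spatial attention sees channel-re-weighted features; with any
    # non-degenerate channel map the two topologies disagree
    assert not np.allclose(out_serial, par(f), atol=1e-6)


def test_parameter_delta_over_eca_matches_printed_budget():
    cfg = IcbamConfig(channels=1280, reduction=16, spatial_kernel=7)
    icbam = make_attention("icbam", cfg)
    eca = make_attention("eca", cfg)
    delta = icbam.n_parameters() - eca.n_parameters()
    assert round(delta / 1e6, 2) == 0.21


def test_se_and_eca_scale_features(rng):
    f = rng.normal(size=(2, 8, 4, 4))
    se = SEBlock(8, 2, rng=np.random.default_rng(1))
    eca = ECABlock(8, 3, rng=np.random.default_rng(1))
    for block in (se, eca):
        out = block(f)
        assert out.shape == f.shape
        assert (np.abs(out) <= np.abs(f) + 1e-12).all()


def test_icbam_gradients_match_finite_differences(small_cfg, rng):
    block = ICBAM(small_cfg, rng=np.random.default_rng(6))
    f = rng.normal(size=(2, 4, 5, 5))
    out = block(f)
    dout = rng.normal(size=out.shape)
    block.zero_grad()
    df = block.backward(dout)
    eps = 1e-6
    for _ in range(20):
        idx = tuple(rng.integers(0, s) for s in f.shape)
        f1, f2 = f.copy(), f.copy()
        f1[idx] += eps
        f2[idx] -= eps
        num = ((block.forward(f1) - block.forward(f2)) * dout).sum() / (2 * eps)
        assert num == pytest.approx(df[idx], rel=1e-4, abs=1e-8)
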