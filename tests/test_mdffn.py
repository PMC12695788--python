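"""Space-to-depth, omnidirectional kernels, FFT attention, and neck wiring."""

import numpy as np
import pytest
from scipy.signal import correlate2d
from scipy.special import erf

from berrydetr import nn
from berrydetr.mdffn import (
    CCFM,
    CMKBlock,
    CMKConfig,
    DDAM,
    FMB,
    MDCM,
    MDFFN,
    NeckConfig,
    SPDConv,
    depth_to_space,
    space_to_depth,
    spdconv,
)
from berrydetr.nn import Tensor

RNG = np.random.default_rng(17)


def gelu(x):
    return x * 0.5 * (1 + erf(x / np.sqrt(2)))


def dft_matrix(n):
    k = np.arange(n)
    return np.exp(-2j * np.pi * np.outer(k, k) / n)


def dft2(x):
    """Dense DFT-matrix 2-D transform of (..., H, W), unnormalized forward."""
    H, W = x.shape[-2:]
    return np.einsum("hi,...iw->...hw", dft_matrix(H), x) @ dft_matrix(W).T


def idft2(x):
    H, W = x.shape[-2:]
    return (
        np.einsum("hi,...iw->...hw", dft_matrix(H).conj(), x) @ dft_matrix(W).conj().T
    ) / (H * W)


# ---------------------------------------------------------------------------
# space-to-depth / SPDConv


def test_space_to_depth_slicing_oracle_and_shape():
    x = RNG.normal(size=(1, 2, 4, 4))
    y = space_to_depth(Tensor(x)).numpy()
    assert y.shape == (1, 8, 2, 2)
    # third group (channel block 2): rows 0,2 and columns 1,3
    np.testing.assert_array_equal(y[:, 4:6], x[:, :, ::2, 1::2])
    np.testing.assert_array_equal(y[:, 0:2], x[:, :, ::2, ::2])
    np.testing.assert_array_equal(y[:, 2:4], x[:, :, 1::2, ::2])
    np.testing.assert_array_equal(y[:, 6:8], x[:, :, 1::2, 1::2])


def test_space_to_depth_constant_bijective_mass():
    c = np.full((1, 3, 6, 8), 2.5)
    y = space_to_depth(Tensor(c)).numpy()
    np.testing.assert_array_equal(y, 2.5)
    x = RNG.normal(size=(2, 3, 6, 8))
    sd = space_to_depth(Tensor(x))
    np.testing.assert_array_equal(depth_to_space(sd).numpy(), x)
    assert np.isclose(sd.numpy().sum(), x.sum())  # activation mass conserved
    with pytest.raises(ValueError):
        space_to_depth(Tensor(np.zeros((1, 1, 5, 4))))


def test_spdconv_kernel_contract_and_composition_oracle():
    x = RNG.normal(size=(1, 3, 8, 8))
    W = RNG.normal(size=(16, 12, 3, 3))
    b = RNG.normal(size=16)
    out = spdconv(Tensor(x), Tensor(W), Tensor(b)).numpy()
    assert out.shape == (1, 16, 4, 4)
    # independent composition oracle: slice-subsample, then scipy correlation
    groups = [x[:, :, ::2, ::2], x[:, :, 1::2, ::2], x[:, :, ::2, 1::2], x[:, :, 1::2, 1::2]]
    sd = np.concatenate(groups, axis=1)
    ref = np.zeros_like(out)
    for o in range(16):
        ref[0, o] = sum(
            correlate2d(sd[0, c], W[o, c], mode="same") for c in range(12)
        ) + b[o]
    np.testing.assert_allclose(out, ref, atol=1e-9)
    with pytest.raises(ValueError):
        spdconv(Tensor(x), Tensor(RNG.normal(size=(16, 8, 3, 3))))


def test_spdconv_selector_kernel_is_strided_subsample():
    x = RNG.normal(size=(1, 1, 6, 6))
    W = np.zeros((1, 4, 3, 3))
    W[0, 0, 1, 1] = 1.0  # centre tap on group 0 (rows 0,2,..., cols 0,2,...)
    out = spdconv(Tensor(x), Tensor(W)).numpy()
    np.testing.assert_allclose(out[0, 0], x[0, 0, ::2, ::2], atol=1e-12)


# ---------------------------------------------------------------------------
# MDCM / DDAM / FMB


def zero_module(m):
    for p in m.parameters():
        p.data[:] = 0.0


def test_mdcm_residual_only_case():
    nn.set_seed(5)
    m = MDCM(4, strip_length=5)
    for k in (m.k_point, m.k_horiz, m.k_vert, m.k_square):
        zero_module(k)
    zero_module(m.ddam.wsca)  # forces the DDAM output to zero
    x = RNG.normal(size=(1, 4, 6, 6))
    np.testing.assert_allclose(m(Tensor(x)).numpy(), np.maximum(x, 0), atol=1e-12)


def test_mdcm_matches_depthwise_sliding_window_oracle():
    nn.set_seed(6)
    m = MDCM(4, strip_length=5)
    zero_module(m.ddam.wsca)
    x = RNG.normal(size=(1, 4, 8, 8))
    out = m(Tensor(x)).numpy()
    fin = gelu(
        np.einsum("oc,bchw->bohw", m.win.weight.data[:, :, 0, 0], x)
        + m.win.bias.data[None, :, None, None]
    )
    acc = x.copy()
    for conv in (m.k_point, m.k_horiz, m.k_vert, m.k_square):
        w = conv.weight.data
        for c in range(4):
            acc[0, c] += correlate2d(fin[0, c], w[c, 0], mode="same")
    np.testing.assert_allclose(out, np.maximum(acc, 0), atol=1e-9)


def test_mdcm_has_exactly_four_depthwise_kernel_sets():
    m = MDCM(8, strip_length=31)
    shapes = {m.k_point.weight.shape, m.k_horiz.weight.shape,
              m.k_vert.weight.shape, m.k_square.weight.shape}
    assert shapes == {(8, 1, 1, 1), (8, 1, 1, 31), (8, 1, 31, 1), (8, 1, 31, 31)}


def test_ddam_unit_gain_roundtrip_and_pooling_identity():
    nn.set_seed(7)
    d = DDAM(3)
    zero_module(d.wfca)
    zero_module(d.wsca)
    d.wfca.bias.data[:] = 1.0
    d.wsca.bias.data[:] = 1.0
    x = np.abs(RNG.normal(size=(1, 3, 5, 5))) + 0.05
    np.testing.assert_allclose(d(Tensor(x)).numpy(), x, atol=1e-10)
    c = np.full((2, 3, 4, 4), 1.7)
    np.testing.assert_allclose(
        nn.functional.global_avg_pool(Tensor(c)).numpy(), 1.7, atol=1e-14
    )


def test_ddam_matches_dense_dft_oracle():
    nn.set_seed(8)
    d = DDAM(1)
    for p in d.parameters():
        p.data = RNG.normal(size=p.shape)
    x = RNG.normal(size=(1, 1, 4, 4))
    out = d(Tensor(x)).numpy()
    gap = x.mean(axis=(2, 3), keepdims=True)
    wf = np.einsum("oc,bcxy->boxy", d.wfca.weight.data[:, :, 0, 0], gap) + d.wfca.bias.data.reshape(1, 1, 1, 1)
    ffca = np.abs(idft2(wf * dft2(x)))
    gap2 = ffca.mean(axis=(2, 3), keepdims=True)
    ws = np.einsum("oc,bcxy->boxy", d.wsca.weight.data[:, :, 0, 0], gap2) + d.wsca.bias.data.reshape(1, 1, 1, 1)
    np.testing.assert_allclose(out, ws * ffca, atol=1e-5)


def test_fmb_identity_zero_and_dft_oracle():
    nn.set_seed(9)
    f = FMB(2)
    x = RNG.normal(size=(1, 2, 4, 4))
    # alpha=0, beta=1 at init: exact pass-through
    np.testing.assert_allclose(f(Tensor(x)).numpy(), x, atol=1e-12)
    f.alpha.data[:] = 0.0
    f.beta.data[:] = 0.0
    np.testing.assert_allclose(f(Tensor(x)).numpy(), 0.0, atol=1e-12)
    # dense-DFT oracle with random modulation
    f.alpha.data = RNG.normal(size=(2, 1, 1))
    f.beta.data = RNG.normal(size=(2, 1, 1))
    out = f(Tensor(x)).numpy()
    w1, w2 = f.w1.weight.data[:, :, 0, 0], f.w2.weight.data[:, :, 0, 0]
    f1 = np.einsum("oc,bchw->bohw", w1, x)
    f2 = np.einsum("oc,bchw->bohw", w2, x)
    ref = f.alpha.data[None] * np.abs(idft2(f1 * dft2(f2))) + f.beta.data[None] * x
    np.testing.assert_allclose(out, ref, atol=1e-5)


def test_fft_roundtrip_magnitude_invariant():
    x = RNG.normal(size=(2, 3, 7, 5))
    rt = nn.cabs(nn.ifft2(nn.fft2(Tensor(x)))).numpy()
    np.testing.assert_allclose(rt, np.abs(x), atol=1e-6)


# ---------------------------------------------------------------------------
# CMKBlock


def test_cmk_split_counts_and_channel_preservation():
    assert CMKConfig(64).processed == 16  # 25% processed, 48 identity
    nn.set_seed(10)
    blk = CMKBlock(CMKConfig(8, strip_length=5))
    blk.eval()
    y = blk(Tensor(RNG.normal(size=(1, 8, 6, 6))))
    assert y.shape == (1, 8, 6, 6)
    with pytest.raises(ValueError):
        CMKConfig(2, split_fraction=0.1)  # too few channels to split


def test_cmk_identity_channels_bypass_processing():
    """Pre-fusion, the wide branch is independent of the MDCM/FMB parameters."""
    nn.set_seed(11)
    blk = CMKBlock(CMKConfig(8, strip_length=5))
    blk.eval()
    cp = blk.cfg.processed
    x = Tensor(RNG.normal(size=(1, 8, 6, 6)))
    y = blk.pre(x)
    ident_before = y.numpy()[:, cp:].copy()
    for p in list(blk.mdcm.parameters()) + list(blk.fmb.parameters()):
        p.data = p.data + 1.0
    y2 = blk.pre(x)
    np.testing.assert_array_equal(y2.numpy()[:, cp:], ident_before)


def test_cmk_param_count_analytic():
    cfg = CMKConfig(16, split_fraction=0.25, strip_length=7)
    blk = CMKBlock(cfg)
    c, cp, L = 16, 4, 7
    expect = (c * c + 2 * c) * 2  # pre/post 1x1 + BN
    expect += cp * cp + cp  # MDCM input 1x1 with bias
    expect += cp * (1 + L + L + L * L)  # four depthwise kernel sets
    expect += 2 * (cp * cp + cp)  # DDAM 1x1s
    expect += 2 * cp * cp + 2 * cp  # FMB convs + alpha/beta
    assert blk.num_params() == expect


# ---------------------------------------------------------------------------
# Neck graphs


def small_cfg(use_p2):
    return NeckConfig(in_channels=(8, 16, 32, 16), fusion_width=16, use_p2=use_p2,
                      split_fraction=0.25, strip_length=5, spd_reduce=8, p2_reduce=8)


def _pyramid(w=64):
    return [
        Tensor(RNG.normal(size=(1, 8, w // 4, w // 4))),
        Tensor(RNG.normal(size=(1, 16, w // 8, w // 8))),
        Tensor(RNG.normal(size=(1, 32, w // 16, w // 16))),
        Tensor(RNG.normal(size=(1, 16, w // 32, w // 32))),  # projected P5
    ]


def test_neck_shape_propagation_and_p2_entry():
    nn.set_seed(12)
    for neck in (MDFFN(small_cfg(True)), CCFM(small_cfg(False))):
        neck.eval()
        outs = neck(_pyramid(64))
        assert [o.shape for o in outs] == [(1, 16, 8, 8), (1, 16, 4, 4), (1, 16, 2, 2)]


def test_neck_zeroed_weights_give_zero_outputs():
    nn.set_seed(13)
    neck = MDFFN(small_cfg(True))
    neck.eval()
    for p in neck.parameters():
        p.data[:] = 0.0
    outs = neck(_pyramid(64))
    for o in outs:
        np.testing.assert_allclose(o.numpy(), 0.0, atol=1e-12)


def test_mdffn_requires_p2_when_configured():
    nn.set_seed(14)
    neck = MDFFN(small_cfg(True))
    feats = _pyramid(64)
    feats[0] = None
    with pytest.raises(ValueError):
        neck(feats)
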