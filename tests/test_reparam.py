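"""RepConv branch arithmetic: BN folding, zero-padding, fusion equivalence."""

import numpy as np
import pytest

from berrydetr import nn, reparam
from berrydetr.reparam import (
    BNStats,
    BranchParams,
    RepConv,
    fold_bn,
    fuse,
    fuse_repconvs,
    fused_forward,
    identity_kernel,
    pad_1x1_to_3x3,
    train_forward,
)

RNG = np.random.default_rng(7)


def silu(x):
    return x / (1 + np.exp(-x))


def conv_oracle(x, W, b, pad):
    """Direct sliding-window cross-correlation, (C,H,W) input."""
    co, ci, kh, kw = W.shape
    H, Wd = x.shape[1:]
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    out = np.zeros((co, H + 2 * pad - kh + 1, Wd + 2 * pad - kw + 1))
    for o in range(co):
        for i in range(out.shape[1]):
            for j in range(out.shape[2]):
                out[o, i, j] = (xp[:, i : i + kh, j : j + kw] * W[o]).sum() + b[o]
    return out


def random_bn(ch, seed):
    r = np.random.default_rng(seed)
    return BNStats(
        gamma=r.normal(1, 0.3, ch),
        beta=r.normal(0, 0.3, ch),
        mean=r.normal(0, 0.5, ch),
        var=r.uniform(0.2, 2.0, ch),
        eps=1e-5,
    )


def random_branch(cin, cout, seed, identity=None):
    r = np.random.default_rng(seed)
    identity = (cin == cout) if identity is None else identity
    return BranchParams(
        W3x3=r.normal(0, 0.5, (cout, cin, 3, 3)),
        b3x3=r.normal(0, 0.2, cout),
        W1x1=r.normal(0, 0.5, (cout, cin, 1, 1)),
        b1x1=r.normal(0, 0.2, cout),
        bn_main=random_bn(cout, seed + 1),
        bn_aux=random_bn(cout, seed + 2),
        bn_id=random_bn(cout, seed + 3) if identity else None,
        has_identity=identity,
    )


def test_zero_input_zero_params_gives_zero():
    p = BranchParams(
        W3x3=np.zeros((2, 2, 3, 3)),
        b3x3=np.zeros(2),
        W1x1=np.zeros((2, 2, 1, 1)),
        b1x1=np.zeros(2),
        bn_main=BNStats.identity(2),
        bn_aux=BNStats.identity(2),
        bn_id=BNStats.identity(2),
        has_identity=True,
    )
    out = train_forward(np.zeros((2, 4, 4)), p)
    np.testing.assert_array_equal(out, 0.0)


def test_pure_identity_branch_gives_silu_of_input():
    x = RNG.normal(size=(3, 5, 5))
    p = BranchParams(
        W3x3=np.zeros((3, 3, 3, 3)),
        b3x3=np.zeros(3),
        W1x1=np.zeros((3, 3, 1, 1)),
        b1x1=np.zeros(3),
        bn_main=BNStats.identity(3),
        bn_aux=BNStats.identity(3),
        bn_id=BNStats.identity(3),
        has_identity=True,
    )
    np.testing.assert_allclose(train_forward(x, p), silu(x), atol=1e-12)


def test_train_forward_matches_sliding_window_oracle():
    x = RNG.normal(size=(1, 5, 5))
    p = random_branch(1, 2, seed=11)
    got = train_forward(x, p)
    y3 = p.bn_main.apply(conv_oracle(x, p.W3x3, p.b3x3, pad=1))
    y1 = p.bn_aux.apply(conv_oracle(x, p.W1x1, p.b1x1, pad=0))
    np.testing.assert_allclose(got, silu(y3 + y1), atol=1e-5)


def test_channel_mismatch_raises():
    p = random_branch(2, 3, seed=1)
    with pytest.raises(ValueError):
        train_forward(np.zeros((4, 5, 5)), p)
    with pytest.raises(ValueError):
        BranchParams(
            W3x3=np.zeros((3, 2, 3, 3)),
            b3x3=np.zeros(3),
            W1x1=np.zeros((3, 2, 1, 1)),
            b1x1=np.zeros(3),
            bn_main=BNStats.identity(3),
            bn_aux=BNStats.identity(3),
            bn_id=BNStats.identity(3),
            has_identity=True,  # non-square channel map
        )
    with pytest.raises(ValueError):
        BNStats(np.ones(2), np.zeros(2), np.zeros(2), np.array([-1.0, 1.0]), eps=0.0)


def test_fold_bn_identity_stats_is_noop():
    W = RNG.normal(size=(3, 2, 3, 3))
    Wf, bf = fold_bn(W, BNStats.identity(3))
    np.testing.assert_array_equal(Wf, W)
    np.testing.assert_array_equal(bf, 0.0)


def test_fold_bn_equals_normalize_after_conv():
    W = RNG.normal(size=(3, 2, 3, 3))
    b = RNG.normal(size=3)
    bn = random_bn(3, 21)
    x = RNG.normal(size=(2, 4, 4))
    Wf, bf = fold_bn(W, bn, b)
    np.testing.assert_allclose(
        conv_oracle(x, Wf, bf, pad=1), bn.apply(conv_oracle(x, W, b, pad=1)), atol=1e-5
    )


def test_identity_branch_folds_to_scaled_diagonal_unit_kernel():
    bn = random_bn(4, 33)
    Wf, bf = fold_bn(identity_kernel(4), bn)
    s = bn.gamma / np.sqrt(bn.var + bn.eps)
    expect = np.zeros((4, 4, 3, 3))
    expect[np.arange(4), np.arange(4), 1, 1] = s
    np.testing.assert_allclose(Wf, expect, atol=1e-12)
    np.testing.assert_allclose(bf, bn.beta - bn.mean * s, atol=1e-12)


def test_pad_1x1_places_value_at_centre():
    W1 = np.full((1, 1, 1, 1), 7.0)
    p = BranchParams(
        W3x3=np.zeros((1, 1, 3, 3)),
        b3x3=np.zeros(1),
        W1x1=W1,
        b1x1=np.zeros(1),
        bn_main=BNStats.identity(1),
        bn_aux=BNStats.identity(1),
        bn_id=None,
        has_identity=False,
    )
    fp = fuse(p)
    expect = np.zeros((1, 1, 3, 3))
    expect[0, 0, 1, 1] = 7.0
    np.testing.assert_array_equal(fp.Wequiv, expect)
    np.testing.assert_array_equal(fp.bequiv, 0.0)
    # padding preserves the operator on interior and borders
    x = RNG.normal(size=(1, 6, 6))
    np.testing.assert_allclose(
        conv_oracle(x, pad_1x1_to_3x3(W1), np.zeros(1), pad=1),
        conv_oracle(x, W1, np.zeros(1), pad=0),
        atol=1e-12,
    )


def test_all_zero_branches_fuse_to_zero():
    p = BranchParams(
        W3x3=np.zeros((2, 2, 3, 3)),
        b3x3=np.zeros(2),
        W1x1=np.zeros((2, 2, 1, 1)),
        b1x1=np.zeros(2),
        bn_main=BNStats(np.ones(2), np.zeros(2), np.zeros(2), np.ones(2), 0.0),
        bn_aux=BNStats(np.ones(2), np.zeros(2), np.zeros(2), np.ones(2), 0.0),
        bn_id=None,
        has_identity=False,
    )
    fp = fuse(p)
    np.testing.assert_array_equal(fp.Wequiv, 0.0)
    np.testing.assert_array_equal(fp.bequiv, 0.0)


def test_fusion_equivalence_sweep_100_random_configs():
    """Fused single-kernel path equals the training path to 1e-5 on random inputs."""
    max_dev = 0.0
    for k in range(100):
        r = np.random.default_rng(1000 + k)
        cin = int(r.integers(1, 5))
        cout = cin if k % 2 == 0 else int(r.integers(1, 5))
        p = random_branch(cin, cout, seed=2000 + k)
        x = r.normal(size=(cin, 8, 8)) if k % 3 else r.normal(size=(2, cin, 8, 8))
        dev = np.abs(train_forward(x, p) - fused_forward(x, fuse(p))).max()
        max_dev = max(max_dev, dev)
    assert max_dev < 1e-5


def test_fused_parameter_count_closed_form():
    p = random_branch(3, 5, seed=77, identity=False)
    fp = fuse(p)
    assert fp.Wequiv.size + fp.bequiv.size == 5 * 3 * 9 + 5


def test_repconv_module_fusion_and_param_drop():
    nn.set_seed(42)
    m = RepConv(4, 4)
    # populate plausible running stats, then compare in eval mode
    x = nn.Tensor(RNG.normal(size=(2, 4, 6, 6)))
    m.train()
    for _ in range(3):
        m(x)
    m.eval()
    before = m(x).numpy()
    n_train_params = m.num_params()
    assert fuse_repconvs(m) == 1
    after = m(x).numpy()
    np.testing.assert_allclose(after, before, atol=1e-5)
    assert m.num_params() == 4 * 4 * 9 + 4 < n_train_params
    # idempotent
    assert fuse_repconvs(m) == 0


def test_checkpoint_conversion_roundtrip(tmp_path):
    """Fused state can be saved and re-loaded into a deployed model."""
    nn.set_seed(9)
    m = RepConv(3, 3)
    m.eval()
    fuse_repconvs(m)
    state = m.state_dict()
    path = tmp_path / "fused.npz"
    np.savez(path, **state)
    loaded = dict(np.load(path))
    m2 = RepConv(3, 3)
    m2.eval()
    fuse_repconvs(m2)
    m2.load_state_dict(loaded)
    x = nn.Tensor(RNG.normal(size=(1, 3, 4, 4)))
    np.testing.assert_allclose(m2(x).numpy(), m(x).numpy(), atol=1e-12)
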