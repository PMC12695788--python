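"""Finite-difference gradient checks and numerics of the autodiff core."""

import numpy as np
import pytest

from berrydetr import nn
from berrydetr.nn import Tensor, functional as F

RNG = np.random.default_rng(1234)


def numeric_grad(fn, x: np.ndarray, eps=1e-6):
    """Central finite differences of a scalar-valued fn of one array."""
    g = np.zeros_like(x)
    flat = x.reshape(-1)
    gf = g.reshape(-1)
    for i in range(flat.size):
        old = flat[i]
        flat[i] = old + eps
        fp = fn(x)
        flat[i] = old - eps
        fm = fn(x)
        flat[i] = old
        gf[i] = (fp - fm) / (2 * eps)
    return g


def check_op(build, shape, atol=1e-7, seed=0):
    """build(Tensor) -> Tensor; compares backprop grad with finite differences."""
    x0 = np.random.default_rng(seed).normal(size=shape)
    w = np.random.default_rng(seed + 1).normal(size=build(Tensor(x0)).shape)

    def scalar(arr):
        return float((build(Tensor(arr)).numpy() * w).sum())

    t = Tensor(x0.copy(), requires_grad=True)
    out = build(t)
    out.backward(w)
    num = numeric_grad(scalar, x0.copy())
    np.testing.assert_allclose(t.grad, num, atol=atol, rtol=1e-5)


@pytest.mark.parametrize(
    "build,shape",
    [
        (lambda x: (x * x + 3 * x).sum(), (4, 3)),
        (lambda x: (x / (x * x + 2.0)), (5,)),
        (lambda x: x.exp().log(), (4,)),
        (lambda x: x.sigmoid(), (6,)),
        (lambda x: x.tanh(), (6,)),
        (lambda x: x.silu(), (6,)),
        (lambda x: x.gelu(), (6,)),
        (lambda x: (x + 1.5).sqrt(), (5,)),
        (lambda x: x.softmax(axis=-1), (2, 5)),
        (lambda x: x.mean(axis=0), (3, 4)),
        (lambda x: x.reshape(6, 2), (3, 4)),
        (lambda x: x.transpose(1, 0), (3, 4)),
        (lambda x: x[1:, ::2], (3, 4)),
        (lambda x: x @ Tensor(np.arange(12.0).reshape(4, 3)), (2, 4)),
        (lambda x: nn.concat([x, x * 2], axis=1), (2, 3)),
        (lambda x: nn.pad2d(x, 1, 2), (1, 2, 3, 3)),
        (lambda x: x.max(axis=1), (3, 4)),
    ],
)
def test_elementwise_and_shape_grads(build, shape):
    check_op(build, shape)


def test_broadcast_add_mul_grads():
    check_op(lambda x: x + Tensor(np.ones((1, 4))), (3, 4))
    a = np.random.default_rng(5).normal(size=(3, 1))
    check_op(lambda x: x * Tensor(a), (3, 4))
    # gradient w.r.t. the broadcast operand
    x0 = np.random.default_rng(6).normal(size=(3, 4))
    b = Tensor(np.random.default_rng(7).normal(size=(1, 4)), requires_grad=True)
    (Tensor(x0) * b).sum().backward()
    np.testing.assert_allclose(b.grad, x0.sum(axis=0, keepdims=True))


def test_conv2d_matches_scipy_and_grads():
    from scipy.signal import correlate2d

    x0 = RNG.normal(size=(1, 2, 6, 6))
    w0 = RNG.normal(size=(3, 2, 3, 3))
    out = F.conv2d(Tensor(x0), Tensor(w0), padding=1).numpy()
    for o in range(3):
        ref = sum(correlate2d(x0[0, c], w0[o, c], mode="same") for c in range(2))
        np.testing.assert_allclose(out[0, o], ref, atol=1e-10)
    # gradients, including stride
    for stride, pad in [(1, 1), (2, 1), (2, 0)]:
        wt = Tensor(w0.copy(), requires_grad=True)
        bt = Tensor(np.zeros(3), requires_grad=True)
        check_op(lambda x: F.conv2d(x, wt, bt, stride=stride, padding=pad), (2, 2, 5, 5))


def test_conv2d_weight_bias_grads():
    x0 = RNG.normal(size=(2, 3, 5, 5))
    w = Tensor(RNG.normal(size=(4, 3, 3, 3)), requires_grad=True)
    b = Tensor(RNG.normal(size=4), requires_grad=True)
    seedw = np.random.default_rng(9).normal(size=(2, 4, 5, 5))
    out = F.conv2d(Tensor(x0), w, b, padding=1)
    out.backward(seedw)

    def fw(arr):
        return float(
            (F.conv2d(Tensor(x0), Tensor(arr), Tensor(b.data), padding=1).numpy() * seedw).sum()
        )

    np.testing.assert_allclose(w.grad, numeric_grad(fw, w.data.copy()), atol=1e-6)
    np.testing.assert_allclose(b.grad, seedw.sum(axis=(0, 2, 3)), atol=1e-10)


def test_depthwise_conv_matches_dense_and_grads():
    x0 = RNG.normal(size=(1, 3, 8, 8))
    w0 = RNG.normal(size=(3, 1, 5, 1))
    out = F.depthwise_conv2d(Tensor(x0), Tensor(w0)).numpy()
    # dense oracle: block-diagonal kernel
    wd = np.zeros((3, 3, 5, 1))
    for c in range(3):
        wd[c, c] = w0[c, 0]
    ref = F.conv2d(Tensor(x0), Tensor(wd), padding=(2, 0)).numpy()
    np.testing.assert_allclose(out, ref, atol=1e-9)
    wt = Tensor(w0.copy(), requires_grad=True)
    check_op(lambda x: F.depthwise_conv2d(x, wt), (1, 3, 6, 6), atol=1e-6)
    # weight gradient
    xt = Tensor(x0)
    wt2 = Tensor(w0.copy(), requires_grad=True)
    seedw = np.random.default_rng(3).normal(size=out.shape)
    F.depthwise_conv2d(xt, wt2).backward(seedw)

    def fw(arr):
        return float((F.depthwise_conv2d(xt, Tensor(arr)).numpy() * seedw).sum())

    np.testing.assert_allclose(wt2.grad, numeric_grad(fw, w0.copy()), atol=1e-6)


def test_maxpool_avgpool_upsample():
    x0 = RNG.normal(size=(1, 2, 6, 6))
    check_op(lambda x: F.maxpool2d(x, 3, 2, 1), (1, 2, 6, 6))
    check_op(lambda x: F.avgpool2d(x, 2), (1, 2, 6, 6))
    check_op(lambda x: F.upsample_nearest2x(x), (1, 2, 3, 3))
    up = F.upsample_nearest2x(Tensor(x0)).numpy()
    assert up.shape == (1, 2, 12, 12)
    np.testing.assert_allclose(up[0, 0, ::2, ::2], x0[0, 0])


def test_spectral_roundtrip_and_grads():
    x0 = np.abs(RNG.normal(size=(2, 3, 4, 4))) + 0.1
    rt = nn.cabs(nn.ifft2(nn.fft2(Tensor(x0)))).numpy()
    np.testing.assert_allclose(rt, x0, atol=1e-12)
    # gradient through |ifft2(a ⊙ fft2(x))|
    a = Tensor(RNG.normal(size=(1, 3, 4, 4)))
    check_op(lambda x: nn.cabs(nn.ifft2(nn.cmul(a, nn.fft2(x)))), (1, 3, 4, 4), atol=1e-6)
    # gradient w.r.t. the real spatial mask in a complex product
    xfix = Tensor(RNG.normal(size=(1, 2, 4, 4)))
    check_op(lambda m: nn.cabs(nn.ifft2(nn.cmul(m, nn.fft2(xfix)))), (1, 2, 4, 4), atol=1e-6)


def test_bilinear_sample_grads_both_inputs():
    x0 = RNG.normal(size=(1, 2, 5, 5))
    c0 = RNG.uniform(0.6, 3.4, size=(1, 2, 2, 3, 2))
    ct = Tensor(c0.copy(), requires_grad=True)
    check_op(lambda x: F.bilinear_sample(x, ct), (1, 2, 5, 5))
    ct.zero_grad()
    xt = Tensor(x0)
    seedw = np.random.default_rng(11).normal(size=(1, 2, 2, 2, 3))
    out = F.bilinear_sample(xt, ct)
    out.backward(seedw)

    def fc(arr):
        return float((F.bilinear_sample(xt, Tensor(arr)).numpy() * seedw).sum())

    np.testing.assert_allclose(ct.grad, numeric_grad(fc, c0.copy()), atol=1e-5)


def test_attention_and_layernorm_grads():
    nn.set_seed(3)
    att = nn.MultiheadAttention(8, 2)
    ln = nn.LayerNorm(8)
    check_op(lambda x: ln(att(x)), (1, 3, 8), atol=1e-6)


def test_batchnorm_train_eval_semantics():
    nn.set_seed(4)
    bn = nn.BatchNorm2d(3, momentum=0.5)
    x0 = RNG.normal(size=(2, 3, 4, 4)) * 2 + 1
    y = bn(Tensor(x0)).numpy()
    np.testing.assert_allclose(y.mean(axis=(0, 2, 3)), 0, atol=1e-10)
    np.testing.assert_allclose(y.std(axis=(0, 2, 3)), 1, atol=1e-3)
    bn.eval()
    y2 = bn(Tensor(x0)).numpy()
    mu = 0.5 * x0.mean(axis=(0, 2, 3))
    assert np.all(np.abs(y2.mean(axis=(0, 2, 3))) < np.abs(x0.mean(axis=(0, 2, 3)) - mu) + 1.0)
    check_op(lambda x: bn(x), (2, 3, 4, 4), atol=1e-6)


def test_mac_counter_closed_forms():
    """One 3x3 conv 64->128 on 160x160 costs 64*128*9*160*160 MACs."""
    conv = nn.Conv2d(64, 128, 3, padding=1, bias=True)
    x = Tensor(np.zeros((1, 64, 160, 160)))
    with nn.count_macs() as ctr:
        with nn.no_grad():
            conv(x)
    macs1 = ctr.macs
    assert macs1 == 64 * 128 * 9 * 160 * 160
    # doubling input area doubles conv MACs
    with nn.count_macs() as ctr2:
        with nn.no_grad():
            conv(Tensor(np.zeros((1, 64, 160, 320))))
    assert ctr2.macs == 2 * macs1


def test_adamw_and_sgd_reduce_quadratic_loss():
    for opt_cls in (nn.AdamW, nn.SGD):
        p = nn.Parameter(np.array([3.0, -2.0]))
        opt = opt_cls([p], lr=0.1)
        losses = []
        for _ in range(50):
            opt.zero_grad()
            loss = (p * p).sum()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        assert losses[-1] < 0.1 * losses[0]
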