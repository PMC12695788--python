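"""Neural-network primitives (convolution, pooling, sampling) on the autodiff core.

All ops take and return :class:`~berrydetr.nn.autograd.Tensor` in NCHW layout.
A process-global multiply-accumulate counter can be armed with
:func:`count_macs`; every dense op then adds its analytic MAC cost, which is
how forward-pass GFLOPs are measured (FFTs and interpolation are excluded
from the count by convention — only MAC-bearing dense ops are tallied).
"""

from __future__ import annotations

import contextlib

import numpy as np
from scipy.signal import fftconvolve

from .autograd import Tensor, as_tensor

# ---------------------------------------------------------------------------
# MAC counting


class _MacCounter:
    __slots__ = ("enabled", "macs")

    def __init__(self):
        self.enabled = False
        self.macs = 0


MAC_COUNTER = _MacCounter()


@contextlib.contextmanager
def count_macs():
    """Arm the global MAC counter; yields the counter object."""
    MAC_COUNTER.enabled = True
    MAC_COUNTER.macs = 0
    try:
        yield MAC_COUNTER
    finally:
        MAC_COUNTER.enabled = False


def _add_macs(n: int):
    if MAC_COUNTER.enabled:
        MAC_COUNTER.macs += int(n)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Matrix product that participates in MAC counting."""
    a, b = as_tensor(a), as_tensor(b)
    if MAC_COUNTER.enabled:
        out_shape = np.broadcast_shapes(a.shape[:-2], b.shape[:-2])
        batch = int(np.prod(out_shape)) if out_shape else 1
        _add_macs(batch * a.shape[-2] * a.shape[-1] * b.shape[-1])
    return a @ b


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """``x @ w.T + b`` with w of shape (out, in)."""
    out = matmul(x, w.transpose(1, 0))
    if b is not None:
        out = out + b
    return out


# ---------------------------------------------------------------------------
# Convolution


def _sliding_windows(xp: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """(B, C, Hp, Wp) -> (B, C, OH, OW, kh, kw) view."""
    v = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    return v[:, :, ::stride, ::stride]


def conv2d(
    x: Tensor,
    w: Tensor,
    b: Tensor | None = None,
    stride: int = 1,
    padding: int | tuple = 0,
) -> Tensor:
    """2-D cross-correlation, kernel (Cout, Cin, kh, kw), NCHW input."""
    x, w = as_tensor(x), as_tensor(w)
    B, C, H, W = x.shape
    Cout, Cin, kh, kw = w.shape
    if Cin != C:
        raise ValueError(f"conv2d channel mismatch: input has {C}, kernel expects {Cin}")
    ph, pw = (padding, padding) if isinstance(padding, int) else padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    OH = (H + 2 * ph - kh) // stride + 1
    OW = (W + 2 * pw - kw) // stride + 1
    cols = _sliding_windows(xp, kh, kw, stride)  # B,C,OH,OW,kh,kw
    cols2 = cols.transpose(0, 2, 3, 1, 4, 5).reshape(B, OH * OW, C * kh * kw)
    wmat = w.data.reshape(Cout, C * kh * kw)
    out_data = (cols2 @ wmat.T).transpose(0, 2, 1).reshape(B, Cout, OH, OW)
    _add_macs(B * OH * OW * kh * kw * C * Cout)
    if b is not None:
        out_data = out_data + b.data.reshape(1, Cout, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def bw(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(B, OH * OW, Cout)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            gw = np.einsum("bpo,bpk->ok", gmat, cols2)
            w._accumulate(gw.reshape(Cout, C, kh, kw))
        if x.requires_grad:
            dcols = (gmat @ wmat).reshape(B, OH, OW, C, kh, kw)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i : i + OH * stride : stride, j : j + OW * stride : stride] += (
                        dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                    )
            x._accumulate(dxp[:, :, ph : ph + H, pw : pw + W])

    return Tensor._make(out_data, parents, bw)


def depthwise_conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Per-channel ("depthwise") correlation with odd kernel, stride 1, 'same' padding.

    FFT-based so that large strip/square kernels (1x31, 31x1, 31x31) stay cheap;
    MACs are nevertheless tallied at the sliding-window cost, matching the usual
    convention of architecture complexity tables.
    """
    x, w = as_tensor(x), as_tensor(w)
    B, C, H, W = x.shape
    Cw, one, kh, kw = w.shape
    if Cw != C or one != 1:
        raise ValueError(f"depthwise kernel shape {w.shape} incompatible with {C} channels")
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError("depthwise_conv2d requires odd kernel sizes")
    wk = w.data[:, 0]  # (C, kh, kw)
    flip = wk[:, ::-1, ::-1]
    out_data = fftconvolve(x.data, flip[None], mode="same", axes=(2, 3))
    _add_macs(B * H * W * kh * kw * C)
    if b is not None:
        out_data = out_data + b.data.reshape(1, C, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def bw(g):
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            x._accumulate(fftconvolve(g, wk[None], mode="same", axes=(2, 3)))
        if w.requires_grad:
            ph, pw = kh // 2, kw // 2
            xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
            gw = fftconvolve(xp, g[:, :, ::-1, ::-1], mode="valid", axes=(2, 3))
            w._accumulate(gw.sum(axis=0)[:, None])

    return Tensor._make(out_data, parents, bw)


# ---------------------------------------------------------------------------
# Pooling / resampling


def maxpool2d(x: Tensor, kernel: int = 3, stride: int = 2, padding: int = 1) -> Tensor:
    x = as_tensor(x)
    B, C, H, W = x.shape
    fill = -np.inf
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding,) * 2, (padding,) * 2), constant_values=fill)
    win = _sliding_windows(xp, kernel, kernel, stride)  # B,C,OH,OW,kh,kw
    B_, C_, OH, OW = win.shape[:4]
    flat = win.reshape(B, C, OH, OW, kernel * kernel)
    arg = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def bw(g):
        dxp = np.zeros_like(xp)
        ki, kj = np.unravel_index(arg, (kernel, kernel))
        oi = np.arange(OH)[None, None, :, None] * stride
        oj = np.arange(OW)[None, None, None, :] * stride
        bi = np.arange(B)[:, None, None, None]
        ci = np.arange(C)[None, :, None, None]
        np.add.at(dxp, (bi, ci, oi + ki, oj + kj), g)
        x._accumulate(dxp[:, :, padding : padding + H, padding : padding + W])

    return Tensor._make(out_data, (x,), bw)


def avgpool2d(x: Tensor, kernel: int, stride: int | None = None) -> Tensor:
    """Non-overlapping average pooling (kernel == stride)."""
    stride = stride or kernel
    if stride != kernel:
        raise NotImplementedError("avgpool2d supports kernel == stride only")
    B, C, H, W = x.shape
    if H % kernel or W % kernel:
        raise ValueError("avgpool2d requires divisible spatial dims")
    r = x.reshape(B, C, H // kernel, kernel, W // kernel, kernel)
    return r.mean(axis=(3, 5))


def global_avg_pool(x: Tensor) -> Tensor:
    """(B, C, H, W) -> (B, C, 1, 1) mean over the spatial plane."""
    return x.mean(axis=(2, 3), keepdims=True)


def upsample_nearest2x(x: Tensor) -> Tensor:
    a = x
    B, C, H, W = a.shape
    data = np.repeat(np.repeat(a.data, 2, axis=2), 2, axis=3)

    def bw(g):
        a._accumulate(g.reshape(B, C, H, 2, W, 2).sum(axis=(3, 5)))

    return Tensor._make(data, (a,), bw)


def bilinear_sample(x: Tensor, coords: Tensor) -> Tensor:
    """Bilinear resampling at continuous coordinates.

    x: (B, C, H, W); coords: (B, ..., 2) with last axis = (col, row) in pixel
    units, origin at the top-left pixel centre. Out-of-bounds neighbours
    contribute zero, so values fade linearly to 0 beyond the border.
    Differentiable in both the image and the coordinates.
    Returns (B, C, ...) matching the coordinate batch layout.
    """
    x, coords = as_tensor(x), as_tensor(coords)
    if np.isnan(coords.data).any():
        raise ValueError("bilinear_sample: NaN coordinates")
    B, C, H, W = x.shape
    lead = coords.shape[1:-1]  # e.g. (Hp, Wp, N)
    L = int(np.prod(lead)) if lead else 1
    px = coords.data[..., 0].reshape(B, L)
    py = coords.data[..., 1].reshape(B, L)
    x0 = np.floor(px)
    y0 = np.floor(py)
    fx = px - x0
    fy = py - y0
    x0i, y0i = x0.astype(np.int64), y0.astype(np.int64)

    flat = x.data.reshape(B, C, H * W)
    bidx = np.arange(B)[:, None]

    corners = []
    for dy, dx_, wgt, dwx, dwy in (
        (0, 0, (1 - fx) * (1 - fy), -(1 - fy), -(1 - fx)),
        (0, 1, fx * (1 - fy), (1 - fy), -fx),
        (1, 0, (1 - fx) * fy, -fy, (1 - fx)),
        (1, 1, fx * fy, fy, fx),
    ):
        xi, yi = x0i + dx_, y0i + dy
        valid = (xi >= 0) & (xi < W) & (yi >= 0) & (yi < H)
        idx = np.clip(yi, 0, H - 1) * W + np.clip(xi, 0, W - 1)
        vals = np.take_along_axis(flat, idx[:, None, :], axis=2)  # (B, C, L)
        vals = vals * valid[:, None, :]
        corners.append((idx, valid, wgt, dwx, dwy, vals))

    out_data = sum(w[:, None, :] * v for (_, _, w, _, _, v) in corners)
    out_data = out_data.reshape((B, C) + lead)

    def bw(g):
        gf = g.reshape(B, C, L)
        if x.requires_grad:
            dflat = np.zeros_like(flat)
            cidx = np.arange(C)[None, :, None]
            for idx, valid, wgt, _, _, _ in corners:
                contrib = gf * (wgt * valid)[:, None, :]
                np.add.at(dflat, (bidx[:, :, None], cidx, idx[:, None, :]), contrib)
            x._accumulate(dflat.reshape(B, C, H, W))
        if coords.requires_grad:
            gx = np.zeros((B, L))
            gy = np.zeros((B, L))
            for _, valid, _, dwx, dwy, vals in corners:
                s = (gf * vals).sum(axis=1)  # weights already folded validity into vals
                gx += s * dwx * valid
                gy += s * dwy * valid
            gc = np.stack([gx, gy], axis=-1).reshape(coords.shape)
            coords._accumulate(gc)

    return Tensor._make(out_data, (x, coords), bw)
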