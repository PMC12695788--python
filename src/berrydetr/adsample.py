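"""Adaptive deformable downsampling (ADSample).

Instead of a fixed strided convolution, each output location samples N
continuous positions of the input: a regular stride-spaced base grid P0,
plus a fixed pattern template Pn laying the N = n^2 points out as an n-by-n
grid, plus offsets predicted from the input by a small stride-matched 3x3
convolution:

    P = P0 + Pn + delta,      delta = W_offset * x + b_offset

The features at the continuous positions are read with bilinear
interpolation (out-of-bounds neighbours contribute zero), stacked along a
new axis, and aggregated with an (N,1) column convolution followed by SiLU.
With zero offsets the module reduces exactly to a patterned strided
convolution; the offset convolution is zero-initialized so training starts
from that regular behaviour.

Coordinate convention: origin at pixel (0,0) top-left, x = column,
y = row, unnormalized pixel units. Offset channels interleave as
(x_0, y_0, x_1, y_1, ...).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor, functional as F


def pattern_template(N: int) -> np.ndarray:
    """Fixed (2N, 1, 1) n-by-n grid layout of the N sampling points.

    Even n uses offsets {0, ..., n-1} (anchored at the window's top-left, so a
    stride-n window is covered exactly); odd n uses centred offsets
    {-(n//2), ..., n//2}, matching the receptive field of an odd strided kernel.
    """
    n = int(round(np.sqrt(N)))
    if n * n != N or n < 1:
        raise ValueError(f"N must be a square number >= 1, got {N}")
    offs = np.arange(n) if n % 2 == 0 else np.arange(n) - n // 2
    pn = np.empty(2 * N)
    k = 0
    for dy in offs:
        for dx in offs:
            pn[2 * k] = dx
            pn[2 * k + 1] = dy
            k += 1
    return pn.reshape(2 * N, 1, 1)


def base_grid(out_h: int, out_w: int, stride: int, N: int) -> np.ndarray:
    """(2N, H', W') regular grid: every point of a location shares (j*s, i*s)."""
    xs = np.arange(out_w) * stride
    ys = np.arange(out_h) * stride
    gx = np.broadcast_to(xs[None, :], (out_h, out_w))
    gy = np.broadcast_to(ys[:, None], (out_h, out_w))
    g = np.stack([gx, gy], axis=0)  # (2, H', W')
    return np.tile(g, (N, 1, 1)).astype(float)


@dataclass
class SamplingField:
    """Per-output-location sampling coordinates decomposition (P = P0 + Pn + delta)."""

    P0: np.ndarray  # (2N, H', W')
    Pn: np.ndarray  # (2N, 1, 1)
    delta: np.ndarray  # (2N, H', W') or (B, 2N, H', W')
    N: int

    def __post_init__(self):
        n = int(round(np.sqrt(self.N)))
        if n * n != self.N:
            raise ValueError("N must be a perfect square")
        for name in ("P0", "Pn", "delta"):
            a = getattr(self, name)
            if a.shape[-3] != 2 * self.N:
                raise ValueError(f"{name} must have 2N coordinate channels")


def build_coords(f: SamplingField) -> np.ndarray:
    """P = P0 + Pn + delta, continuous (unclamped) coordinates."""
    return f.P0 + f.Pn + f.delta


@dataclass
class BilinearStencil:
    q_lt: tuple
    q_rt: tuple
    q_lb: tuple
    q_rb: tuple
    w_lt: float
    w_rt: float
    w_lb: float
    w_rb: float


def bilinear_weights(p) -> BilinearStencil:
    """Four-neighbour stencil of a continuous point p = (px, py).

    w_corner = max(0, 1-|px-qx|) * max(0, 1-|py-qy|); for the floor/floor+1
    neighbours the weights are the standard bilinear ones and sum to 1.
    """
    px, py = float(p[0]), float(p[1])
    x0, y0 = int(np.floor(px)), int(np.floor(py))
    x1, y1 = x0 + 1, y0 + 1

    def w(qx, qy):
        return max(0.0, 1.0 - abs(px - qx)) * max(0.0, 1.0 - abs(py - qy))

    return BilinearStencil(
        q_lt=(x0, y0),
        q_rt=(x1, y0),
        q_lb=(x0, y1),
        q_rb=(x1, y1),
        w_lt=w(x0, y0),
        w_rt=w(x1, y0),
        w_lb=w(x0, y1),
        w_rb=w(x1, y1),
    )


def resample(x: Tensor, P) -> Tensor:
    """Bilinear gather at coordinates P.

    x: (B, C, H, W); P: (B, 2N, H', W') or (2N, H', W') coordinate planes.
    Returns (B, C, H', W', N).
    """
    x = nn.as_tensor(x)
    P = nn.as_tensor(P)
    if P.ndim == 3:
        P = P.reshape((1,) + P.shape)
    B, twoN, Hp, Wp = P.shape
    N = twoN // 2
    # (B, 2N, H', W') -> (B, H', W', N, 2)
    coords = P.reshape(B, N, 2, Hp, Wp).transpose(0, 3, 4, 1, 2)
    return F.bilinear_sample(x, coords)


class ADSample(nn.Module):
    """Learnable deformable downsampling layer."""

    def __init__(self, in_ch: int, out_ch: int, stride: int = 2, N: int = 4,
                 init_zero_offsets: bool = True):
        super().__init__()
        self.in_ch, self.out_ch, self.stride, self.N = in_ch, out_ch, stride, N
        self.pattern = pattern_template(N)  # validates N
        self.offset_conv = nn.Conv2d(in_ch, 2 * N, 3, stride=stride, padding=1, bias=True)
        if init_zero_offsets:
            self.offset_conv.weight.data[:] = 0.0
            self.offset_conv.bias.data[:] = 0.0
        rng_bound = np.sqrt(1.0 / (in_ch * N))
        from .nn.modules import _INIT_RNG

        self.col_weight = nn.Parameter(
            _INIT_RNG.uniform(-rng_bound, rng_bound, (out_ch, in_ch, N))
        )
        self.col_bias = nn.Parameter(np.zeros(out_ch))

    def predict_offsets(self, x: Tensor) -> Tensor:
        """delta = W_offset * x + b_offset, at output resolution, 2N channels."""
        return self.offset_conv(x)

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        if H % self.stride or W % self.stride:
            raise ValueError(f"stride {self.stride} must divide input dims {H}x{W}")
        delta = self.predict_offsets(x)
        Hp, Wp = delta.shape[-2:]
        p0 = base_grid(Hp, Wp, self.stride, self.N)
        coords = delta + Tensor(p0 + self.pattern)
        sampled = resample(x, coords)  # (B, C, H', W', N)
        # column aggregation: (N,1) kernel as a dense contraction over (C, N)
        flat = sampled.transpose(0, 2, 3, 1, 4).reshape(B, Hp * Wp, C * self.N)
        wmat = self.col_weight.reshape(self.out_ch, C * self.N)
        out = F.linear(flat, wmat, self.col_bias)
        out = out.transpose(0, 2, 1).reshape(B, self.out_ch, Hp, Wp)
        return out.silu()


def adsample_factory(stride: int = 2, N: int = 4):
    """Downsample factory for backbone/neck assembly."""

    def make(in_ch: int, out_ch: int) -> ADSample:
        return ADSample(in_ch, out_ch, stride=stride, N=N)

    return make
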