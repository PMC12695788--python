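"""Multi-domain feature-fusion neck (MDFFN) and the baseline CCFM neck.

The neck takes the backbone pyramid, runs a top-down (upsample + fuse) and a
bottom-up (downsample + fuse) pass at a fixed fusion width, and hands three
maps at strides 8/16/32 to the decoder. The multi-domain variant differs from
the plain concatenation-convolution baseline (CCFM) in three ways:

* downsampling inside the neck is lossless: a space-to-depth rearrangement
  moves each 2x2 neighbourhood into 4x channels before a 3x3 convolution
  (SPDConv), instead of discarding pixels with a strided convolution;
* every fusion node is a cross-stage multi-kernel block (CMKBlock): a thin
  processed branch (25% of channels by default) runs through depthwise
  kernels of four geometries (1x1, 1x31, 31x1, 31x31), dual-domain attention
  and a frequency-modulation block, while the remaining channels pass through
  untouched;
* the high-resolution P2 level joins the fusion: it is space-to-depth
  downsampled to stride 8 and merged into the finest fusion node (it is not
  given to the decoder, keeping decoder cost unchanged).

FFT convention (fixed): unnormalized forward transform, 1/(H*W) inverse —
numpy's default. Magnitudes are taken after the inverse transform, so the
convention is observable and pinned by the oracle tests.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import nn
from .nn import Tensor, cabs, cmul, concat, fft2, ifft2, functional as F
from .reparam import RepConv


# ---------------------------------------------------------------------------
# Space-to-depth


def space_to_depth(x: Tensor) -> Tensor:
    """Rearrange (B,C,H,W) -> (B,4C,H/2,W/2); bijective on pixels.

    Channel groups are ordered X[::2,::2], X[1::2,::2], X[::2,1::2],
    X[1::2,1::2] (row offset first, then column offset).
    """
    B, C, H, W = x.shape
    if H % 2 or W % 2:
        raise ValueError(f"space_to_depth requires even spatial dims, got {H}x{W}")
    return concat(
        [x[:, :, ::2, ::2], x[:, :, 1::2, ::2], x[:, :, ::2, 1::2], x[:, :, 1::2, 1::2]],
        axis=1,
    )


def depth_to_space(x: Tensor) -> Tensor:
    """Inverse of :func:`space_to_depth` (used to verify bijectivity)."""
    import numpy as np

    B, C4, Hh, Wh = x.shape
    C = C4 // 4
    data = x.numpy()
    out = np.empty((B, C, 2 * Hh, 2 * Wh), dtype=data.dtype)
    out[:, :, ::2, ::2] = data[:, :C]
    out[:, :, 1::2, ::2] = data[:, C : 2 * C]
    out[:, :, ::2, 1::2] = data[:, 2 * C : 3 * C]
    out[:, :, 1::2, 1::2] = data[:, 3 * C :]
    return Tensor(out)


def spdconv(x: Tensor, W: Tensor, b: Tensor | None = None) -> Tensor:
    """Space-to-depth followed by a stride-1, padding-1 3x3 convolution."""
    return F.conv2d(space_to_depth(x), W, b, stride=1, padding=1)


class SPDConv(nn.Module):
    """Lossless downsampling block: optional 1x1 reduction, space-to-depth, 3x3 conv."""

    def __init__(self, in_ch: int, out_ch: int, reduce: int | None = None):
        super().__init__()
        self.pre = nn.ConvNormAct(in_ch, reduce, 1) if reduce else nn.Identity()
        mid = reduce or in_ch
        self.conv = nn.ConvNormAct(4 * mid, out_ch, 3)

    def forward(self, x):
        return self.conv(space_to_depth(self.pre(x)))


# ---------------------------------------------------------------------------
# Dual-domain attention and frequency modulation


class DDAM(nn.Module):
    """Frequency-channel then spatial-channel attention.

    F_fca = |IFFT( Wfca(GAP(x)) ⊙ FFT(x) )|;   out = Wsca(GAP(F_fca)) ⊙ F_fca.
    Both attention convolutions are 1x1 on pooled (C,1,1) descriptors.
    """

    def __init__(self, ch: int):
        super().__init__()
        self.wfca = nn.Conv2d(ch, ch, 1, bias=True)
        self.wsca = nn.Conv2d(ch, ch, 1, bias=True)

    def forward(self, x):
        wf = self.wfca(F.global_avg_pool(x))
        ffca = cabs(ifft2(cmul(wf, fft2(x))))
        ws = self.wsca(F.global_avg_pool(ffca))
        return ws * ffca


class FMB(nn.Module):
    """Frequency-modulation block: spatial gate on the spectrum of a sibling branch.

    out = alpha ⊙ |IFFT( W1(x) ⊙ FFT(W2(x)) )| + beta ⊙ x.
    alpha starts at 0 and beta at 1, so the block is the identity at
    initialization and learns its modulation strength.
    """

    def __init__(self, ch: int):
        super().__init__()
        import numpy as np

        self.w1 = nn.Conv2d(ch, ch, 1, bias=False)
        self.w2 = nn.Conv2d(ch, ch, 1, bias=False)
        self.alpha = nn.Parameter(np.zeros((ch, 1, 1)))
        self.beta = nn.Parameter(np.ones((ch, 1, 1)))

    def forward(self, x):
        mod = cabs(ifft2(cmul(self.w1(x), fft2(self.w2(x)))))
        return self.alpha * mod + self.beta * x


class MDCM(nn.Module):
    """Multi-directional convolution module (omnidirectional kernels + DDAM).

    Fin = GELU(Win * x);  out = ReLU( x + Σ_k Wk * Fin + DDAM(Fin) ) with
    depthwise kernels k ∈ {1x1, 1xL, Lx1, LxL} (L odd, default 31), each
    padded to preserve the spatial size so the residual sum aligns.
    """

    def __init__(self, ch: int, strip_length: int = 31):
        super().__init__()
        if strip_length % 2 == 0:
            raise ValueError("strip length must be odd")
        L = strip_length
        self.win = nn.Conv2d(ch, ch, 1, bias=True)
        self.k_point = nn.Conv2d(ch, ch, 1, groups=ch, bias=False)
        self.k_horiz = nn.Conv2d(ch, ch, (1, L), padding=(0, L // 2), groups=ch, bias=False)
        self.k_vert = nn.Conv2d(ch, ch, (L, 1), padding=(L // 2, 0), groups=ch, bias=False)
        self.k_square = nn.Conv2d(ch, ch, (L, L), padding=L // 2, groups=ch, bias=False)
        self.ddam = DDAM(ch)

    def forward(self, x):
        fin = self.win(x).gelu()
        y = (
            x
            + self.k_point(fin)
            + self.k_horiz(fin)
            + self.k_vert(fin)
            + self.k_square(fin)
            + self.ddam(fin)
        )
        return y.relu()


@dataclass
class CMKConfig:
    channels: int
    split_fraction: float = 0.25
    strip_length: int = 31

    def __post_init__(self):
        if not 0 < self.split_fraction < 1:
            raise ValueError("split fraction must lie in (0,1)")
        if self.strip_length % 2 == 0:
            raise ValueError("strip length must be odd")
        if round(self.channels * self.split_fraction) < 1:
            raise ValueError("too few channels for the requested split")

    @property
    def processed(self) -> int:
        return round(self.channels * self.split_fraction)


class CMKBlock(nn.Module):
    """Cross-stage multi-kernel block: thin processed branch, wide identity branch."""

    def __init__(self, cfg: CMKConfig):
        super().__init__()
        self.cfg = cfg
        c, cp = cfg.channels, cfg.processed
        self.pre = nn.ConvNormAct(c, c, 1)
        self.mdcm = MDCM(cp, cfg.strip_length)
        self.fmb = FMB(cp)
        self.post = nn.ConvNormAct(c, c, 1)

    def forward(self, x):
        cp = self.cfg.processed
        y = self.pre(x)
        processed = self.fmb(self.mdcm(y[:, :cp]))
        return self.post(concat([processed, y[:, cp:]], axis=1))


# ---------------------------------------------------------------------------
# Neck graphs


class CSPRepLayer(nn.Module):
    """Baseline fusion node: split-path 1x1s around a run of RepConv blocks."""

    def __init__(self, in_ch: int, out_ch: int, blocks: int = 3, expansion: float = 0.5):
        super().__init__()
        h = int(out_ch * expansion)
        self.conv1 = nn.ConvNormAct(in_ch, h, 1)
        self.conv2 = nn.ConvNormAct(in_ch, h, 1)
        self.blocks = nn.Sequential(*[RepConv(h, h) for _ in range(blocks)])
        self.conv3 = nn.ConvNormAct(h, out_ch, 1) if h != out_ch else nn.Identity()

    def forward(self, x):
        return self.conv3(self.blocks(self.conv1(x)) + self.conv2(x))


class CMKFusionNode(nn.Module):
    """Multi-domain fusion node: 1x1 merge of the concatenation, then a CMKBlock."""

    def __init__(self, in_ch: int, out_ch: int, cfg_kw: dict):
        super().__init__()
        self.entry = nn.ConvNormAct(in_ch, out_ch, 1)
        self.cmk = CMKBlock(CMKConfig(channels=out_ch, **cfg_kw))

    def forward(self, x):
        return self.cmk(self.entry(x))


@dataclass
class NeckConfig:
    in_channels: tuple = (64, 128, 256, 512)  # backbone P2..P5 widths
    fusion_width: int = 256
    use_p2: bool = False
    split_fraction: float = 0.25
    strip_length: int = 31
    spd_reduce: int = 118  # 1x1 reduction before space-to-depth in downsample paths
    p2_reduce: int = 70
    csp_blocks: int = 3
    csp_expansion: float = 0.5


class _NeckBase(nn.Module):
    """Shared top-down/bottom-up wiring; subclasses choose node and downsample types."""

    def __init__(self, cfg: NeckConfig):
        super().__init__()
        self.cfg = cfg
        w = cfg.fusion_width
        c2, c3, c4, c5 = cfg.in_channels
        self.proj3 = nn.ConvNormAct(c3, w, 1, act=None)
        self.proj4 = nn.ConvNormAct(c4, w, 1, act=None)
        self.lat5 = nn.ConvNormAct(w, w, 1)
        self.lat4 = nn.ConvNormAct(w, w, 1)
        self.fuse4 = self._node(2 * w, w)
        self.fuse3 = self._node(2 * w, w)
        if cfg.use_p2:
            self.p2_down = SPDConv(c2, w, reduce=cfg.p2_reduce)
            self.fuse2 = self._node(2 * w, w)
        self.down3 = self._downsample(w, w)
        self.pan4 = self._node(2 * w, w)
        self.down4 = self._downsample(w, w)
        self.pan5 = self._node(2 * w, w)

    def forward(self, feats):
        """feats: [P2raw, P3raw, P4raw, P5(projected, encoder output)] -> [N3, N4, N5]."""
        p2, p3, p4, p5 = feats
        c3, c4 = self.proj3(p3), self.proj4(p4)
        l5 = self.lat5(p5)
        t4 = self.fuse4(concat([F.upsample_nearest2x(l5), c4], axis=1))
        l4 = self.lat4(t4)
        t3 = self.fuse3(concat([F.upsample_nearest2x(l4), c3], axis=1))
        if self.cfg.use_p2:
            if p2 is None:
                raise ValueError("neck configured with use_p2 but no P2 map given")
            t3 = self.fuse2(concat([t3, self.p2_down(p2)], axis=1))
        n3 = t3
        n4 = self.pan4(concat([self.down3(n3), l4], axis=1))
        n5 = self.pan5(concat([self.down4(n4), l5], axis=1))
        return [n3, n4, n5]


class CCFM(_NeckBase):
    """Baseline concatenation-convolution fusion: CSP nodes, strided-conv downsampling."""

    def __init__(self, cfg: NeckConfig | None = None, downsample_factory=None):
        self._ds_factory = downsample_factory
        super().__init__(cfg or NeckConfig(use_p2=False))

    def _node(self, in_ch, out_ch):
        return CSPRepLayer(in_ch, out_ch, self.cfg.csp_blocks, self.cfg.csp_expansion)

    def _downsample(self, in_ch, out_ch):
        if self._ds_factory is not None:
            return self._ds_factory(in_ch, out_ch)
        return nn.ConvNormAct(in_ch, out_ch, 3, stride=2)


class MDFFN(_NeckBase):
    """Multi-domain neck: CMK fusion nodes, SPDConv downsampling, P2 entry node."""

    def __init__(self, cfg: NeckConfig | None = None):
        cfg = cfg or NeckConfig(use_p2=True)
        super().__init__(cfg)

    def _node(self, in_ch, out_ch):
        kw = dict(split_fraction=self.cfg.split_fraction, strip_length=self.cfg.strip_length)
        return CMKFusionNode(in_ch, out_ch, kw)

    def _downsample(self, in_ch, out_ch):
        return SPDConv(in_ch, out_ch, reduce=self.cfg.spd_reduce)
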