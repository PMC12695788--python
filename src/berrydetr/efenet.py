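"""Enhanced feature-extraction backbone (EFENet) built from MFEM blocks.

The backbone has a two-convolution stem (stride 4 total) and four stages at
pyramid strides 4/8/16/32 (P2..P5). Each stage is a stride-2 downsampling
transition followed by a run of multi-path feature-enhancement modules (MFEM).

An MFEM expands its input with a 1x1 convolution to twice a hidden width,
splits the result into two equal halves F1 and F2, pushes F2 through a
RepConv (giving Frep) and then through a cascade of n-1 further 3x3
convolutions (Fm_1 .. Fm_{n-1}); a final 1x1 convolution of the last cascade
output gives Fcv4. All branch outputs are concatenated — (n+2) maps of the
hidden width — and fused by a closing 1x1 convolution:

    Y = Wcv2 * Concat[F1, Frep, Fm_1, ..., Fm_{n-1}, Fcv4]

The split keeps a gradient highway through F1 while the cascade deepens the
receptive field, the cross-stage-partial design idea.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import nn
from .nn import concat
from .reparam import RepConv


@dataclass
class MFEMConfig:
    in_channels: int
    out_channels: int
    n: int = 2
    hidden: int | None = None  # defaults to out_channels // 2

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("MFEM requires n >= 1")
        if self.hidden is None:
            self.hidden = max(1, self.out_channels // 2)
        if self.hidden < 1:
            raise ValueError("hidden width must be >= 1")


class MFEM(nn.Module):
    def __init__(self, cfg: MFEMConfig):
        super().__init__()
        self.cfg = cfg
        h, n = cfg.hidden, cfg.n
        self.expand = nn.ConvNormAct(cfg.in_channels, 2 * h, 1)
        self.rep = RepConv(h, h)
        self.cascade = nn.ModuleList(
            [nn.ConvNormAct(h, h, 3) for _ in range(n - 1)]
        )
        self.cv4 = nn.Conv2d(h, h, 1, bias=True)
        self.cv2 = nn.ConvNormAct((n + 2) * h, cfg.out_channels, 1)

    def forward(self, x):
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"MFEM expects {self.cfg.in_channels} channels, got {x.shape[1]}"
            )
        h = self.cfg.hidden
        e = self.expand(x)
        f1 = e[:, :h]
        f2 = e[:, h:]
        branches = [f1, self.rep(f2)]
        y = branches[-1]
        for conv in self.cascade:
            y = conv(y)
            branches.append(y)
        branches.append(self.cv4(y))
        return self.cv2(concat(branches, axis=1))


def strided_conv_downsample(in_ch: int, out_ch: int) -> nn.Module:
    """Plain 3x3 stride-2 convolution transition (the non-adaptive default)."""
    return nn.ConvNormAct(in_ch, out_ch, 3, stride=2)


@dataclass
class EFENetConfig:
    stage_widths: tuple = (64, 128, 256, 512)  # channels of P2..P5
    stage_depths: tuple = (3, 3, 3, 1)  # MFEM blocks per stage
    n: tuple = (2, 2, 1, 2)  # cascade length per stage
    stem_channels: int = 32
    hidden_ratio: float | tuple = 0.5  # MFEM hidden width as a fraction of out width

    def __post_init__(self):
        if list(self.stage_widths) != sorted(set(self.stage_widths)):
            raise ValueError("stage widths must be strictly increasing")
        if len(self.stage_widths) != 4 or len(self.stage_depths) != 4 or len(self.n) != 4:
            raise ValueError("EFENet has exactly four stages")
        if not isinstance(self.hidden_ratio, (tuple, list)):
            self.hidden_ratio = (self.hidden_ratio,) * 4

    @property
    def out_channels(self):
        return tuple(self.stage_widths)

    @property
    def strides(self):
        return (4, 8, 16, 32)


class EFENet(nn.Module):
    """Backbone mapping an image (B,3,H,W), H,W divisible by 32, to [P2,P3,P4,P5].

    ``downsample_factory(in_ch, out_ch) -> Module`` builds the stride-2
    transitions between stages; the default is a 3x3 strided convolution and
    the assembled detector can swap in adaptive deformable sampling.
    """

    def __init__(self, cfg: EFENetConfig | None = None, downsample_factory=None):
        super().__init__()
        self.cfg = cfg = cfg or EFENetConfig()
        make_ds = downsample_factory or strided_conv_downsample
        self.stem = nn.Sequential(
            nn.ConvNormAct(3, cfg.stem_channels, 3, stride=2),
            nn.ConvNormAct(cfg.stem_channels, cfg.stage_widths[0], 3, stride=2),
        )
        self.stages = nn.ModuleList()
        self.transitions = nn.ModuleList()
        prev = cfg.stage_widths[0]
        for i, (w, d, n) in enumerate(zip(cfg.stage_widths, cfg.stage_depths, cfg.n)):
            self.transitions.append(
                nn.Identity() if i == 0 else make_ds(prev, w)
            )
            h = max(1, round(w * cfg.hidden_ratio[i]))
            blocks = [MFEM(MFEMConfig(w, w, n=n, hidden=h)) for _ in range(d)]
            self.stages.append(nn.Sequential(*blocks))
            prev = w

    def forward(self, x):
        H, W = x.shape[-2:]
        if H % 32 or W % 32:
            raise ValueError(f"input spatial dims must be divisible by 32, got {H}x{W}")
        x = self.stem(x)
        feats = []
        for trans, stage in zip(self.transitions, self.stages):
            x = stage(trans(x))
            feats.append(x)
        return feats
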