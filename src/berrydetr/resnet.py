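"""ResNet-18 backbone (the baseline feature extractor)."""

from __future__ import annotations

from . import nn
from .nn import functional as F


class BasicBlock(nn.Module):
    def __init__(self, in_ch: int, out_ch: int, stride: int = 1):
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, stride=stride, padding=1, bias=False)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, padding=1, bias=False)
        self.bn2 = nn.BatchNorm2d(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.short_conv = nn.Conv2d(in_ch, out_ch, 1, stride=stride, bias=False)
            self.short_bn = nn.BatchNorm2d(out_ch)
            self.has_short = True
        else:
            self.has_short = False

    def forward(self, x):
        y = self.bn2(self.conv2(self.bn1(self.conv1(x)).relu()))
        s = self.short_bn(self.short_conv(x)) if self.has_short else x
        return (y + s).relu()


class ResNet18(nn.Module):
    """Standard 18-layer residual network, feature-pyramid outputs P2..P5.

    Stage widths 64/128/256/512 at strides 4/8/16/32 (stem: 7x7/2 conv +
    3x3/2 max-pool), two basic blocks per stage. 11.2M parameters.
    """

    out_channels = (64, 128, 256, 512)
    strides = (4, 8, 16, 32)

    def __init__(self):
        super().__init__()
        self.stem_conv = nn.Conv2d(3, 64, 7, stride=2, padding=3, bias=False)
        self.stem_bn = nn.BatchNorm2d(64)
        widths = self.out_channels
        self.layers = nn.ModuleList()
        in_ch = 64
        for i, w in enumerate(widths):
            stride = 1 if i == 0 else 2
            self.layers.append(
                nn.Sequential(BasicBlock(in_ch, w, stride), BasicBlock(w, w, 1))
            )
            in_ch = w

    def forward(self, x):
        H, W = x.shape[-2:]
        if H % 32 or W % 32:
            raise ValueError(f"input spatial dims must be divisible by 32, got {H}x{W}")
        x = self.stem_bn(self.stem_conv(x)).relu()
        x = F.maxpool2d(x, 3, 2, 1)
        feats = []
        for layer in self.layers:
            x = layer(x)
            feats.append(x)
        return feats
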