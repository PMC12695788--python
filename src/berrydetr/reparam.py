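"""Structural reparameterization: multi-branch RepConv and its single-kernel fusion.

A RepConv trains with three parallel branches — a 3x3 convolution, a 1x1
convolution, and (when input and output widths match) an identity path — each
followed by its own normalization, summed before the SiLU activation:

    y = silu( BN_main(conv3x3(x)) + BN_aux(conv1x1(x)) + BN_id(x) )

At inference the whole sum collapses into one 3x3 convolution with identical
output: each normalization folds into its branch kernel (per-output-channel
scale and shift), the 1x1 kernel zero-pads to 3x3, and the identity path
becomes a "diagonal unit" 3x3 kernel whose centre tap is 1 on its own channel.
Fusion is exact pre-activation, so the fused network reproduces the training
network to floating-point round-off.

Two surfaces are provided: a plain-array functional layer
(:class:`BranchParams`, :func:`fold_bn`, :func:`fuse`, :func:`train_forward`)
used by the equivalence test-suites, and the :class:`RepConv` module used
inside the backbone, with :func:`fuse_repconvs` to convert a trained model
in place.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor, functional as F


# ---------------------------------------------------------------------------
# Functional layer


@dataclass
class BNStats:
    """Per-channel normalization statistics (inference semantics)."""

    gamma: np.ndarray
    beta: np.ndarray
    mean: np.ndarray
    var: np.ndarray
    eps: float = 1e-5

    def __post_init__(self):
        self.gamma, self.beta, self.mean, self.var = (
            np.asarray(a, dtype=float) for a in (self.gamma, self.beta, self.mean, self.var)
        )
        if np.any(self.var + self.eps <= 0):
            raise ValueError("normalization variance + eps must be positive")

    @staticmethod
    def identity(ch: int) -> "BNStats":
        return BNStats(np.ones(ch), np.zeros(ch), np.zeros(ch), np.ones(ch), eps=0.0)

    def apply(self, x: np.ndarray) -> np.ndarray:
        """Normalize (C, H, W) or (B, C, H, W) channel-wise."""
        c = self.gamma.size
        shape = (c, 1, 1) if x.ndim == 3 else (1, c, 1, 1)
        s = self.gamma / np.sqrt(self.var + self.eps)
        return (x - self.mean.reshape(shape)) * s.reshape(shape) + self.beta.reshape(shape)


@dataclass
class BranchParams:
    """The three-branch parameterization of a RepConv operator."""

    W3x3: np.ndarray
    b3x3: np.ndarray
    W1x1: np.ndarray
    b1x1: np.ndarray
    bn_main: BNStats
    bn_aux: BNStats
    bn_id: BNStats | None = None
    has_identity: bool = False

    def __post_init__(self):
        self.W3x3 = np.asarray(self.W3x3, dtype=float)
        self.W1x1 = np.asarray(self.W1x1, dtype=float)
        self.b3x3 = np.asarray(self.b3x3, dtype=float)
        self.b1x1 = np.asarray(self.b1x1, dtype=float)
        if self.W3x3.shape[2:] != (3, 3) or self.W1x1.shape[2:] != (1, 1):
            raise ValueError("kernel spatial sizes must be 3x3 and 1x1")
        if self.W3x3.shape[:2] != self.W1x1.shape[:2]:
            raise ValueError("3x3 and 1x1 branches must share channel counts")
        if self.has_identity and self.W3x3.shape[0] != self.W3x3.shape[1]:
            raise ValueError("identity branch requires equal in/out channels")
        if self.has_identity and self.bn_id is None:
            raise ValueError("identity branch requires bn_id statistics")

    @property
    def out_channels(self) -> int:
        return self.W3x3.shape[0]

    @property
    def in_channels(self) -> int:
        return self.W3x3.shape[1]


@dataclass
class FusedParams:
    """Single-kernel equivalent of a :class:`BranchParams`."""

    Wequiv: np.ndarray
    bequiv: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.Wequiv = np.asarray(self.Wequiv, dtype=float)
        if self.bequiv is None:
            self.bequiv = np.zeros(self.Wequiv.shape[0])
        self.bequiv = np.asarray(self.bequiv, dtype=float)
        if self.Wequiv.shape[2:] != (3, 3):
            raise ValueError("fused kernel must be 3x3")


def fold_bn(W: np.ndarray, bn: BNStats, b: np.ndarray | None = None):
    """Fold conv-then-normalize into an equivalent conv.

    Returns ``(W * s, beta + (b - mean) * s)`` with ``s = gamma/sqrt(var+eps)``
    per output channel, so that ``bn(conv(x, W, b)) == conv(x, W_f, b_f)`` on
    any input.
    """
    W = np.asarray(W, dtype=float)
    s = bn.gamma / np.sqrt(bn.var + bn.eps)
    Wf = W * s.reshape(-1, 1, 1, 1)
    b = np.zeros(W.shape[0]) if b is None else np.asarray(b, dtype=float)
    bf = bn.beta + (b - bn.mean) * s
    return Wf, bf


def pad_1x1_to_3x3(W1: np.ndarray) -> np.ndarray:
    """Zero-pad a (Cout, Cin, 1, 1) kernel to 3x3 (value moves to the centre tap)."""
    out = np.zeros(W1.shape[:2] + (3, 3), dtype=float)
    out[:, :, 1, 1] = W1[:, :, 0, 0]
    return out


def identity_kernel(ch: int) -> np.ndarray:
    """Diagonal-unit 3x3 kernel: centre tap 1 on each channel's own map."""
    W = np.zeros((ch, ch, 3, 3))
    W[np.arange(ch), np.arange(ch), 1, 1] = 1.0
    return W


def fuse(p: BranchParams) -> FusedParams:
    """Collapse the three branches into one 3x3 kernel + bias (exact pre-activation)."""
    W3f, b3f = fold_bn(p.W3x3, p.bn_main, p.b3x3)
    W1f, b1f = fold_bn(p.W1x1, p.bn_aux, p.b1x1)
    Wequiv = W3f + pad_1x1_to_3x3(W1f)
    bequiv = b3f + b1f
    if p.has_identity:
        Wid, bid = fold_bn(identity_kernel(p.in_channels), p.bn_id)
        Wequiv = Wequiv + Wid
        bequiv = bequiv + bid
    return FusedParams(Wequiv, bequiv)


def _conv(x: np.ndarray, W: np.ndarray, b: np.ndarray | None, padding: int) -> np.ndarray:
    squeeze = x.ndim == 3
    xb = x[None] if squeeze else x
    with nn.no_grad():
        out = F.conv2d(
            Tensor(xb), Tensor(W), None if b is None else Tensor(b), padding=padding
        ).numpy()
    return out[0] if squeeze else out


def _silu(x: np.ndarray) -> np.ndarray:
    return x / (1.0 + np.exp(-x))


def train_forward(x: np.ndarray, p: BranchParams) -> np.ndarray:
    """Multi-branch forward: silu(BN(conv3x3) + BN(conv1x1) + BN_id(x))."""
    cin = x.shape[0] if x.ndim == 3 else x.shape[1]
    if cin != p.in_channels:
        raise ValueError(f"input has {cin} channels, branches expect {p.in_channels}")
    y = p.bn_main.apply(_conv(x, p.W3x3, p.b3x3, padding=1))
    y = y + p.bn_aux.apply(_conv(x, p.W1x1, p.b1x1, padding=0))
    if p.has_identity:
        y = y + p.bn_id.apply(x)
    return _silu(y)


def fused_forward(x: np.ndarray, fp: FusedParams) -> np.ndarray:
    """Single-branch forward: silu(conv3x3(x; Wequiv, bequiv))."""
    return _silu(_conv(x, fp.Wequiv, fp.bequiv, padding=1))


# ---------------------------------------------------------------------------
# Module layer


class RepConv(nn.Module):
    """Trainable RepConv block (3x3 + 1x1 + optional identity, each with BN)."""

    def __init__(self, in_ch: int, out_ch: int, act: str = "silu"):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.conv3 = nn.Conv2d(in_ch, out_ch, 3, padding=1, bias=False)
        self.bn3 = nn.BatchNorm2d(out_ch)
        self.conv1 = nn.Conv2d(in_ch, out_ch, 1, bias=False)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.has_identity = in_ch == out_ch
        if self.has_identity:
            self.bnid = nn.BatchNorm2d(out_ch)
        self.act = {"silu": nn.SiLU, "relu": nn.ReLU, None: nn.Identity}[act]()
        self.deployed = False

    def forward(self, x):
        if self.deployed:
            return self.act(self.fused(x))
        y = self.bn3(self.conv3(x)) + self.bn1(self.conv1(x))
        if self.has_identity:
            y = y + self.bnid(x)
        return self.act(y)

    def branch_params(self) -> BranchParams:
        """Export branches with stored running statistics (inference semantics)."""

        def stats(bn: nn.BatchNorm2d) -> BNStats:
            return BNStats(
                bn.weight.data.copy(),
                bn.bias.data.copy(),
                bn._buffers["running_mean"].copy(),
                bn._buffers["running_var"].copy(),
                bn.eps,
            )

        return BranchParams(
            W3x3=self.conv3.weight.data.copy(),
            b3x3=np.zeros(self.out_ch),
            W1x1=self.conv1.weight.data.copy(),
            b1x1=np.zeros(self.out_ch),
            bn_main=stats(self.bn3),
            bn_aux=stats(self.bn1),
            bn_id=stats(self.bnid) if self.has_identity else None,
            has_identity=self.has_identity,
        )

    def fuse_(self):
        """Switch to single-branch execution (idempotent)."""
        if self.deployed:
            return self
        fp = fuse(self.branch_params())
        fused = nn.Conv2d(self.in_ch, self.out_ch, 3, padding=1, bias=True)
        fused.weight.data = fp.Wequiv
        fused.bias.data = fp.bequiv
        self.fused = fused
        self.deployed = True
        # drop branch modules so parameter counts reflect deployment
        for name in ("conv3", "bn3", "conv1", "bn1", "bnid"):
            self._modules.pop(name, None)
        return self


def fuse_repconvs(module: nn.Module) -> int:
    """Fuse every RepConv in a model tree in place; returns how many were fused."""
    n = 0
    for m in module.modules():
        if isinstance(m, RepConv) and not m.deployed:
            m.fuse_()
            n += 1
    return n
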