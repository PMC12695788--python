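"""End-to-end detector assembly: backbone + hybrid encoder + query decoder.

The detector follows the real-time detection-transformer design: a CNN
backbone produces a feature pyramid; the stride-32 level passes through a
single intra-scale transformer encoder layer (AIFI); a cross-scale fusion
neck (baseline CCFM or the multi-domain MDFFN) merges strides 8/16/32; a
transformer decoder with IoU-aware query selection refines a fixed set of
object queries into boxes + scores directly — no non-maximum suppression.

:func:`assemble` builds any ablation combination of the three replacements
(EFENet backbone / MDFFN neck / ADSample downsampling) over the ResNet-18
baseline. :func:`count_parameters` and :func:`count_flops` report model
complexity; FLOPs are measured by running one forward pass under the MAC
counter (GFLOPs = 2 x GMACs, the multiply-and-add convention used by common
detector complexity tables).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .adsample import ADSample
from .efenet import EFENet, EFENetConfig
from .mdffn import CCFM, MDFFN, NeckConfig
from .nn import Tensor, concat, functional as F
from .resnet import BasicBlock, ResNet18


def inverse_sigmoid(x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    x = np.clip(x, eps, 1 - eps)
    return np.log(x / (1 - x))


# ---------------------------------------------------------------------------
# AIFI: intra-scale interaction on the stride-32 map


def sincos_pos_embed_2d(h: int, w: int, dim: int, temperature: float = 10000.0) -> np.ndarray:
    """(h*w, dim) fixed 2-D sine-cosine positional embedding."""
    if dim % 4:
        raise ValueError("embedding dim must be divisible by 4")
    gw, gh = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    pos_dim = dim // 4
    omega = 1.0 / temperature ** (np.arange(pos_dim) / pos_dim)
    out_w = gw.reshape(-1)[:, None] * omega[None]
    out_h = gh.reshape(-1)[:, None] * omega[None]
    return np.concatenate(
        [np.sin(out_w), np.cos(out_w), np.sin(out_h), np.cos(out_h)], axis=1
    )


class AIFI(nn.Module):
    """One post-norm transformer encoder layer over the flattened P5 tokens."""

    def __init__(self, dim: int = 256, heads: int = 8, ffn: int = 1024):
        super().__init__()
        self.dim = dim
        self.attn = nn.MultiheadAttention(dim, heads)
        self.ln1 = nn.LayerNorm(dim)
        self.fc1 = nn.Linear(dim, ffn)
        self.fc2 = nn.Linear(ffn, dim)
        self.ln2 = nn.LayerNorm(dim)

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        src = x.reshape(B, C, H * W).transpose(0, 2, 1)
        pos = Tensor(sincos_pos_embed_2d(H, W, C)[None])
        q = src + pos
        src = self.ln1(src + self.attn(q, q, src))
        src = self.ln2(src + self.fc2(self.fc1(src).gelu()))
        return src.transpose(0, 2, 1).reshape(B, C, H, W)


# ---------------------------------------------------------------------------
# Decoder


class MSDeformAttention(nn.Module):
    """Multi-scale deformable cross-attention (sampled with bilinear gathers)."""

    def __init__(self, dim: int = 256, heads: int = 8, levels: int = 3, points: int = 4):
        super().__init__()
        if dim % heads:
            raise ValueError("dim must divide into heads")
        self.dim, self.heads, self.levels, self.points = dim, heads, levels, points
        self.hd = dim // heads
        self.sampling_offsets = nn.Linear(dim, heads * levels * points * 2)
        self.attention_weights = nn.Linear(dim, heads * levels * points)
        self.value_proj = nn.Linear(dim, dim)
        self.output_proj = nn.Linear(dim, dim)

    def forward(self, query: Tensor, refs: Tensor, value_maps) -> Tensor:
        """query (B,Q,D); refs (B,Q,4) normalized cxcywh; value_maps: [(B,D,H,W)]."""
        B, Q, D = query.shape
        Hn, Ln, Pn = self.heads, self.levels, self.points
        off = self.sampling_offsets(query).reshape(B, Q, Hn, Ln, Pn, 2)
        w = self.attention_weights(query).reshape(B, Q, Hn, Ln * Pn).softmax(axis=-1)
        w = w.reshape(B, Q, Hn, Ln, Pn)
        center = refs[:, :, 0:2].reshape(B, Q, 1, 1, 1, 2)
        wh = refs[:, :, 2:4].reshape(B, Q, 1, 1, 1, 2)
        loc = center + off * wh * (0.5 / Pn)  # normalized sampling locations
        out = None
        for lvl, vmap in enumerate(value_maps):
            _, _, Hl, Wl = vmap.shape
            v = self.value_proj(vmap.reshape(B, D, Hl * Wl).transpose(0, 2, 1))
            v = v.transpose(0, 2, 1).reshape(B, Hn, self.hd, Hl, Wl)
            v = v.reshape(B * Hn, self.hd, Hl, Wl)
            scale = Tensor(np.array([Wl, Hl], dtype=float).reshape(1, 1, 1, 1, 2))
            c = loc[:, :, :, lvl] * scale - 0.5  # (B,Q,H,P,2) pixel units
            c = c.transpose(0, 2, 1, 3, 4).reshape(B * Hn, Q, Pn, 2)
            sampled = F.bilinear_sample(v, c)  # (B*H, hd, Q, P)
            wl = w[:, :, :, lvl].transpose(0, 2, 1, 3).reshape(B * Hn, 1, Q, Pn)
            contrib = (sampled * wl).sum(axis=-1)  # (B*H, hd, Q)
            out = contrib if out is None else out + contrib
        out = out.reshape(B, Hn * self.hd, Q).transpose(0, 2, 1)
        return self.output_proj(out)


class DecoderLayer(nn.Module):
    def __init__(self, dim: int, heads: int, levels: int, points: int, ffn: int):
        super().__init__()
        self.self_attn = nn.MultiheadAttention(dim, heads)
        self.ln1 = nn.LayerNorm(dim)
        self.cross_attn = MSDeformAttention(dim, heads, levels, points)
        self.ln2 = nn.LayerNorm(dim)
        self.fc1 = nn.Linear(dim, ffn)
        self.fc2 = nn.Linear(ffn, dim)
        self.ln3 = nn.LayerNorm(dim)

    def forward(self, tgt: Tensor, query_pos: Tensor, refs: Tensor, value_maps) -> Tensor:
        q = tgt + query_pos
        tgt = self.ln1(tgt + self.self_attn(q, q, tgt))
        tgt = self.ln2(tgt + self.cross_attn(tgt + query_pos, refs, value_maps))
        tgt = self.ln3(tgt + self.fc2(self.fc1(tgt).relu()))
        return tgt


class QueryDecoder(nn.Module):
    """IoU-aware query selection + iterative box refinement decoder."""

    def __init__(self, num_classes: int = 1, dim: int = 256, layers: int = 3,
                 num_queries: int = 300, heads: int = 8, points: int = 4,
                 levels: int = 3, ffn: int = 1024, anchor_grid_size: float = 0.05):
        super().__init__()
        self.nc, self.dim, self.num_queries = num_classes, dim, num_queries
        self.levels = levels
        self.anchor_grid_size = anchor_grid_size
        self.input_proj = nn.ModuleList(
            [nn.ConvNormAct(dim, dim, 1, act=None) for _ in range(levels)]
        )
        self.enc_output = nn.Linear(dim, dim)
        self.enc_norm = nn.LayerNorm(dim)
        self.enc_score = nn.Linear(dim, num_classes)
        self.enc_bbox = nn.MLP(dim, dim, 4, 3)
        self.query_pos_head = nn.MLP(4, 2 * dim, dim, 2)
        self.layers = nn.ModuleList(
            [DecoderLayer(dim, heads, levels, points, ffn) for _ in range(layers)]
        )
        # prediction heads are tied across refinement steps
        self.score_head = nn.Linear(dim, num_classes)
        self.bbox_head = nn.MLP(dim, dim, 4, 3)

    def _anchors(self, shapes):
        anchors, valid = [], []
        for lvl, (h, w) in enumerate(shapes):
            gy, gx = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float),
                                 indexing="ij")
            cx = (gx.reshape(-1) + 0.5) / w
            cy = (gy.reshape(-1) + 0.5) / h
            wh = np.full_like(cx, self.anchor_grid_size * 2.0**lvl)
            a = np.stack([cx, cy, wh, wh], axis=1)
            ok = ((a[:, :2] > 0.01) & (a[:, :2] < 0.99)).all(axis=1)
            anchors.append(a)
            valid.append(ok)
        a = np.concatenate(anchors, axis=0)
        return inverse_sigmoid(a), np.concatenate(valid, axis=0)

    def forward(self, feats):
        feats = [proj(f) for proj, f in zip(self.input_proj, feats)]
        B, D = feats[0].shape[0], self.dim
        shapes = [(f.shape[2], f.shape[3]) for f in feats]
        tokens = concat(
            [f.reshape(B, D, f.shape[2] * f.shape[3]).transpose(0, 2, 1) for f in feats],
            axis=1,
        )
        anchor_logit, valid = self._anchors(shapes)
        memory = self.enc_norm(self.enc_output(tokens))
        enc_logits = self.enc_score(memory)  # (B, L, nc)
        enc_deltas = self.enc_bbox(memory)
        # top-k query selection on the class-max proposal score
        sel_score = enc_logits.numpy().max(axis=-1)
        sel_score = np.where(valid[None], sel_score, -np.inf)
        k = min(self.num_queries, sel_score.shape[1])
        topk = np.argpartition(-sel_score, k - 1, axis=1)[:, :k]
        bidx = np.arange(B)[:, None]
        tgt = memory[bidx, topk]  # (B, k, D)
        ref_logit = enc_deltas[bidx, topk] + Tensor(anchor_logit[topk])
        refs = ref_logit.sigmoid()
        enc_out = {"logits": enc_logits[bidx, topk], "boxes": refs}
        aux = []
        tgt_out, logits, boxes = tgt, None, None
        for layer in self.layers:
            refs_in = Tensor(refs.numpy())  # detached reference points
            qpos = self.query_pos_head(refs_in)
            tgt_out = layer(tgt_out, qpos, refs_in, feats)
            logits = self.score_head(tgt_out)
            delta = self.bbox_head(tgt_out)
            boxes = (delta + Tensor(inverse_sigmoid(refs_in.numpy()))).sigmoid()
            aux.append({"logits": logits, "boxes": boxes})
            refs = boxes
        out = {"logits": logits, "boxes": boxes, "enc": enc_out, "aux": aux[:-1]}
        return out


# ---------------------------------------------------------------------------
# Full model


@dataclass
class Detection:
    class_id: int
    score: float
    box: tuple  # (cx, cy, w, h) absolute pixels

    def __post_init__(self):
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must lie in [0,1]")
        if self.box[2] <= 0 or self.box[3] <= 0:
            raise ValueError("box must have positive extent")


@dataclass
class ModelConfig:
    num_classes: int = 1
    input_size: int = 640
    use_efenet: bool = False
    use_mdffn: bool = False
    use_adsample: bool = False
    efenet: EFENetConfig = field(default_factory=EFENetConfig)
    fusion_width: int = 256
    spd_reduce: int = 118
    p2_reduce: int = 70
    split_fraction: float = 0.25
    strip_length: int = 31
    csp_blocks: int = 3
    csp_expansion: float = 0.5
    decoder_layers: int = 3
    num_queries: int = 300
    hidden: int = 256
    heads: int = 8
    points: int = 4
    ffn: int = 1024
    adsample_n: int = 9  # N sampling points (3x3 pattern by default)

    def __post_init__(self):
        if self.input_size % 32:
            raise ValueError("input size must be divisible by 32")
        if self.num_queries < 1:
            raise ValueError("need at least one query")


VARIANTS = {
    "rtdetr_r18": dict(use_efenet=False, use_mdffn=False, use_adsample=False),
    "base": dict(use_efenet=False, use_mdffn=False, use_adsample=False),
    "efenet": dict(use_efenet=True, use_mdffn=False, use_adsample=False),
    "mdffn": dict(use_efenet=False, use_mdffn=True, use_adsample=False),
    "adsample": dict(use_efenet=False, use_mdffn=False, use_adsample=True),
    "efenet+mdffn": dict(use_efenet=True, use_mdffn=True, use_adsample=False),
    "efenet+adsample": dict(use_efenet=True, use_mdffn=False, use_adsample=True),
    "mdffn+adsample": dict(use_efenet=False, use_mdffn=True, use_adsample=True),
    "mde_detr": dict(use_efenet=True, use_mdffn=True, use_adsample=True),
    "full": dict(use_efenet=True, use_mdffn=True, use_adsample=True),
}


class MDEDETR(nn.Module):
    """Assembled detector (any ablation combination of the three replacements)."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        w = cfg.hidden
        ds_factory = None
        if cfg.use_adsample:
            n = cfg.adsample_n

            def ds_factory(cin, cout):
                return ADSample(cin, cout, stride=2, N=n)

        if cfg.use_efenet:
            self.backbone = EFENet(cfg.efenet, downsample_factory=ds_factory)
            bb_ch = cfg.efenet.out_channels
        else:
            self.backbone = ResNet18()
            bb_ch = ResNet18.out_channels
            if cfg.use_adsample:
                self._swap_resnet_downsamples(ds_factory)
        self.proj5 = nn.ConvNormAct(bb_ch[3], w, 1, act=None)
        self.aifi = AIFI(w, cfg.heads, cfg.ffn)
        neck_cfg = NeckConfig(
            in_channels=bb_ch, fusion_width=w, use_p2=cfg.use_mdffn,
            split_fraction=cfg.split_fraction, strip_length=cfg.strip_length,
            spd_reduce=cfg.spd_reduce, p2_reduce=cfg.p2_reduce,
            csp_blocks=cfg.csp_blocks, csp_expansion=cfg.csp_expansion,
        )
        if cfg.use_mdffn:
            self.neck = MDFFN(neck_cfg)
        else:
            self.neck = CCFM(neck_cfg, downsample_factory=ds_factory)
        self.decoder = QueryDecoder(
            num_classes=cfg.num_classes, dim=w, layers=cfg.decoder_layers,
            num_queries=cfg.num_queries, heads=cfg.heads, points=cfg.points,
            levels=3, ffn=cfg.ffn,
        )

    def _swap_resnet_downsamples(self, ds_factory):
        """Replace the strided 3x3 convs of the residual stage transitions."""
        for layer in self.backbone.layers:
            blk = layer[0]
            if isinstance(blk, BasicBlock) and blk.conv1.stride == 2:
                ds = ds_factory(blk.conv1.in_ch, blk.conv1.out_ch)
                blk.adsample = ds  # registers the module

                def fwd(x, _blk=blk):
                    y = _blk.bn2(_blk.conv2(_blk.adsample(x)))
                    s = _blk.short_bn(_blk.short_conv(x))
                    return (y + s).relu()

                blk.forward = fwd
                # the replaced conv/bn no longer participate
                for name in ("conv1", "bn1"):
                    blk._modules.pop(name, None)

    def forward(self, x: Tensor):
        p2, p3, p4, p5 = self.backbone(x)
        p5 = self.aifi(self.proj5(p5))
        n3, n4, n5 = self.neck([p2, p3, p4, p5])
        return self.decoder([n3, n4, n5])

    # -- complexity -----------------------------------------------------------
    def component_params(self) -> dict:
        return {
            "backbone": self.backbone.num_params(),
            "encoder": self.proj5.num_params() + self.aifi.num_params()
            + self.neck.num_params(),
            "decoder": self.decoder.num_params(),
        }


def assemble(variant: str = "mde_detr", cfg: ModelConfig | None = None, **overrides) -> MDEDETR:
    """Build a detector variant ('base', 'efenet', ..., 'mde_detr') or flag combo."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {sorted(VARIANTS)}")
    cfg = cfg or ModelConfig()
    cfg = replace(cfg, **VARIANTS[variant], **overrides)
    return MDEDETR(cfg)


def count_parameters(model: nn.Module) -> int:
    """Total trainable scalars (use ``params_millions`` for the printed form)."""
    return model.num_params()


def params_millions(model: nn.Module) -> float:
    return round(model.num_params() / 1e6, 1)


def count_flops(model: MDEDETR, input_size: int | None = None) -> dict:
    """Measured multiply-accumulates of one forward pass at ``input_size``.

    Returns ``{"gmacs": ..., "gflops": ...}`` with GFLOPs = 2 x GMACs (one
    multiply + one add per MAC), the convention under which the reproduced
    baseline matches published detector complexity tables.
    """
    size = input_size or model.cfg.input_size
    was_training = model.training
    model.eval()
    x = Tensor(np.zeros((1, 3, size, size)))
    with nn.no_grad():
        with nn.count_macs() as ctr:
            model(x)
    macs = ctr.macs
    if was_training:
        model.train()
    return {"gmacs": macs / 1e9, "gflops": 2 * macs / 1e9}


# ---------------------------------------------------------------------------
# Inference


def letterbox(img: np.ndarray, size: int):
    """Resize an HxWx3 uint8 image to size x size preserving aspect (top-left pad).

    Returns (canvas, scale) with original = canvas_coords / scale.
    """
    from PIL import Image

    h, w = img.shape[:2]
    scale = size / max(h, w)
    nw, nh = max(1, round(w * scale)), max(1, round(h * scale))
    resized = np.asarray(Image.fromarray(img).resize((nw, nh), Image.BILINEAR))
    canvas = np.zeros((size, size, 3), dtype=np.uint8)
    canvas[:nh, :nw] = resized
    return canvas, scale


def preprocess(images, size: int) -> tuple:
    batch, scales = [], []
    for img in images:
        canvas, s = letterbox(np.asarray(img), size)
        batch.append(canvas.astype(float).transpose(2, 0, 1) / 255.0)
        scales.append(s)
    return Tensor(np.stack(batch)), scales


def infer(model: MDEDETR, images, score_threshold: float = 0.5):
    """Run detection on a list of HxWx3 uint8 arrays; returns per-image Detection lists."""
    model.eval()
    size = model.cfg.input_size
    x, scales = preprocess(images, size)
    with nn.no_grad():
        out = model(x)
    logits = out["logits"].numpy()
    boxes = out["boxes"].numpy()
    results = []
    for b, scale in enumerate(scales):
        scores = 1.0 / (1.0 + np.exp(-logits[b]))
        cls = scores.argmax(axis=-1)
        sc = scores.max(axis=-1)
        keep = sc >= score_threshold
        dets = []
        for q in np.nonzero(keep)[0]:
            cx, cy, w, h = boxes[b, q] * size / scale
            if w > 0 and h > 0:
                dets.append(Detection(int(cls[q]), float(sc[q]), (cx, cy, w, h)))
        dets.sort(key=lambda d: -d.score)
        results.append(dets)
    return results
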