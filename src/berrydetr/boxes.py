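"""Axis-aligned box utilities (numpy + differentiable Tensor variants).

Boxes are (cx, cy, w, h), normalized to [0,1] unless stated otherwise;
corner format is (x1, y1, x2, y2).
"""

from __future__ import annotations

import numpy as np

from .nn import Tensor, concat


def cxcywh_to_xyxy(b: np.ndarray) -> np.ndarray:
    b = np.asarray(b, dtype=float)
    cx, cy, w, h = b[..., 0], b[..., 1], b[..., 2], b[..., 3]
    return np.stack([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2], axis=-1)


def xyxy_to_cxcywh(b: np.ndarray) -> np.ndarray:
    b = np.asarray(b, dtype=float)
    x1, y1, x2, y2 = b[..., 0], b[..., 1], b[..., 2], b[..., 3]
    return np.stack([(x1 + x2) / 2, (y1 + y2) / 2, x2 - x1, y2 - y1], axis=-1)


def box_iou_xyxy(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU matrix (len(a), len(b)) of xyxy boxes."""
    a, b = np.atleast_2d(a), np.atleast_2d(b)
    area_a = np.maximum(a[:, 2] - a[:, 0], 0) * np.maximum(a[:, 3] - a[:, 1], 0)
    area_b = np.maximum(b[:, 2] - b[:, 0], 0) * np.maximum(b[:, 3] - b[:, 1], 0)
    lt = np.maximum(a[:, None, :2], b[None, :, :2])
    rb = np.minimum(a[:, None, 2:], b[None, :, 2:])
    wh = np.maximum(rb - lt, 0)
    inter = wh[..., 0] * wh[..., 1]
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / np.maximum(union, 1e-12), 0.0)


def generalized_iou_xyxy(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise generalized IoU matrix (IoU minus enclosing-box penalty)."""
    a, b = np.atleast_2d(a), np.atleast_2d(b)
    iou = box_iou_xyxy(a, b)
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    lt = np.maximum(a[:, None, :2], b[None, :, :2])
    rb = np.minimum(a[:, None, 2:], b[None, :, 2:])
    inter = np.prod(np.maximum(rb - lt, 0), axis=-1)
    union = area_a[:, None] + area_b[None, :] - inter
    elt = np.minimum(a[:, None, :2], b[None, :, :2])
    erb = np.maximum(a[:, None, 2:], b[None, :, 2:])
    enc = np.prod(np.maximum(erb - elt, 0), axis=-1)
    return iou - np.where(enc > 0, (enc - union) / np.maximum(enc, 1e-12), 0.0)


# ---------------------------------------------------------------------------
# differentiable variants (matched pairs, Tensor in/out)


def _tmax(a: Tensor, b: Tensor) -> Tensor:
    return a + (b - a).relu()


def _tmin(a: Tensor, b: Tensor) -> Tensor:
    return a - (a - b).relu()


def t_cxcywh_to_xyxy(b: Tensor) -> Tensor:
    cx, cy = b[..., 0:1], b[..., 1:2]
    w, h = b[..., 2:3], b[..., 3:4]
    half_w, half_h = w * 0.5, h * 0.5
    return concat([cx - half_w, cy - half_h, cx + half_w, cy + half_h], axis=-1)


def t_giou_pairs(pred_xyxy: Tensor, tgt_xyxy: Tensor) -> Tensor:
    """Elementwise GIoU of matched (M,4) box pairs; differentiable in pred."""
    px1, py1, px2, py2 = (pred_xyxy[:, i] for i in range(4))
    tx1, ty1, tx2, ty2 = (tgt_xyxy[:, i] for i in range(4))
    inter_w = (_tmin(px2, tx2) - _tmax(px1, tx1)).relu()
    inter_h = (_tmin(py2, ty2) - _tmax(py1, ty1)).relu()
    inter = inter_w * inter_h
    area_p = (px2 - px1) * (py2 - py1)
    area_t = (tx2 - tx1) * (ty2 - ty1)
    union = area_p + area_t - inter
    iou = inter / (union + 1e-9)
    enc_w = _tmax(px2, tx2) - _tmin(px1, tx1)
    enc_h = _tmax(py2, ty2) - _tmin(py1, ty1)
    enc = enc_w * enc_h
    return iou - (enc - union) / (enc + 1e-9)
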