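"""Minimal training loop for the detector (used for overfit checks and the CLI)."""

from __future__ import annotations

import numpy as np

from . import nn
from .detector import MDEDETR
from .evaluation import map_suite
from .losses import DetectionCriterion
from .nn import Tensor


def items_to_arrays(items, size: int):
    """AnnotatedImage list -> (images (N,3,S,S) float, targets list)."""
    xs, targets = [], []
    for it in items:
        img = it.image
        if img.shape[0] != size or img.shape[1] != size:
            from PIL import Image

            img = np.asarray(Image.fromarray(img).resize((size, size), Image.BILINEAR))
        xs.append(img.astype(float).transpose(2, 0, 1) / 255.0)
        targets.append(
            {
                "labels": np.array([b[0] for b in it.boxes], dtype=int),
                "boxes": np.array([b[1:] for b in it.boxes], dtype=float).reshape(-1, 4),
            }
        )
    return np.stack(xs), targets


def train_detector(model: MDEDETR, items, steps: int = 200, lr: float = 2e-3,
                   batch_size: int = 4, seed: int = 0, weight_decay: float = 1e-4,
                   log=None):
    """AdamW training on a fixed in-memory dataset; returns per-step losses."""
    xs, targets = items_to_arrays(items, model.cfg.input_size)
    crit = DetectionCriterion(model.cfg.num_classes)
    opt = nn.AdamW(model.parameters(), lr=lr, weight_decay=weight_decay)
    rng = np.random.default_rng(seed)
    model.train()
    losses = []
    order = rng.permutation(len(items))
    cursor = 0
    for step in range(steps):
        if cursor + batch_size > len(order):
            order = rng.permutation(len(items))
            cursor = 0
        idx = order[cursor : cursor + batch_size]
        cursor += batch_size
        out = model(Tensor(xs[idx]))
        loss = crit(out, [targets[i] for i in idx])
        opt.zero_grad()
        loss.backward()
        opt.step()
        losses.append(loss.item())
        if log and (step % 20 == 0 or step == steps - 1):
            log(f"step {step:4d}  loss {losses[-1]:.3f}")
    model.eval()
    return losses


def evaluate_detector(model: MDEDETR, items, classes=None):
    """(mAP50, mAP50:95) of the model on a list of AnnotatedImages."""
    xs, targets = items_to_arrays(items, model.cfg.input_size)
    model.eval()
    dets, gts = [], []
    for i in range(len(items)):
        with nn.no_grad():
            out = model(Tensor(xs[i : i + 1]))
        logits = out["logits"].numpy()[0]
        boxes = out["boxes"].numpy()[0]
        scores = 1 / (1 + np.exp(-logits))
        dets.append((boxes, scores.max(axis=-1), scores.argmax(axis=-1)))
        gts.append((targets[i]["boxes"], targets[i]["labels"]))
    if classes is None:
        classes = tuple(range(model.cfg.num_classes))
    return map_suite(dets, gts, classes=classes)
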