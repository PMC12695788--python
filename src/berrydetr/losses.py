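"""Set-based detection loss: Hungarian matching + focal / L1 / GIoU terms.

The loss follows the standard real-time detection-transformer recipe: each
decoder layer's predictions (plus the encoder proposal head) are matched
one-to-one to the ground-truth boxes with the Hungarian algorithm on a cost
mixing classification score, L1 box distance and generalized IoU; the matched
pairs contribute focal classification, L1 and GIoU losses.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment

from . import boxes as B
from .nn import Tensor


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class HungarianMatcher:
    def __init__(self, cost_class: float = 2.0, cost_bbox: float = 5.0, cost_giou: float = 2.0,
                 alpha: float = 0.25, gamma: float = 2.0):
        self.cost_class, self.cost_bbox, self.cost_giou = cost_class, cost_bbox, cost_giou
        self.alpha, self.gamma = alpha, gamma

    def __call__(self, logits: np.ndarray, pred_boxes: np.ndarray, gt_labels, gt_boxes):
        """Per-image assignment. logits (Q, nc), pred_boxes (Q,4) cxcywh normalized.

        Returns (pred_idx, gt_idx) arrays.
        """
        if len(gt_boxes) == 0:
            return np.array([], dtype=int), np.array([], dtype=int)
        prob = _sigmoid(logits)[:, gt_labels]  # (Q, M)
        # focal-style classification cost
        neg = (1 - self.alpha) * prob**self.gamma * (-np.log(1 - prob + 1e-8))
        pos = self.alpha * (1 - prob) ** self.gamma * (-np.log(prob + 1e-8))
        c_class = pos - neg
        c_bbox = np.abs(pred_boxes[:, None, :] - np.asarray(gt_boxes)[None, :, :]).sum(-1)
        c_giou = -B.generalized_iou_xyxy(
            B.cxcywh_to_xyxy(pred_boxes), B.cxcywh_to_xyxy(np.asarray(gt_boxes))
        )
        cost = self.cost_class * c_class + self.cost_bbox * c_bbox + self.cost_giou * c_giou
        return linear_sum_assignment(np.nan_to_num(cost, nan=1e6))


class DetectionCriterion:
    """Focal + L1 + GIoU over all decoder layers and the encoder proposals."""

    def __init__(self, num_classes: int = 1, weight_class: float = 1.0,
                 weight_bbox: float = 5.0, weight_giou: float = 2.0,
                 alpha: float = 0.25, gamma: float = 2.0):
        self.nc = num_classes
        self.wc, self.wb, self.wg = weight_class, weight_bbox, weight_giou
        self.alpha, self.gamma = alpha, gamma
        self.matcher = HungarianMatcher(alpha=alpha, gamma=gamma)

    def _layer_loss(self, logits: Tensor, pboxes: Tensor, targets) -> Tensor:
        """logits (B,Q,nc), pboxes (B,Q,4); targets: list of dicts(labels, boxes)."""
        Bn, Q, nc = logits.shape
        cls_target = np.zeros((Bn, Q, nc))
        matched_p, matched_t = [], []
        n_gt_total = 0
        for b, tgt in enumerate(targets):
            labels = np.asarray(tgt["labels"], dtype=int)
            gtb = np.asarray(tgt["boxes"], dtype=float).reshape(-1, 4)
            n_gt_total += len(gtb)
            pi, ti = self.matcher(logits.numpy()[b], pboxes.numpy()[b], labels, gtb)
            for p, t in zip(pi, ti):
                cls_target[b, p, labels[t]] = 1.0
                matched_p.append((b, p))
                matched_t.append(gtb[t])
        # focal classification over every query
        p = logits.sigmoid()
        ce_pos = -1.0 * (p + 1e-8).log()
        ce_neg = -1.0 * (1.0 - p + 1e-8).log()
        tmask = Tensor(cls_target)
        focal = (
            self.alpha * tmask * (1.0 - p) ** self.gamma * ce_pos
            + (1 - self.alpha) * (1.0 - tmask) * p**self.gamma * ce_neg
        )
        denom = max(n_gt_total, 1)
        loss = self.wc * focal.sum() * (1.0 / denom)
        if matched_p:
            bi = np.array([m[0] for m in matched_p])
            qi = np.array([m[1] for m in matched_p])
            pb = pboxes[bi, qi]  # (M, 4)
            tb = np.stack(matched_t)
            l1 = (pb - Tensor(tb)).abs().sum() * (1.0 / denom)
            giou = B.t_giou_pairs(B.t_cxcywh_to_xyxy(pb), Tensor(B.cxcywh_to_xyxy(tb)))
            giou_loss = (1.0 - giou).sum() * (1.0 / denom)
            loss = loss + self.wb * l1 + self.wg * giou_loss
        return loss

    def __call__(self, outputs: dict, targets) -> Tensor:
        loss = self._layer_loss(outputs["logits"], outputs["boxes"], targets)
        for aux in outputs.get("aux", []):
            loss = loss + self._layer_loss(aux["logits"], aux["boxes"], targets)
        if "enc" in outputs:
            loss = loss + self._layer_loss(outputs["enc"]["logits"], outputs["enc"]["boxes"],
                                           targets)
        return loss
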