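"""Detection metrics (precision/recall/AP/mAP) and detection-to-counting regression.

Precision P = TP/(TP+FP) and recall R = TP/(TP+FN) follow their standard
definitions ("proportion of true positives among predicted / actual
positives"). AP integrates the precision-recall curve; the default uses
COCO-style 101-point interpolation, with 11-point and continuous
(all-recall-points) integration selectable. mAP50:95 averages IoU thresholds
0.50:0.05:0.95.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .boxes import box_iou_xyxy, cxcywh_to_xyxy


@dataclass
class MatchResult:
    """Score-ordered TP/FP flags for one image at one IoU threshold."""

    scores: np.ndarray  # descending
    tp: np.ndarray  # bool, per detection (in score order)
    n_gt: int

    @property
    def fp(self) -> np.ndarray:
        return ~self.tp

    @property
    def n_tp(self) -> int:
        return int(self.tp.sum())

    @property
    def n_fp(self) -> int:
        return int((~self.tp).sum())

    @property
    def n_fn(self) -> int:
        return self.n_gt - self.n_tp


def match_detections(boxes, scores, gt_boxes, iou_threshold: float = 0.5) -> MatchResult:
    """Greedy score-ordered matching: best unmatched ground truth at IoU >= t.

    boxes/gt_boxes are (N,4)/(M,4) in cxcywh (any consistent units).
    """
    if not 0 < iou_threshold < 1:
        raise ValueError("IoU threshold must lie in (0,1)")
    boxes = np.asarray(boxes, dtype=float).reshape(-1, 4)
    scores = np.asarray(scores, dtype=float).reshape(-1)
    gt_boxes = np.asarray(gt_boxes, dtype=float).reshape(-1, 4)
    order = np.argsort(-scores, kind="stable")
    tp = np.zeros(len(boxes), dtype=bool)
    if len(gt_boxes):
        iou = box_iou_xyxy(cxcywh_to_xyxy(boxes[order]), cxcywh_to_xyxy(gt_boxes))
        taken = np.zeros(len(gt_boxes), dtype=bool)
        for i in range(len(order)):
            row = np.where(taken, -1.0, iou[i])
            j = int(row.argmax())
            if row[j] >= iou_threshold:
                tp[i] = True
                taken[j] = True
    return MatchResult(scores=scores[order], tp=tp, n_gt=len(gt_boxes))


def precision_recall(m: MatchResult):
    """(P, R) in percent; zero denominators give 0 with a warning."""
    tp, fp, fn = m.n_tp, m.n_fp, m.n_fn
    if tp + fp == 0:
        warnings.warn("no detections: precision undefined, reporting 0")
        p = 0.0
    else:
        p = 100.0 * tp / (tp + fp)
    if tp + fn == 0:
        warnings.warn("no ground truth: recall undefined, reporting 0")
        r = 0.0
    else:
        r = 100.0 * tp / (tp + fn)
    return p, r


def average_precision(scores, tp_flags, n_gt: int, interpolation: str = "101point") -> float:
    """Area under the interpolated precision-recall curve, in [0,1].

    scores/tp_flags may be pooled across images; they are (re)sorted by score.
    """
    if n_gt == 0:
        raise ValueError("AP undefined with no ground truth")
    scores = np.asarray(scores, dtype=float)
    tp = np.asarray(tp_flags, dtype=bool)
    if len(scores) == 0:
        return 0.0
    order = np.argsort(-scores, kind="stable")
    tp = tp[order]
    ctp = np.cumsum(tp)
    cfp = np.cumsum(~tp)
    recall = ctp / n_gt
    precision = ctp / np.maximum(ctp + cfp, 1)
    # monotone non-increasing precision envelope
    env = np.maximum.accumulate(precision[::-1])[::-1]
    if interpolation == "101point":
        pts = np.linspace(0, 1, 101)
    elif interpolation == "11point":
        pts = np.linspace(0, 1, 11)
    elif interpolation == "continuous":
        # exact area under the step envelope
        r_prev = np.concatenate([[0.0], recall[:-1]])
        return float(((recall - r_prev) * env).sum())
    else:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    idx = np.searchsorted(recall, pts, side="left")
    vals = np.where(idx < len(env), env[np.minimum(idx, len(env) - 1)], 0.0)
    return float(vals.mean())


def map_suite(detections, ground_truths, classes=(0,), interpolation: str = "101point"):
    """(mAP50, mAP50:95) in percent over a set of images.

    detections: per image, (boxes (N,4) cxcywh, scores (N,), labels (N,));
    ground_truths: per image, (boxes (M,4), labels (M,)).
    """
    thresholds = np.arange(0.50, 0.96, 0.05)
    ap_per_thr = {t: [] for t in thresholds}
    for cls in classes:
        n_gt = sum(int((np.asarray(g[1]) == cls).sum()) for g in ground_truths)
        if n_gt == 0:
            warnings.warn(f"class {cls} has no ground truth; excluded from mAP")
            continue
        for t in thresholds:
            scores_all, tp_all = [], []
            for (dboxes, dscores, dlabels), (gboxes, glabels) in zip(detections, ground_truths):
                dsel = np.asarray(dlabels) == cls
                gsel = np.asarray(glabels) == cls
                m = match_detections(
                    np.asarray(dboxes).reshape(-1, 4)[dsel],
                    np.asarray(dscores)[dsel],
                    np.asarray(gboxes).reshape(-1, 4)[gsel],
                    iou_threshold=t,
                )
                scores_all.append(m.scores)
                tp_all.append(m.tp)
            ap = average_precision(np.concatenate(scores_all), np.concatenate(tp_all),
                                   n_gt, interpolation)
            ap_per_thr[t].append(ap)
    if not any(ap_per_thr[t] for t in thresholds):
        raise ValueError("no class with ground truth")
    map50 = 100.0 * float(np.mean(ap_per_thr[thresholds[0]]))
    map5095 = 100.0 * float(np.mean([np.mean(ap_per_thr[t]) for t in thresholds]))
    return map50, map5095


# ---------------------------------------------------------------------------
# Counting


@dataclass
class CountRecord:
    image_id: str
    machine: int
    manual: float  # mean of repeated manual counts

    def __post_init__(self):
        if self.machine < 0 or self.manual < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class CountRegression:
    slope: float
    intercept: float
    r2: float
    mae: float
    rmse: float


def count_regression(records) -> CountRegression:
    """OLS of machine counts on manual counts; MAE/RMSE of the raw differences."""
    records = list(records)
    if len(records) < 3:
        raise ValueError("need at least 3 records for a regression")
    manual = np.array([r.manual for r in records], dtype=float)
    machine = np.array([r.machine for r in records], dtype=float)
    if np.allclose(manual, manual[0]):
        raise ValueError("manual counts have zero variance; R^2 undefined")
    fit = stats.linregress(manual, machine)
    pred = fit.intercept + fit.slope * manual
    ss_res = float(((machine - pred) ** 2).sum())
    ss_tot = float(((machine - machine.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    diff = machine - manual
    return CountRegression(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=r2,
        mae=float(np.abs(diff).mean()),
        rmse=float(np.sqrt((diff**2).mean())),
    )


def regression_plot(records, path):
    """Scatter of machine vs manual counts with the fitted line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    reg = count_regression(records)
    manual = np.array([r.manual for r in records])
    machine = np.array([r.machine for r in records])
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(manual, machine, s=18, alpha=0.7)
    xs = np.linspace(manual.min(), manual.max(), 50)
    ax.plot(xs, reg.intercept + reg.slope * xs, "r-",
            label=f"y={reg.slope:.3f}x+{reg.intercept:.2f}\nR²={reg.r2:.4f}")
    ax.set_xlabel("manual count")
    ax.set_ylabel("machine count")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return reg
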