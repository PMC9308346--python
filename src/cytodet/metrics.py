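"""Evaluation metrics: confusion-matrix statistics for the classifier and
average precision for the detector.

Classification reports sensitivity, specificity, their harmonic mean
(h-mean), F1 and accuracy.  Detection AP uses greedy score-ranked matching
at an IoU threshold and all-points interpolation of the precision-recall
curve; mAP averages AP over classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anchors import iou_boxes_matrix

#: marker for a metric whose denominator is zero
UNDEFINED = float("nan")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @staticmethod
    def from_predictions(pred: np.ndarray, truth: np.ndarray,
                         positive: int = 1) -> "ConfusionCounts":
        pred = np.asarray(pred)
        truth = np.asarray(truth)
        pos_p, pos_t = pred == positive, truth == positive
        return ConfusionCounts(tp=int(np.sum(pos_p & pos_t)),
                               fp=int(np.sum(pos_p & ~pos_t)),
                               tn=int(np.sum(~pos_p & ~pos_t)),
                               fn=int(np.sum(~pos_p & pos_t)))


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else UNDEFINED


def classification_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Sensitivity, specificity, h-mean, F1 and accuracy from counts.

    A metric whose denominator is zero is reported as NaN rather than
    raising, so callers can render it as "undefined".
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    prec = _ratio(tp, tp + fp)
    if np.isnan(sens) or np.isnan(spec) or sens + spec == 0:
        h_mean = UNDEFINED
    else:
        h_mean = 2 * sens * spec / (sens + spec)
    if np.isnan(prec) or np.isnan(sens) or prec + sens == 0:
        f1 = UNDEFINED
    else:
        f1 = 2 * prec * sens / (prec + sens)
    return {
        "sensitivity": sens,
        "specificity": spec,
        "h_mean": h_mean,
        "f1": f1,
        "accuracy": _ratio(tp + tn, counts.total),
    }


# --------------------------------------------------------------------------
# detection AP
# --------------------------------------------------------------------------

def match_detections(detections, gt_boxes, iou_thr: float):
    """Greedy matching of score-ranked detections to ground truth.

    ``detections``: (n, 5) array-like [x0, y0, x1, y1, score];
    ``gt_boxes``: (m, 4).  Each gt box is matched at most once, in order of
    descending detection score.  Returns a boolean TP flag per detection,
    in descending-score order, together with that ordering's scores.
    """
    det = np.asarray(detections, dtype=float).reshape(-1, 5)
    gt = np.asarray(gt_boxes, dtype=float).reshape(-1, 4)
    order = np.argsort(-det[:, 4], kind="stable")
    det = det[order]
    tp = np.zeros(len(det), dtype=bool)
    taken = np.zeros(len(gt), dtype=bool)
    if len(gt) and len(det):
        iou = iou_boxes_matrix(det[:, :4], gt)
        for i in range(len(det)):
            free = np.where(~taken)[0]
            if not len(free):
                break
            j = free[np.argmax(iou[i, free])]
            if iou[i, j] >= iou_thr:
                tp[i] = True
                taken[j] = True
    return tp, det[:, 4]


def average_precision(detections, gt_boxes, iou_thr: float = 0.5) -> float:
    """All-points interpolated AP of one class on one or many images.

    ``detections``/``gt_boxes`` may be single arrays (one image) or lists of
    per-image arrays.  NaN when there is no ground truth.
    """
    det_list = detections if isinstance(detections, (list, tuple)) else [detections]
    gt_list = gt_boxes if isinstance(gt_boxes, (list, tuple)) else [gt_boxes]
    if len(det_list) != len(gt_list):
        raise ValueError("detections and ground truth must pair per image")
    n_gt = sum(len(np.asarray(g).reshape(-1, 4)) for g in gt_list)
    if n_gt == 0:
        return UNDEFINED
    flags, scores = [], []
    for det, gt in zip(det_list, gt_list):
        det = np.asarray(det, dtype=float).reshape(-1, 5)
        if len(det) == 0:
            continue
        tp, s = match_detections(det, gt, iou_thr)
        flags.append(tp)
        scores.append(s)
    if not flags:
        return 0.0
    flags = np.concatenate(flags)
    scores = np.concatenate(scores)
    order = np.argsort(-scores, kind="stable")
    flags = flags[order]
    tp_cum = np.cumsum(flags)
    fp_cum = np.cumsum(~flags)
    recall = tp_cum / n_gt
    precision = tp_cum / (tp_cum + fp_cum)
    # all-points interpolation: precision envelope, integrate over recall
    mrec = np.concatenate([[0.0], recall, [recall[-1]]])
    mpre = np.concatenate([[1.0], precision, [0.0]])
    for i in range(len(mpre) - 2, -1, -1):
        mpre[i] = max(mpre[i], mpre[i + 1])
    idx = np.where(np.diff(mrec) > 0)[0]
    return float(np.sum((mrec[idx + 1] - mrec[idx]) * mpre[idx + 1]))


def map_score(per_class_ap: dict[str, float] | list[float]) -> float:
    """Mean AP over classes, ignoring classes whose AP is undefined."""
    values = list(per_class_ap.values()) if isinstance(per_class_ap, dict) \
        else list(per_class_ap)
    defined = [v for v in values if not np.isnan(v)]
    if not defined:
        return UNDEFINED
    return float(np.mean(defined))


def mean_best_iou(detections, gt_boxes) -> float:
    """Mean over gt boxes of the best detection IoU (localization quality)."""
    det_list = detections if isinstance(detections, (list, tuple)) else [detections]
    gt_list = gt_boxes if isinstance(gt_boxes, (list, tuple)) else [gt_boxes]
    best = []
    for det, gt in zip(det_list, gt_list):
        det = np.asarray(det, dtype=float).reshape(-1, 5)
        gt = np.asarray(gt, dtype=float).reshape(-1, 4)
        if len(gt) == 0:
            continue
        if len(det) == 0:
            best.extend([0.0] * len(gt))
            continue
        iou = iou_boxes_matrix(det[:, :4], gt)
        best.extend(iou.max(axis=0).tolist())
    return float(np.mean(best)) if best else UNDEFINED
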