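"""Detection and classification metrics: confusion counts, precision/recall/
accuracy/F1/specificity, PR curves, AP and mAP, per-class confusion matrices.

AP supports two areas under the precision-recall curve: ``trapezoid`` (the
exact trapezoidal area over the full score sweep, matching a brute-force
threshold enumeration) and ``interp101`` (COCO-style 101-point interpolation,
the default for detector mAP reporting).  mAP is the arithmetic mean of the
per-class APs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detnet.boxes import Detection, iou_xywh


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def validate(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")
        return self

    @property
    def total(self):
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class PRCurve:
    """(recall, precision) pairs swept from high to low score threshold."""

    recall: np.ndarray
    precision: np.ndarray

    def validate(self):
        if np.any(np.diff(self.recall) < 0):
            raise ValueError("recall must be non-decreasing along the sweep")
        return self


def match_detections(detections: list[Detection], truths: list[tuple],
                     iou_thresh: float = 0.5) -> list[bool]:
    """Greedy score-descending matching; one match per ground-truth box.

    ``truths``: (class_id, cx, cy, w, h).  Returns a TP/FP flag per detection
    in score order: TP iff IoU >= thresh with a not-yet-matched truth of the
    same class (the best such truth is consumed).
    """
    order = sorted(range(len(detections)), key=lambda i: -detections[i].score)
    used = [False] * len(truths)
    flags = [False] * len(detections)
    for i in order:
        det = detections[i]
        best, best_iou = -1, iou_thresh
        for j, t in enumerate(truths):
            if used[j] or t[0] != det.class_id:
                continue
            iou = iou_xywh(det.box, t[1:5])
            if iou >= best_iou:
                best, best_iou = j, iou
        if best >= 0:
            used[best] = True
            flags[i] = True
    return flags


def basic_metrics(c: ConfusionCounts) -> dict:
    """The standard confusion-count ratios; a metric whose denominator is zero
    is reported as None (undefined), never as 0."""
    c.validate()

    def ratio(num, den):
        return num / den if den > 0 else None

    precision = ratio(c.tp, c.tp + c.fp)
    recall = ratio(c.tp, c.tp + c.fn)
    f1 = None
    if precision is not None and recall is not None and (precision + recall) > 0:
        f1 = 2 * precision * recall / (precision + recall)
    return {
        "precision": precision,
        "recall": recall,
        "accuracy": ratio(c.tp + c.tn, c.total),
        "f1": f1,
        "specificity": ratio(c.tn, c.tn + c.fp),
    }


def pr_curve(scores: np.ndarray, is_tp: np.ndarray, num_truth: int) -> PRCurve:
    """Precision/recall swept over detections sorted by descending score."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    tp = np.asarray(is_tp, dtype=float)[order]
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(1.0 - tp)
    rec = cum_tp / max(num_truth, 1)
    prec = cum_tp / np.maximum(cum_tp + cum_fp, 1e-12)
    return PRCurve(rec, prec)


def average_precision(curve: PRCurve, method: str = "interp101") -> float:
    """Area under the PR curve.

    ``trapezoid``: exact trapezoidal area over the sweep, anchored at
    (recall 0, precision of the first prediction).  ``interp101``: COCO-style
    mean of interpolated precision at 101 evenly spaced recalls.
    """
    rec, prec = np.asarray(curve.recall), np.asarray(curve.precision)
    if rec.size == 0:
        return 0.0
    if method == "trapezoid":
        r = np.concatenate([[0.0], rec])
        p = np.concatenate([[prec[0]], prec])
        return float(np.trapezoid(p, r))
    if method == "interp101":
        # precision envelope: best precision at recall >= r
        mrec = np.concatenate([[0.0], rec, [1.0]])
        mpre = np.concatenate([[0.0], prec, [0.0]])
        for i in range(mpre.size - 2, -1, -1):
            mpre[i] = max(mpre[i], mpre[i + 1])
        grid = np.linspace(0, 1, 101)
        idx = np.searchsorted(mrec, grid, side="left")
        return float(mpre[np.minimum(idx, mpre.size - 1)].mean())
    raise ValueError(f"unknown AP method {method!r}")


def map_over_classes(aps: list[float]) -> float:
    """mAP = arithmetic mean of the per-class APs."""
    if not aps:
        raise ValueError("mAP needs at least one class AP")
    return float(np.mean(aps))


def detection_map(per_image_detections, per_image_truths, num_classes: int,
                  iou_thresh: float = 0.5, method: str = "interp101") -> dict:
    """mAP over a test set: greedy per-image matching, per-class PR curves."""
    aps = []
    per_class = {}
    for c in range(num_classes):
        scores, flags, n_truth = [], [], 0
        for dets, truths in zip(per_image_detections, per_image_truths):
            tr = [t for t in truths if t[0] == c]
            n_truth += len(tr)
            dc = [d for d in dets if d.class_id == c]
            fl = match_detections(dc, tr, iou_thresh)
            scores.extend(d.score for d in dc)
            flags.extend(fl)
        if n_truth == 0:
            continue
        if not scores:
            aps.append(0.0)
            per_class[c] = 0.0
            continue
        ap = average_precision(pr_curve(np.array(scores), np.array(flags),
                                        n_truth), method)
        aps.append(ap)
        per_class[c] = ap
    return {"mAP": map_over_classes(aps) if aps else 0.0, "per_class": per_class}


def detection_map_range(per_image_detections, per_image_truths, num_classes,
                        thresholds=None, method: str = "interp101") -> float:
    """COCO-style mAP averaged over IoU thresholds 0.5:0.05:0.95."""
    thresholds = thresholds if thresholds is not None else np.arange(0.5, 1.0, 0.05)
    vals = [detection_map(per_image_detections, per_image_truths, num_classes,
                          float(t), method)["mAP"] for t in thresholds]
    return float(np.mean(vals))


def confusion_matrix(per_image_detections, per_image_class, num_classes: int
                     ) -> np.ndarray:
    """Row-normalized image-level confusion matrix, one row per true class and
    one extra column for images with no surviving detection ("missed").  The
    image-level prediction is the class of the highest-scoring detection."""
    m = np.zeros((num_classes, num_classes + 1))
    for dets, true_c in zip(per_image_detections, per_image_class):
        if dets:
            pred = max(dets, key=lambda d: d.score).class_id
            m[true_c, pred] += 1
        else:
            m[true_c, num_classes] += 1
    sums = m.sum(axis=1, keepdims=True)
    return np.divide(m, sums, out=np.zeros_like(m), where=sums > 0)
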