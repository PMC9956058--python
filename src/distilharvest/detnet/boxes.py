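"""Box geometry, anchor estimation, decoding and non-maximum suppression."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..nn import Tensor, no_grad


@dataclass
class Detection:
    class_id: int
    score: float
    box: tuple[float, float, float, float]   # normalized cx, cy, w, h


def iou_xywh(a, b) -> float:
    """IoU of two (cx, cy, w, h) boxes."""
    ax0, ay0 = a[0] - a[2] / 2, a[1] - a[3] / 2
    ax1, ay1 = a[0] + a[2] / 2, a[1] + a[3] / 2
    bx0, by0 = b[0] - b[2] / 2, b[1] - b[3] / 2
    bx1, by1 = b[0] + b[2] / 2, b[1] + b[3] / 2
    iw = max(0.0, min(ax1, bx1) - max(ax0, bx0))
    ih = max(0.0, min(ay1, by1) - max(ay0, by0))
    inter = iw * ih
    union = a[2] * a[3] + b[2] * b[3] - inter
    return inter / union if union > 0 else 0.0


def kmeans_anchors(boxes_wh: np.ndarray, levels: int = 3, per_level: int = 3,
                   seed: int = 0, iters: int = 50) -> list[list[tuple]]:
    """k-means (IoU-agnostic, plain Euclidean on w,h) over normalized box
    sizes; clusters sorted by area and dealt to the three head levels,
    smallest anchors to the finest grid."""
    k = levels * per_level
    wh = np.asarray(boxes_wh, dtype=np.float64)
    rng = np.random.default_rng(seed)
    if len(wh) < k:  # degenerate corpus: jitter what we have
        reps = int(np.ceil(k / max(len(wh), 1)))
        wh = np.concatenate([wh * (1 + 0.05 * i) for i in range(reps)])[:k * 4]
    centers = wh[rng.choice(len(wh), size=k, replace=False)]
    for _ in range(iters):
        d = ((wh[:, None, :] - centers[None]) ** 2).sum(-1)
        lab = d.argmin(1)
        new = np.array([wh[lab == j].mean(0) if (lab == j).any() else centers[j]
                        for j in range(k)])
        if np.allclose(new, centers):
            break
        centers = new
    order = np.argsort(centers.prod(1))
    centers = np.clip(centers[order], 1e-3, 1.0)
    return [[tuple(map(float, c)) for c in centers[i * per_level:(i + 1) * per_level]]
            for i in range(levels)]


def decode_level(raw: np.ndarray, anchors, num_classes: int) -> np.ndarray:
    """Decode one head level to (N, na*g*g, 5+nc): normalized cx,cy,w,h,
    objectness, class probabilities."""
    n, _, g, _ = raw.shape
    na = len(anchors)
    p = raw.reshape(n, na, 5 + num_classes, g, g)
    sig = 1.0 / (1.0 + np.exp(-p))
    gy, gx = np.mgrid[0:g, 0:g]
    cx = (2 * sig[:, :, 0] - 0.5 + gx) / g
    cy = (2 * sig[:, :, 1] - 0.5 + gy) / g
    aw = np.array([a[0] for a in anchors]).reshape(1, na, 1, 1)
    ah = np.array([a[1] for a in anchors]).reshape(1, na, 1, 1)
    bw = (2 * sig[:, :, 2]) ** 2 * aw
    bh = (2 * sig[:, :, 3]) ** 2 * ah
    obj = sig[:, :, 4]
    cls = sig[:, :, 5:]
    out = np.concatenate([np.clip(cx[:, :, None], 0, 1),
                          np.clip(cy[:, :, None], 0, 1),
                          np.clip(bw[:, :, None], 1e-6, 1),
                          np.clip(bh[:, :, None], 1e-6, 1),
                          obj[:, :, None], cls], axis=2)
    return out.transpose(0, 1, 3, 4, 2).reshape(n, na * g * g, 5 + num_classes)


def decode_and_nms(raw_outs, anchors, num_classes: int,
                   score_thresh: float = 0.25,
                   iou_thresh: float = 0.45) -> list[list[Detection]]:
    """Decode all head levels and run per-class greedy NMS.

    ``raw_outs``: list of per-level arrays/Tensors (N, na*(5+nc), g, g).
    Returns one Detection list per batch image, sorted by score descending.
    """
    if not 0 <= score_thresh <= 1 or not 0 <= iou_thresh <= 1:
        raise ValueError("thresholds must be in [0, 1]")
    arrs = [r.data if isinstance(r, Tensor) else np.asarray(r) for r in raw_outs]
    n = arrs[0].shape[0]
    per_level = [decode_level(a, anc, num_classes)
                 for a, anc in zip(arrs, anchors)]
    allp = np.concatenate(per_level, axis=1)
    results = []
    for i in range(n):
        p = allp[i]
        obj = p[:, 4]
        cls_p = p[:, 5:] * obj[:, None]          # score = objectness * class prob
        dets: list[Detection] = []
        for c in range(num_classes):
            sc = cls_p[:, c]
            keep = sc >= score_thresh
            if not keep.any():
                continue
            boxes = p[keep, :4]
            scores = sc[keep]
            order = np.argsort(-scores, kind="stable")
            chosen = []
            for j in order:
                if all(iou_xywh(boxes[j], boxes[k]) <= iou_thresh for k in chosen):
                    chosen.append(j)
            dets.extend(Detection(c, float(scores[j]),
                                  tuple(map(float, boxes[j]))) for j in chosen)
        dets.sort(key=lambda d: -d.score)
        results.append(dets)
    return results
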