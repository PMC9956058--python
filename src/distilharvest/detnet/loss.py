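"""The single-stage composite detection loss (the Lobj of the total
distillation objective): binary cross-entropy for objectness and class plus
CIoU box regression.

Target assignment is yolo-style: at every head level, a ground-truth box is
matched to each anchor whose width/height ratio to the box is within
``ANCHOR_T``, at the cell containing the box centre plus its two nearest
neighbour cells (the decode allows centre offsets in (-0.5, 1.5)).  A box that
fits no anchor anywhere falls back to its single best-IoU anchor.  The
objectness term is balanced between positive and negative cells so the sparse
positives are not drowned out by the background.
"""

from __future__ import annotations

import numpy as np

from ..nn import Tensor
from ..nn.tensor import concat

BOX_GAIN, OBJ_GAIN, CLS_GAIN = 0.05, 1.0, 0.5
ANCHOR_T = 4.0                       # anchor/box wh-ratio gate
LEVEL_BALANCE = (4.0, 1.0, 0.4)      # objectness weight per head level


def _wh_iou(wh: np.ndarray, anchors: np.ndarray) -> np.ndarray:
    inter = np.minimum(wh[:, None, 0], anchors[None, :, 0]) * \
        np.minimum(wh[:, None, 1], anchors[None, :, 1])
    union = wh[:, 0:1] * wh[:, 1:2] + (anchors[:, 0] * anchors[:, 1])[None] - inter
    return inter / union


def build_targets(batch_objects, anchors, grids, num_classes):
    """Per-level positive assignments: (img, anchor, gy, gx, box, cls)."""
    nl = len(anchors)
    na = len(anchors[0])
    flat = np.array([a for lvl in anchors for a in lvl], dtype=np.float64)
    per_level = [dict(img=[], a=[], gy=[], gx=[], box=[], cls=[])
                 for _ in range(nl)]

    def add(lvl, n, a, gy, gx, box, cid):
        g = grids[lvl]
        if 0 <= gy < g and 0 <= gx < g:
            t = per_level[lvl]
            t["img"].append(n); t["a"].append(a)
            t["gy"].append(gy); t["gx"].append(gx)
            t["box"].append(box); t["cls"].append(cid)

    for n, objs in enumerate(batch_objects):
        for cid, cx, cy, w, h in objs:
            box = np.array([cx, cy, w, h], dtype=np.float64)
            matched = False
            for lvl in range(nl):
                g = grids[lvl]
                for a in range(na):
                    aw, ah = anchors[lvl][a]
                    r = max(w / aw, aw / w, h / ah, ah / h)
                    if r >= ANCHOR_T:
                        continue
                    matched = True
                    fx, fy = cx * g, cy * g
                    gx, gy = min(int(fx), g - 1), min(int(fy), g - 1)
                    cells = {(gy, gx),
                             (gy, gx - 1 if fx - gx < 0.5 else gx + 1),
                             (gy - 1 if fy - gy < 0.5 else gy + 1, gx)}
                    for (yy, xx) in cells:
                        add(lvl, n, a, yy, xx, box, int(cid))
            if not matched:
                best = int(_wh_iou(box[None, 2:4], flat).argmax())
                lvl, a = divmod(best, na)
                g = grids[lvl]
                add(lvl, n, a, min(int(cy * g), g - 1), min(int(cx * g), g - 1),
                    box, int(cid))

    # drop duplicate (img, a, gy, gx) slots, first assignment wins
    for t in per_level:
        seen, keep = set(), []
        for i, key in enumerate(zip(t["img"], t["a"], t["gy"], t["gx"])):
            if key not in seen:
                seen.add(key)
                keep.append(i)
        for k in t:
            t[k] = [t[k][i] for i in keep]
    return per_level


def _bce_elem(logits: Tensor, targets: np.ndarray) -> Tensor:
    t = Tensor(targets)
    return (logits.clamp(lo=0.0) - logits * t
            + ((-logits.abs()).exp() + 1.0).log())


def _ciou(pred: Tensor, tgt: np.ndarray) -> Tensor:
    """Complete IoU between decoded (k,4) boxes and their targets."""
    px, py, pw, ph = (pred[:, i] for i in range(4))
    tx, ty, tw, th = (Tensor(tgt[:, i]) for i in range(4))
    px0, px1 = px - pw * 0.5, px + pw * 0.5
    py0, py1 = py - ph * 0.5, py + ph * 0.5
    tx0, tx1 = tx - tw * 0.5, tx + tw * 0.5
    ty0, ty1 = ty - th * 0.5, ty + th * 0.5
    iw = (px1.minimum(tx1) - px0.maximum(tx0)).clamp(lo=0.0)
    ih = (py1.minimum(ty1) - py0.maximum(ty0)).clamp(lo=0.0)
    inter = iw * ih
    union = pw * ph + tw * th - inter + 1e-9
    iou = inter / union
    cw = px1.maximum(tx1) - px0.minimum(tx0)
    chh = py1.maximum(ty1) - py0.minimum(ty0)
    c2 = cw * cw + chh * chh + 1e-9
    rho2 = (px - tx) ** 2 + (py - ty) ** 2
    v = (4.0 / np.pi ** 2) * ((tw / th).atan() - (pw / ph).atan()) ** 2
    alpha = Tensor(v.data / (1.0 - iou.data + v.data + 1e-9))  # detached
    return iou - rho2 / c2 - v * alpha


def detection_loss(raw_outs, batch_objects, anchors, num_classes):
    """Composite loss over all head levels; returns (total, parts dict)."""
    grids = [r.shape[-1] for r in raw_outs]
    tgts = build_targets(batch_objects, anchors, grids, num_classes)
    box_l, cls_l, obj_l = Tensor(0.0), Tensor(0.0), Tensor(0.0)
    npos = 0
    for lvl, (raw, t, bal) in enumerate(zip(raw_outs, tgts, LEVEL_BALANCE)):
        n, _, g, _ = raw.shape
        na = len(anchors[lvl])
        p = raw.reshape(n, na, 5 + num_classes, g, g)
        obj_logits = p[:, :, 4]
        pos_mask = np.zeros((n, na, g, g), dtype=bool)
        if t["img"]:
            ii = np.asarray(t["img"])
            aa = np.asarray(t["a"])
            yy = np.asarray(t["gy"])
            xx = np.asarray(t["gx"])
            idx = (ii, aa, slice(None), yy, xx)
            sel = p[idx]                               # (k, 5+nc)
            k = sel.shape[0]
            npos += k
            sxy = sel[:, 0:2].sigmoid() * 2.0 - 0.5
            cell = np.stack([xx, yy], axis=1).astype(np.float64)
            pxy = (sxy + Tensor(cell)) * (1.0 / g)
            anc = np.array([anchors[lvl][a] for a in t["a"]], dtype=np.float64)
            pwh = (sel[:, 2:4].sigmoid() * 2.0) ** 2 * Tensor(anc)
            tbox = np.asarray(t["box"], dtype=np.float64)
            ciou = _ciou(concat([pxy, pwh], axis=1), tbox)
            box_l = box_l + (1.0 - ciou).mean()
            pos_mask[ii, aa, yy, xx] = True
            cls_target = np.zeros((k, num_classes))
            cls_target[np.arange(k), np.asarray(t["cls"])] = 1.0
            cls_l = cls_l + _bce_elem(sel[:, 5:], cls_target).mean()
        # balanced objectness: positives and negatives each contribute a mean
        raw_bce = _bce_elem(obj_logits, pos_mask.astype(np.float64))
        neg = ~pos_mask
        obj_lvl = (raw_bce * Tensor(neg)).sum() * (1.0 / max(neg.sum(), 1))
        if pos_mask.any():
            obj_lvl = obj_lvl + (raw_bce * Tensor(pos_mask)).sum() \
                * (1.0 / pos_mask.sum())
        obj_l = obj_l + bal * obj_lvl
    total = BOX_GAIN * box_l + OBJ_GAIN * obj_l + CLS_GAIN * cls_l
    parts = {"box": float(box_l.data), "obj": float(obj_l.data),
             "cls": float(cls_l.data), "total": float(total.data),
             "num_pos": npos}
    return total, parts
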