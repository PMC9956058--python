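"""Mini-batch training loops shared by the teacher, the sparsity-trained
student and the distilled student."""

from __future__ import annotations

import numpy as np

from . import nn, slimmer
from .detnet.boxes import decode_and_nms
from .detnet.loss import detection_loss
from .distill import Distiller, DistillWeights, distill_step, total_loss
from .evalkit import detection_map, detection_map_range
from .nn import Tensor


def images_to_batch(images, side: int) -> np.ndarray:
    """AnnotatedImages -> float32 NCHW batch in [0, 1] (resized if needed)."""
    from .imageprep import resize_square
    if not images:
        return np.zeros((0, 3, side, side), dtype=np.float32)
    arrs = []
    for im in images:
        if im.pixels.shape[0] != side:
            im = resize_square(im, side)
        arrs.append(im.pixels.astype(np.float32).transpose(2, 0, 1) / 255.0)
    return np.stack(arrs)


def evaluate_detector(net, X: np.ndarray, objects, score_thresh=0.1,
                      iou_thresh=0.45, map_iou=0.5, batch=16,
                      with_range=False) -> dict:
    """mAP@0.5 (and optionally mAP@[0.5:0.95]) of a detector on a split."""
    net.eval()
    dets = []
    with nn.no_grad():
        for i in range(0, len(X), batch):
            outs = net(X[i:i + batch])
            dets.extend(decode_and_nms(outs, net.spec.anchors,
                                       net.spec.num_classes, score_thresh,
                                       iou_thresh))
    res = detection_map(dets, objects, net.spec.num_classes, map_iou)
    out = {"mAP@0.5": res["mAP"], "per_class": res["per_class"]}
    if with_range:
        out["mAP@0.5:0.95"] = detection_map_range(dets, objects,
                                                  net.spec.num_classes)
    return out


def _cache_teacher_taps(teacher, X_clean: np.ndarray, batch: int = 8) -> dict:
    """The teacher is frozen, so its taps over a fixed clean set are constant;
    computing them once per run instead of once per epoch dominates the cost
    saving of distillation training."""
    teacher.eval()
    cache: dict[str, list] = {}
    with nn.no_grad():
        for i in range(0, len(X_clean), batch):
            _, taps = teacher.forward_with_taps(X_clean[i:i + batch])
            for k, v in taps.items():
                cache.setdefault(k, []).append(v.data)
    return {k: np.concatenate(v) for k, v in cache.items()}


def train_detector(net, X: np.ndarray, objects, *, epochs: int, batch: int,
                   lr: float = 1e-4, seed: int = 0, sparsity_lam: float = 0.0,
                   teacher=None, distiller: Distiller | None = None,
                   weights: DistillWeights | None = None,
                   X_clean: np.ndarray | None = None,
                   lr_schedule: str = "cosine",
                   select_on: tuple | None = None, select_every: int = 5,
                   log=None) -> list[dict]:
    """Adam training of the detection loss, optionally plus BN-L1 sparsity
    and/or the four-stage distillation losses.

    When distilling, the frozen ``teacher`` sees ``X_clean`` (the clean
    rendering of each student image) while the student sees ``X``; the
    teacher's taps are precomputed once since its parameters never move.
    ``lr_schedule``: "cosine" decays to 10 % of ``lr``; "constant" holds it.
    ``select_on=(X_val, objects_val)`` enables validation-based model
    selection: every ``select_every`` epochs (and at the end) the val mAP@0.5
    is measured and the best-scoring parameters are restored after training.
    Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    params = net.parameters()
    tap_cache = None
    if distiller is not None:
        params = params + distiller.parameters()
        if teacher is None:
            raise ValueError("distillation requires a teacher network")
        if X_clean is None:
            X_clean = X
        tap_cache = _cache_teacher_taps(teacher, X_clean, batch)
        weights = weights or DistillWeights()
    opt = nn.Adam(params, lr=lr)
    n = len(X)
    history = []
    best_state = None
    for epoch in range(epochs):
        if lr_schedule == "cosine" and epochs > 1:
            opt.lr = lr * (0.1 + 0.9 * 0.5 *
                           (1 + np.cos(np.pi * epoch / (epochs - 1))))
        net.train()
        order = rng.permutation(n)
        ep = {"epoch": epoch, "loss": 0.0, "ttl1": 0.0, "ttl2": 0.0,
              "ttl3": 0.0, "ttl4": 0.0, "lobj": 0.0}
        nb = 0
        for i in range(0, n, batch):
            idx = order[i:i + batch]
            xb = X[idx]
            ob = [objects[j] for j in idx]
            opt.zero_grad()
            if distiller is not None:
                taps_t = {k: Tensor(v[idx]) for k, v in tap_cache.items()}
                outs_s, taps_s = net.forward_with_taps(xb)
                ttls = distiller.stage_losses(taps_t, taps_s)
                lobj, _parts = detection_loss(outs_s, ob, net.spec.anchors,
                                              net.spec.num_classes)
                total, breakdown = total_loss(ttls, lobj, weights)
                for k, v in zip(("ttl1", "ttl2", "ttl3", "ttl4"),
                                breakdown.ttl):
                    ep[k] += v
                ep["lobj"] += breakdown.lobj
            else:
                total, parts = detection_loss(net(xb), ob, net.spec.anchors,
                                              net.spec.num_classes)
                ep["lobj"] += parts["total"]
            total.backward()
            if sparsity_lam > 0:
                slimmer.apply_sparsity_grad(net, sparsity_lam)
            opt.step()
            ep["loss"] += float(total.data)
            nb += 1
        for k in ("loss", "ttl1", "ttl2", "ttl3", "ttl4", "lobj"):
            ep[k] /= max(nb, 1)
        if select_on is not None and (epoch % select_every == select_every - 1
                                      or epoch == epochs - 1):
            val_map = evaluate_detector(net, select_on[0], select_on[1]
                                        )["mAP@0.5"]
            ep["val_map"] = val_map
            if best_state is None or val_map > best_state[0]:
                best_state = (val_map, net.state_dict())
        history.append(ep)
        if log is not None:
            log(ep)
    if select_on is not None and best_state is not None:
        net.load_state_dict(best_state[1])
    return history
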