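"""The desk-scale experiment protocol behind the headline checks.

Bundles, in one place, the exact experiment definitions that both the test
suite and ``scripts/acceptance.py`` execute: the full-scale dataset-protocol
arithmetic, the full-raster architecture geometry, the pruning guarantees,
the distillation-loss algebra, and the paired distilled-vs-unsupervised
comparison on the degraded synthetic task.

Desk-scale conditions (chosen once; see docs/methods.md): 96-px rasters,
30 images per class with a 3+2 per-class degradation quota (≈ the protocol's
45 % degraded share of the student partition), width-0.25 teacher /
width-0.5 student, Adam at 1e-3 with cosine decay, 60/25/50-epoch schedules
for teacher / sparsity / distillation phases, batch 8.
"""

from __future__ import annotations

from collections import Counter

import numpy as np

from . import nn, slimmer
from .detnet import NetworkSpec, build_network, build_teacher
from .distill import Distiller, DistillWeights, SKFuse, multiscale_l2, total_loss
from .nn import Tensor
from .pipeline import RunConfig, fit_anchors, prepare_data
from .synthcarrot import DEFECT_CLASSES, CorpusSpec, build_corpus
from .training import evaluate_detector, train_detector

TEACHER_EPOCHS = 60
SPARSITY_EPOCHS = 25
DISTILL_EPOCHS = 50
DESK_LR = 3e-3
BATCH = 8
PRUNE_FRACTION = 0.8


def desk_config(seed: int) -> RunConfig:
    cfg = RunConfig()
    cfg.corpus = CorpusSpec(per_class_count=30, image_side=96,
                            degrade_per_class=(3, 2), seed=seed)
    cfg.teacher = NetworkSpec(role="teacher", backbone="cspdarknet",
                              input_side=96, width_multiple=0.25,
                              depth_multiple=0.33, dropout=0.0, seed=seed)
    cfg.student = NetworkSpec(role="student", backbone="mobilenetv2",
                              input_side=96, width_multiple=0.5,
                              depth_multiple=0.33, dropout=0.1, seed=seed)
    cfg.lr = DESK_LR
    cfg.batch = BATCH
    cfg.seed = seed
    return cfg


def study_corpus_counts(seed: int = 0, image_side: int = 96) -> dict:
    """Run the full-scale protocol (5 x 3200, 6:4, 3:1:1, 300+276
    degraded per class) and count what comes out."""
    spec = CorpusSpec(per_class_count=3200, image_side=image_side,
                      degrade_per_class=(300, 276), seed=seed)
    corpus, plan = build_corpus(spec)
    by_ds = Counter(v[0] for v in plan.assignments.values())
    tags = Counter(im.degradation_tag for im in corpus)
    first = DEFECT_CLASSES[0]
    per_class_T = sum(1 for i, v in plan.assignments.items()
                      if i.startswith(first + "_") and v[0] == "T")
    t_sub = Counter(v[1] for v in plan.assignments.values() if v[0] == "T")
    deg_per_class = sum(1 for im in corpus
                        if im.source_id.startswith(first + "_")
                        and im.degradation_tag != "none")
    return {
        "total_images": len(corpus),
        "images_per_class": len(corpus) // len(DEFECT_CLASSES),
        "teacher_set_size": by_ds["T"],
        "student_set_size": by_ds["S"],
        "teacher_per_class": per_class_T,
        "teacher_train_size": t_sub["train"],
        "degraded_per_class": deg_per_class,
        "degraded_x2_total": tags["x2"],
        "degraded_x4_total": tags["x4"],
    }


def geometry_report() -> dict:
    """Single 608-px forward pass of the teacher; tap sides and head grids."""
    spec = NetworkSpec(role="teacher", backbone="cspdarknet", input_side=608,
                       width_multiple=0.25, depth_multiple=0.33)
    net = build_teacher(spec)
    net.eval()
    with nn.no_grad():
        outs, taps = net.forward_with_taps(
            np.zeros((1, 3, 608, 608), dtype=np.float32))
    report = {f"tap_p{i}_side": taps[f"backbone.p{i}"].shape[-1]
              for i in range(1, 6)}
    for lvl, o in enumerate(outs, start=1):
        report[f"head_grid_{lvl}"] = o.shape[-1]
    return report


def pruning_report(seed: int = 0) -> dict:
    """Threshold-fraction accuracy on a tie-free pool plus the reconstruction
    equivalence error of a randomized tiny network."""
    rng = np.random.default_rng(seed)
    pool = rng.uniform(0.001, 1.0, 1000)
    thr = slimmer.global_threshold(pool, PRUNE_FRACTION)
    removed_fraction = float((np.abs(pool) < thr).mean())

    net = build_network(NetworkSpec(role="student", backbone="mobilenetv2",
                                    input_side=96, width_multiple=0.25,
                                    depth_multiple=0.33, dropout=0.0))
    for _name, u in net.bn_units():
        c = u.bn.channels
        u.bn.weight.data = rng.normal(0, 1, c).astype(np.float32)
        u.bn.bias.data = rng.normal(0, 0.5, c).astype(np.float32)
        u.bn.running_mean = rng.normal(0, 0.5, c).astype(np.float32)
        u.bn.running_var = rng.uniform(0.5, 2.0, c).astype(np.float32)
    net.eval()
    thr_net = slimmer.global_threshold(slimmer.collect_gammas(net), 0.5)
    mask = slimmer.build_masks(net, thr_net, 0.5)
    for name, u in net.bn_units():
        if name in mask.keeps:
            removed = ~mask.keeps[name]
            u.bn.weight.data[removed] = 0.0
            u.bn.bias.data[removed] = 0.0
    pruned = slimmer.reconstruct(net, mask)
    max_rel_err = 0.0
    with nn.no_grad():
        for i in range(5):
            x = rng.random((20, 3, 96, 96)).astype(np.float32)
            for a, b in zip(net(x), pruned(x)):
                scale = max(float(np.abs(a.data).max()), 1e-9)
                max_rel_err = max(max_rel_err,
                                  float(np.abs(a.data - b.data).max()) / scale)
    return {
        "removed_fraction_at_80pct": removed_fraction,
        "equivalence_max_rel_err": max_rel_err,
        "params_before": net.num_parameters(),
        "params_after": pruned.num_parameters(),
    }


def loss_algebra_report(seed: int = 0) -> dict:
    """Eq.-style fixtures: softmax pair sums to one, unit TtL fixture equals
    0.1+0.2+0.5+0.2, pooled-L2 hand value."""
    rng = np.random.default_rng(seed)
    fuse = SKFuse(8, rng=np.random.default_rng(seed))
    b1 = Tensor(rng.standard_normal((2, 8, 4, 4)))
    b2 = Tensor(rng.standard_normal((2, 8, 4, 4)))
    _, a, b = fuse(b1, b2)
    total, bd = total_loss([1.0, 1.0, 1.0, 1.0], 0.0)
    ones = Tensor(np.ones((1, 1, 2, 2)))
    zeros = Tensor(np.zeros((1, 1, 2, 2)))
    return {
        "fusion_weight_sum": float((a.data + b.data).mean()),
        "fusion_weight_sum_max_dev": float(np.abs(a.data + b.data - 1).max()),
        "unit_ttl_total": float(total.data),
        "total_identity_residual": bd.identity_residual(),
        "pooled_l2_ones_vs_zeros": float(multiscale_l2(ones, zeros,
                                                       scales=(1,)).data),
    }


def distillation_benefit(seed: int = 0, n_seeds: int = 3) -> dict:
    """Teacher on T, sparsity-trained + pruned student, then the paired
    distilled / unsupervised comparison on the S test split over ``n_seeds``
    paired seeds.  Establishes the supervised-vs-unsupervised ordering the method claims."""
    cfg = desk_config(seed)
    data, _plan = prepare_data(cfg)
    fit_anchors(data, cfg)
    tr_T = data[("T", "train")]
    va_T = data[("T", "val")]
    tr_S = data[("S", "train")]
    va_S = data[("S", "val")]
    te_S = data[("S", "test")]

    teacher = build_network(cfg.teacher)
    train_detector(teacher, tr_T["X"], tr_T["objects"], epochs=TEACHER_EPOCHS,
                   batch=BATCH, lr=DESK_LR, seed=seed,
                   select_on=(va_T["X"], va_T["objects"]))
    teacher_map = evaluate_detector(teacher, data[("T", "test")]["X"],
                                    data[("T", "test")]["objects"])["mAP@0.5"]

    student = build_network(cfg.student)
    train_detector(student, tr_S["X"], tr_S["objects"], epochs=SPARSITY_EPOCHS,
                   batch=BATCH, lr=DESK_LR, seed=seed + 1, sparsity_lam=1e-4)
    pruned, mask, _report = slimmer.prune_network(student, PRUNE_FRACTION)

    probe = np.zeros((1, 3, cfg.student.input_side, cfg.student.input_side),
                     dtype=np.float32)
    teacher.eval()
    pruned.eval()
    with nn.no_grad():
        _, taps_t = teacher.forward_with_taps(probe)
        _, taps_s = pruned.forward_with_taps(probe)

    runs = {"distilled": [], "unsupervised": []}
    for k in range(n_seeds):
        pair_seed = seed + 10 * k
        for mode in ("distilled", "unsupervised"):
            net = slimmer.clone_network(pruned)
            kwargs = {}
            if mode == "distilled":
                kwargs = dict(teacher=teacher,
                              distiller=Distiller(taps_t, taps_s,
                                                  seed=pair_seed),
                              weights=DistillWeights(),
                              X_clean=tr_S["X_clean"])
            train_detector(net, tr_S["X"], tr_S["objects"],
                           epochs=DISTILL_EPOCHS, batch=BATCH, lr=DESK_LR,
                           seed=pair_seed + 2,
                           select_on=(va_S["X"], va_S["objects"]), **kwargs)
            m = evaluate_detector(net, te_S["X"], te_S["objects"])["mAP@0.5"]
            runs[mode].append(m)
    deltas = [d - u for d, u in zip(runs["distilled"], runs["unsupervised"])]
    return {
        "teacher_T_test_map": teacher_map,
        "n_teacher_test_images": len(data[("T", "test")]["X"]),
        "student_params_before_prune": student.num_parameters(),
        "student_params_after_prune": pruned.num_parameters(),
        "pruned_removed_fraction": mask.removed_fraction(),
        "distilled_maps": runs["distilled"],
        "unsupervised_maps": runs["unsupervised"],
        "median_distilled_map": float(np.median(runs["distilled"])),
        "median_unsupervised_map": float(np.median(runs["unsupervised"])),
        "median_delta": float(np.median(deltas)),
        "n_test_images": len(te_S["X"]),
    }
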