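"""Run orchestration: the three-step operation flow as reproducible runs.

Step 1 trains the full-resolution teacher on the clean partition ``T``.
Step 2 swaps the backbone, sparsity-trains the student on the degraded
partition ``S`` and prunes it at the global threshold.  Step 3 trains the
pruned student on ``S`` twice under the same seed — once under multi-stage
teacher guidance and once unsupervised — and juxtaposes their test metrics.

Every run writes a self-contained directory: resolved config, seeds, logs,
checkpoints and metrics.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import slimmer
from .detnet import NetworkSpec, build_network, kmeans_anchors
from .detnet.model import Detector
from .distill import Distiller, DistillWeights, StagePairing
from .errors import ConfigurationError, DataError
from .synthcarrot import (CorpusSpec, SplitPlan, apply_degradation_quota,
                          generate_corpus)
from .training import evaluate_detector, images_to_batch, train_detector


@dataclass
class RunConfig:
    corpus: CorpusSpec = field(default_factory=lambda: CorpusSpec(
        per_class_count=20, image_side=96, degrade_per_class=(4, 3)))
    teacher: NetworkSpec = field(default_factory=lambda: NetworkSpec(
        role="teacher", backbone="cspdarknet"))
    student: NetworkSpec = field(default_factory=lambda: NetworkSpec(
        role="student", backbone="mobilenetv2"))
    lr: float = 1e-4
    batch: int = 8
    epochs: int = 20
    sparsity_lambda: float = 1e-4
    prune_fraction: float = 0.8
    distill_weights: DistillWeights = field(default_factory=DistillWeights)
    score_thresh: float = 0.1
    iou_thresh: float = 0.45
    seed: int = 0

    def to_dict(self):
        return {
            "corpus": vars(self.corpus).copy(),
            "teacher": self.teacher.to_dict(),
            "student": self.student.to_dict(),
            "train": {"lr": self.lr, "batch": self.batch, "epochs": self.epochs},
            "prune": {"lambda": self.sparsity_lambda,
                      "fraction": self.prune_fraction},
            "distill": {"alpha": self.distill_weights.alpha,
                        "beta": self.distill_weights.beta_w,
                        "theta": self.distill_weights.theta,
                        "gamma": self.distill_weights.gamma_w},
            "eval": {"score_thresh": self.score_thresh,
                     "iou_thresh": self.iou_thresh},
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cfg = cls()
        try:
            if "corpus" in d:
                c = dict(d["corpus"])
                for k in ("ts_ratio", "tvt_ratio", "degrade_per_class"):
                    if k in c:
                        c[k] = tuple(c[k])
                cfg.corpus = CorpusSpec(**c)
            if "teacher" in d:
                cfg.teacher = NetworkSpec.from_dict(d["teacher"])
            if "student" in d:
                cfg.student = NetworkSpec.from_dict(d["student"])
            tr = d.get("train", {})
            cfg.lr = float(tr.get("lr", cfg.lr))
            cfg.batch = int(tr.get("batch", cfg.batch))
            cfg.epochs = int(tr.get("epochs", cfg.epochs))
            pr = d.get("prune", {})
            cfg.sparsity_lambda = float(pr.get("lambda", cfg.sparsity_lambda))
            cfg.prune_fraction = float(pr.get("fraction", cfg.prune_fraction))
            di = d.get("distill", {})
            cfg.distill_weights = DistillWeights(
                alpha=float(di.get("alpha", 0.1)),
                beta_w=float(di.get("beta", 0.2)),
                theta=float(di.get("theta", 0.5)),
                gamma_w=float(di.get("gamma", 0.2)))
            ev = d.get("eval", {})
            cfg.score_thresh = float(ev.get("score_thresh", cfg.score_thresh))
            cfg.iou_thresh = float(ev.get("iou_thresh", cfg.iou_thresh))
            cfg.seed = int(d.get("seed", cfg.seed))
        except (TypeError, ValueError) as exc:
            raise ConfigurationError(str(exc)) from exc
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def write_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# checkpoints: npz with an embedded spec copy


def save_checkpoint(net: Detector, path):
    state = net.state_dict()
    np.savez(path, __spec__=np.array(yaml.safe_dump(net.spec.to_dict())),
             **state)


def load_checkpoint(path) -> Detector:
    path = Path(path)
    if not path.exists():
        raise DataError(f"checkpoint not found: {path}")
    data = np.load(path, allow_pickle=False)
    spec = NetworkSpec.from_dict(yaml.safe_load(str(data["__spec__"])))
    net = build_network(spec)
    net.load_state_dict({k: data[k] for k in data.files if k != "__spec__"})
    return net


# ---------------------------------------------------------------------------
# corpus assembly with paired clean/degraded renderings


def prepare_data(cfg: RunConfig):
    """Generate the corpus and tensorize every split.

    Returns a dict with, per split: NCHW arrays and object lists; for the
    student splits both the degraded pixels (student input) and the clean
    rendering of the same scenes (teacher input during distillation).
    """
    clean, plan = generate_corpus(cfg.corpus)
    clean_pixels = {im.source_id: im for im in clean}
    degraded = [type(im)(im.pixels.copy(), list(im.objects), im.degradation_tag,
                         im.source_id) for im in clean]
    degraded = apply_degradation_quota(degraded, plan, cfg.corpus)
    by_id = {im.source_id: im for im in degraded}
    side = cfg.teacher.input_side
    data = {}
    for dset in ("T", "S"):
        for subset in ("train", "val", "test"):
            ids = sorted(plan.members(dset, subset))
            ims = [by_id[i] for i in ids]
            data[(dset, subset)] = {
                "ids": ids,
                "X": images_to_batch(ims, side),
                "X_clean": images_to_batch([clean_pixels[i] for i in ids], side),
                "objects": [im.objects for im in ims],
            }
    return data, plan


def fit_anchors(data, cfg: RunConfig):
    """k-means anchors over all training boxes, shared by both networks."""
    wh = [(o[3], o[4]) for key in (("T", "train"), ("S", "train"))
          for objs in data[key]["objects"] for o in objs]
    anchors = kmeans_anchors(np.array(wh), seed=cfg.seed)
    cfg.teacher.anchors = anchors
    cfg.student.anchors = anchors
    return anchors


def _write_history(history, path):
    if not history:
        return
    fields = list(dict.fromkeys(k for h in history for k in h))
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=fields, restval="")
        w.writeheader()
        w.writerows(history)


# ---------------------------------------------------------------------------
# the three steps


def run_step1_train_teacher(cfg: RunConfig, outdir, data=None):
    """Train the teacher on T-train; report on T-val and T-test."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if data is None:
        data, _ = prepare_data(cfg)
        fit_anchors(data, cfg)
    cfg.write_yaml(outdir / "config.yaml")
    teacher = build_network(cfg.teacher)
    tr = data[("T", "train")]
    va = data[("T", "val")]
    select = (va["X"], va["objects"]) if len(va["X"]) else None
    history = train_detector(teacher, tr["X"], tr["objects"], epochs=cfg.epochs,
                             batch=cfg.batch, lr=cfg.lr, seed=cfg.seed,
                             select_on=select)
    _write_history(history, outdir / "teacher_loss.csv")
    metrics = {split: evaluate_detector(teacher, data[("T", split)]["X"],
                                        data[("T", split)]["objects"],
                                        cfg.score_thresh, cfg.iou_thresh)
               for split in ("val", "test")}
    save_checkpoint(teacher, outdir / "teacher.npz")
    with open(outdir / "teacher_metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=2, default=float)
    return teacher, metrics, history


def run_step2_build_student(cfg: RunConfig, outdir, data=None):
    """Sparsity-train the student on S, prune at the global threshold,
    reconstruct, and emit the per-layer channel report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if data is None:
        data, _ = prepare_data(cfg)
        fit_anchors(data, cfg)
    student = build_network(cfg.student)
    tr = data[("S", "train")]
    history = train_detector(student, tr["X"], tr["objects"], epochs=cfg.epochs,
                             batch=cfg.batch, lr=cfg.lr, seed=cfg.seed + 1,
                             sparsity_lam=cfg.sparsity_lambda)
    _write_history(history, outdir / "sparsity_loss.csv")
    pruned, mask, report = slimmer.prune_network(student, cfg.prune_fraction)
    slimmer.write_report_tsv(report, outdir / "prune_report.tsv")
    size = {"params_before": student.num_parameters(),
            "params_after": pruned.num_parameters(),
            "removed_channel_fraction": mask.removed_fraction(),
            "global_threshold": mask.global_threshold}
    save_checkpoint(pruned, outdir / "student_pruned.npz")
    with open(outdir / "prune_summary.json", "w") as fh:
        json.dump(size, fh, indent=2, default=float)
    return pruned, size, report


def run_step3_distill(cfg: RunConfig, outdir, teacher=None, student=None,
                      data=None):
    """Distilled vs unsupervised student on S under the same seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if data is None:
        data, _ = prepare_data(cfg)
        fit_anchors(data, cfg)
    if teacher is None:
        teacher = load_checkpoint(Path(outdir) / "teacher.npz")
    if student is None:
        student = load_checkpoint(Path(outdir) / "student_pruned.npz")

    tr = data[("S", "train")]
    va = data[("S", "val")]
    te = data[("S", "test")]
    select = (va["X"], va["objects"]) if len(va["X"]) else None
    results = {}
    curves = {}
    for mode in ("distilled", "unsupervised"):
        net = slimmer.clone_network(student)
        if mode == "distilled":
            teacher.eval()
            with_probe = _probe_taps(teacher, student, cfg)
            distiller = Distiller(*with_probe, seed=cfg.seed)
            history = train_detector(
                net, tr["X"], tr["objects"], epochs=cfg.epochs, batch=cfg.batch,
                lr=cfg.lr, seed=cfg.seed + 2, teacher=teacher,
                distiller=distiller, weights=cfg.distill_weights,
                X_clean=tr["X_clean"], select_on=select)
        else:
            history = train_detector(net, tr["X"], tr["objects"],
                                     epochs=cfg.epochs, batch=cfg.batch,
                                     lr=cfg.lr, seed=cfg.seed + 2,
                                     select_on=select)
        _write_history(history, outdir / f"{mode}_loss.csv")
        curves[mode] = history
        results[mode] = evaluate_detector(net, te["X"], te["objects"],
                                          cfg.score_thresh, cfg.iou_thresh)
        save_checkpoint(net, outdir / f"student_{mode}.npz")
    report = {
        "weights": {"alpha": cfg.distill_weights.alpha,
                    "beta": cfg.distill_weights.beta_w,
                    "theta": cfg.distill_weights.theta,
                    "gamma": cfg.distill_weights.gamma_w},
        "S_test_mAP@0.5": {m: results[m]["mAP@0.5"] for m in results},
        "distill_minus_unsupervised": results["distilled"]["mAP@0.5"]
        - results["unsupervised"]["mAP@0.5"],
    }
    with open(outdir / "distill_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return results, curves, report


def _probe_taps(teacher, student, cfg: RunConfig):
    side = cfg.student.input_side
    probe = np.zeros((1, 3, side, side), dtype=np.float32)
    teacher.eval()
    student.eval()
    from . import nn
    with nn.no_grad():
        _, taps_t = teacher.forward_with_taps(probe)
        _, taps_s = student.forward_with_taps(probe)
    return taps_t, taps_s


def plot_loss_curves(curves: dict, path):
    """Distilled vs unsupervised training loss (matplotlib PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(6, 4))
    for mode, hist in curves.items():
        ax.plot([h["epoch"] for h in hist], [h["lobj"] for h in hist],
                label=f"{mode} (object loss)")
    ax.set_xlabel("epoch")
    ax.set_ylabel("loss")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
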