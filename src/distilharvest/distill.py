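"""Multi-stage feature distillation with learned importance weights.

The trained teacher's intermediate features supervise the student at four
stages.  Where a stage taps several teacher maps, they are cascaded and fused
SK-style: a pooled descriptor Z (global average pool -> fully connected layer
over the cascaded maps) drives two trainable matrices A and B whose softmax
pair

    a = e^{AZ} / (e^{AZ} + e^{BZ}),    b = e^{BZ} / (e^{AZ} + e^{BZ})

weights the two branches channelwise (a + b = 1 elementwise); the fused map
``a * branch1 + b * branch2`` is the regression target.  Each stage loss TtL_i
is the sum of L2 distances between the teacher and student maps average-pooled
at four scales, and the total training objective is

    L_total = alpha*TtL1 + beta*TtL2 + theta*TtL3 + gamma*TtL4 + Lobj

with the stage weights alpha=0.1, beta=0.2, theta=0.5, gamma=0.2 and Lobj
the ordinary single-stage detection loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .detnet.loss import detection_loss
from .errors import ConfigurationError
from .nn import Tensor, adaptive_avg_pool2d

DEFAULT_POOL_SCALES = (1, 2, 4, 8)


@dataclass
class DistillWeights:
    """Stage weights of the total loss (beta/gamma renamed to avoid clashing
    with the BN affine parameters)."""

    alpha: float = 0.1
    beta_w: float = 0.2
    theta: float = 0.5
    gamma_w: float = 0.2

    def as_tuple(self):
        return (self.alpha, self.beta_w, self.theta, self.gamma_w)


@dataclass
class DistillLossBreakdown:
    ttl: tuple[float, float, float, float]
    lobj: float
    weights: DistillWeights
    total: float

    def identity_residual(self) -> float:
        """|total - (alpha*TtL1 + ... + Lobj)| — must be ~0 by construction."""
        w = self.weights.as_tuple()
        return abs(self.total - (sum(wi * t for wi, t in zip(w, self.ttl))
                                 + self.lobj))


@dataclass
class StagePairing:
    """teacher tap names (>=1; fused when several) -> student tap name."""

    stages: list[tuple[list[str], str]] = field(default_factory=lambda: [
        (["backbone.p3", "backbone.p4", "backbone.p5"], "backbone.p5"),
        (["neck.n1"], "neck.n1"),
        (["neck.n2", "neck.n3"], "neck.n3"),
        (["head.out3"], "head.out3"),
    ])
    pool_scales: tuple[int, ...] = DEFAULT_POOL_SCALES

    def validate(self):
        if len(self.stages) != 4:
            raise ConfigurationError("exactly four distillation stages required")
        if len(self.pool_scales) != 4:
            raise ConfigurationError("four pooling scales required")
        return self


class SKFuse(nn.Module):
    """Two-branch selective fusion (per-stage A and B matrices)."""

    def __init__(self, channels: int, descriptor_dim: int | None = None, rng=None):
        super().__init__()
        d = descriptor_dim or max(channels // 2, 4)
        self.channels = channels
        self.fc = nn.Linear(2 * channels, d, rng=rng)
        self.A = nn.Linear(d, channels, bias=False, rng=rng)
        self.B = nn.Linear(d, channels, bias=False, rng=rng)

    def forward(self, b1: Tensor, b2: Tensor):
        cascade = nn.concat([b1, b2], axis=1)
        z = self.fc(adaptive_avg_pool2d(cascade, 1).reshape(
            cascade.shape[0], 2 * self.channels))
        az, bz = self.A(z), self.B(z)
        m = az.maximum(bz)
        ea, eb = (az - m).exp(), (bz - m).exp()
        denom = ea + eb
        a, b = ea / denom, eb / denom
        n = b1.shape[0]
        a4 = a.reshape(n, self.channels, 1, 1)
        b4 = b.reshape(n, self.channels, 1, 1)
        return a4 * b1 + b4 * b2, a, b


def sk_fuse(features: list[Tensor], state: SKFuse):
    """Fuse two same-shape feature maps; returns (fused, a, b)."""
    if len(features) < 2:
        raise ConfigurationError("sk_fuse needs at least two feature maps")
    fused, a, b = state(features[0], features[1])
    for extra in features[2:]:
        fused, a, b = state(fused, extra)
    return fused, a, b


def multiscale_l2(fm_t: Tensor, fm_s: Tensor,
                  scales=DEFAULT_POOL_SCALES, adapter=None) -> Tensor:
    """Sum over four scales of the mean squared difference of the
    average-pooled teacher and student maps (>= 0, zero iff they pool equal)."""
    if adapter is not None:
        fm_s = adapter(fm_s)
    if fm_t.shape != fm_s.shape:
        raise ConfigurationError(
            f"feature shapes differ after adaptation: {fm_t.shape} vs {fm_s.shape}")
    side = fm_t.shape[-1]
    loss = Tensor(0.0)
    for s in scales:
        s_eff = min(int(s), side)
        pt = adaptive_avg_pool2d(fm_t, s_eff)
        ps = adaptive_avg_pool2d(fm_s, s_eff)
        loss = loss + ((pt - ps) ** 2).mean()
    return loss


def total_loss(ttls, lobj, weights: DistillWeights = DistillWeights()):
    """Weighted sum of the four stage losses plus the object loss.

    Accepts Tensors (training) or floats (bookkeeping); returns
    (total, DistillLossBreakdown).
    """
    w = weights.as_tuple()
    if any(wi < 0 for wi in w):
        raise ConfigurationError("stage weights must be >= 0")
    ttls = [t if isinstance(t, Tensor) else Tensor(float(t)) for t in ttls]
    lobj_t = lobj if isinstance(lobj, Tensor) else Tensor(float(lobj))
    total = lobj_t
    for wi, t in zip(w, ttls):
        total = total + wi * t
    breakdown = DistillLossBreakdown(
        ttl=tuple(float(t.data) for t in ttls), lobj=float(lobj_t.data),
        weights=weights, total=float(total.data))
    return total, breakdown


class _StageHead(nn.Module):
    """Per-stage plumbing: teacher branch channel/raster alignment, optional
    SK fusion, and the trainable 1x1 student projection."""

    def __init__(self, t_shapes, s_shape, rng):
        super().__init__()
        ct, raster = t_shapes[-1][1], t_shapes[-1][2:]
        self.target_channels = ct
        self.target_raster = raster
        self.branch_adapters = [
            nn.Conv2d(c, ct, 1, bias=True, rng=rng) if c != ct else None
            for (_, c, *_r) in t_shapes]
        self.fuse = SKFuse(ct, rng=rng) if len(t_shapes) > 1 else None
        cs = s_shape[1]
        self.student_adapter = nn.Conv2d(cs, ct, 1, bias=True, rng=rng) \
            if cs != ct else None

    def _align(self, fm, adapter):
        if adapter is not None:
            fm = adapter(fm)
        if tuple(fm.shape[2:]) != tuple(self.target_raster):
            fm = adaptive_avg_pool2d(fm, self.target_raster)
        return fm

    def teacher_target(self, feats):
        branches = [self._align(f, a)
                    for f, a in zip(feats, self.branch_adapters)]
        if self.fuse is None:
            return branches[0], None, None
        return sk_fuse(branches, self.fuse)

    def student_feature(self, fm):
        return self._align(fm, self.student_adapter)


class Distiller(nn.Module):
    """Holds the four stage heads; built from one probe forward of each net."""

    def __init__(self, taps_t: dict, taps_s: dict,
                 pairing: StagePairing | None = None, seed: int = 0):
        super().__init__()
        self.pairing = (pairing or StagePairing()).validate()
        rng = np.random.default_rng(seed)
        self.stage_heads = []
        for t_names, s_name in self.pairing.stages:
            for n in t_names:
                if n not in taps_t:
                    raise ConfigurationError(f"teacher tap {n!r} not found")
            if s_name not in taps_s:
                raise ConfigurationError(f"student tap {s_name!r} not found")
            t_shapes = [taps_t[n].shape for n in t_names]
            self.stage_heads.append(_StageHead(t_shapes, taps_s[s_name].shape, rng))

    def stage_losses(self, taps_t: dict, taps_s: dict) -> list[Tensor]:
        losses = []
        for head, (t_names, s_name) in zip(self.stage_heads, self.pairing.stages):
            target, _a, _b = head.teacher_target([taps_t[n] for n in t_names])
            student = head.student_feature(taps_s[s_name])
            losses.append(multiscale_l2(target, student, self.pairing.pool_scales))
        return losses


def distill_train(teacher, student, X_degraded, objects, *, X_clean=None,
                  pairing: StagePairing | None = None,
                  weights: DistillWeights | None = None, epochs: int = 50,
                  batch: int = 8, lr: float = 1e-4, seed: int = 0,
                  select_on=None):
    """Train ``student`` on the degraded set under frozen-teacher guidance.

    Convenience wrapper: probes both networks for tap shapes, builds the
    :class:`Distiller`, and runs the shared training loop.  Returns
    ``(student, distiller, history)``; the per-epoch history rows carry the
    TtL1..TtL4 / Lobj breakdown.
    """
    from .training import train_detector
    side = student.spec.input_side
    probe = np.zeros((1, 3, side, side), dtype=np.float32)
    teacher.eval()
    was_training = student.training
    student.eval()
    with nn.no_grad():
        _, taps_t = teacher.forward_with_taps(probe)
        _, taps_s = student.forward_with_taps(probe)
    student.train(was_training)
    distiller = Distiller(taps_t, taps_s, pairing=pairing, seed=seed)
    history = train_detector(student, X_degraded, objects, epochs=epochs,
                             batch=batch, lr=lr, seed=seed, teacher=teacher,
                             distiller=distiller, weights=weights,
                             X_clean=X_clean, select_on=select_on)
    return student, distiller, history


def distill_step(teacher, student, distiller: Distiller, x_clean, x_degraded,
                 batch_objects, weights: DistillWeights):
    """One distillation forward: frozen-teacher taps on the clean rendering,
    student taps on the degraded one, four TtLs + Lobj -> total."""
    with nn.no_grad():
        _, taps_t = teacher.forward_with_taps(x_clean)
    outs_s, taps_s = student.forward_with_taps(x_degraded)
    ttls = distiller.stage_losses(taps_t, taps_s)
    lobj, parts = detection_loss(outs_s, batch_objects, student.spec.anchors,
                                 student.spec.num_classes)
    total, breakdown = total_loss(ttls, lobj, weights)
    return total, breakdown, parts
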