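"""Teacher and student single-stage detectors.

The teacher is a yolo-v5-family network: Focus stem, CSP-bottleneck backbone
with stride-2 downsampling, SPP, an FPN (top-down) + PAN (bottom-up) neck and
three prediction heads at strides 8/16/32.  The student keeps the identical
neck/head geometry but swaps the backbone for a mobilenetv2-style stack of
inverted-residual blocks whose last three downsampling outputs feed the neck.

``forward_with_taps`` exposes the named intermediate feature maps
(``backbone.p1..p5``, ``neck.n1..n3``, ``head.out1..out3``) that the
distillation losses regress; successive backbone taps halve the spatial side
(608 -> 304/152/76/38/19).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .. import nn
from ..errors import ConfigurationError
from ..nn import Tensor
from .blocks import (CSP, SPP, ConvBNAct, DetectHead, Focus, InvertedResidual,
                     PruneState)

TAP_NAMES = ("backbone.p1", "backbone.p2", "backbone.p3", "backbone.p4",
             "backbone.p5", "neck.n1", "neck.n2", "neck.n3",
             "head.out1", "head.out2", "head.out3")

# default anchors (normalized w,h per head level) for the synthetic corpus;
# replaced by k-means over the corpus boxes at run time
DEFAULT_ANCHORS = [[(0.08, 0.18), (0.12, 0.28), (0.18, 0.38)],
                   [(0.22, 0.50), (0.30, 0.60), (0.38, 0.70)],
                   [(0.45, 0.80), (0.55, 0.90), (0.70, 0.95)]]


@dataclass
class NetworkSpec:
    role: str = "teacher"                 # teacher | student
    backbone: str = "cspdarknet"          # cspdarknet | mobilenetv2
    depth_multiple: float = 0.33
    width_multiple: float = 0.25
    input_side: int = 96
    num_classes: int = 5
    dropout: float = 0.6
    anchors: list = field(default_factory=lambda: [list(l) for l in DEFAULT_ANCHORS])
    seed: int = 0

    def validate(self):
        if self.input_side % 32:
            raise ConfigurationError("input_side must be a multiple of 32")
        if self.num_classes < 1:
            raise ConfigurationError("num_classes must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigurationError("dropout must be in [0, 1)")
        if self.role not in ("teacher", "student"):
            raise ConfigurationError(f"bad role {self.role!r}")
        return self

    def to_dict(self):
        return {"role": self.role, "backbone": self.backbone,
                "depth_multiple": self.depth_multiple,
                "width_multiple": self.width_multiple,
                "input_side": self.input_side, "num_classes": self.num_classes,
                "dropout": self.dropout,
                "anchors": [[list(map(float, a)) for a in l] for l in self.anchors],
                "seed": self.seed}

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        if "anchors" in d:
            d["anchors"] = [[tuple(a) for a in l] for l in d["anchors"]]
        return cls(**d)


def _width(base: int, mult: float, divisor: int = 2) -> int:
    return max(divisor, int(round(base * mult / divisor)) * divisor)


def _depth(base: int, mult: float) -> int:
    return max(1, round(base * mult))


class Neck(nn.Module):
    """FPN top-down fusion followed by PAN bottom-up aggregation."""

    def __init__(self, c3, c4, c5, n, act, rng):
        super().__init__()
        self.lat5 = ConvBNAct(c5, c4, 1, act=act, rng=rng)
        self.csp_f4 = CSP(2 * c4, c4, n, shortcut=False, act=act, rng=rng)
        self.lat4 = ConvBNAct(c4, c3, 1, act=act, rng=rng)
        self.csp_f3 = CSP(2 * c3, c3, n, shortcut=False, act=act, rng=rng)
        self.down3 = ConvBNAct(c3, c3, 3, 2, act=act, rng=rng)
        self.csp_p4 = CSP(2 * c3, c4, n, shortcut=False, act=act, rng=rng)
        self.down4 = ConvBNAct(c4, c4, 3, 2, act=act, rng=rng)
        self.csp_p5 = CSP(2 * c4, c5, n, shortcut=False, act=act, rng=rng)

    def forward(self, p3, p4, p5):
        l5 = self.lat5(p5)
        f4 = self.csp_f4(nn.concat([nn.upsample_nearest2x(l5), p4]))
        l4 = self.lat4(f4)
        n1 = self.csp_f3(nn.concat([nn.upsample_nearest2x(l4), p3]))
        n2 = self.csp_p4(nn.concat([self.down3(n1), l4]))
        n3 = self.csp_p5(nn.concat([self.down4(n2), l5]))
        return n1, n2, n3

    def bns(self, prefix):
        for name in ("lat5", "csp_f4", "lat4", "csp_f3", "down3", "csp_p4",
                     "down4", "csp_p5"):
            yield from getattr(self, name).bns(f"{prefix}.{name}")

    def mask_groups(self, prefix):
        for name in ("csp_f4", "csp_f3", "csp_p4", "csp_p5"):
            yield from getattr(self, name).mask_groups(f"{prefix}.{name}")

    def prune(self, s3, s4, s5, masks, name):
        l5 = self.lat5.prune(s5, masks, f"{name}.lat5")
        f4 = self.csp_f4.prune(_cat(l5, s4), masks, f"{name}.csp_f4")
        l4 = self.lat4.prune(f4, masks, f"{name}.lat4")
        n1 = self.csp_f3.prune(_cat(l4, s3), masks, f"{name}.csp_f3")
        d3 = self.down3.prune(n1, masks, f"{name}.down3")
        n2 = self.csp_p4.prune(_cat(d3, l4), masks, f"{name}.csp_p4")
        d4 = self.down4.prune(n2, masks, f"{name}.down4")
        n3 = self.csp_p5.prune(_cat(d4, l5), masks, f"{name}.csp_p5")
        return n1, n2, n3


def _cat(a: PruneState, b: PruneState) -> PruneState:
    return PruneState(np.concatenate([a.mask, b.mask]),
                      np.concatenate([a.const, b.const]))


class Detector(nn.Module):
    """Shared forward/tap/prune plumbing for both roles."""

    spec: NetworkSpec

    def forward(self, x, taps: bool = False):
        raise NotImplementedError

    def forward_with_taps(self, x):
        """Head outputs plus the named intermediate feature maps."""
        if isinstance(x, np.ndarray):
            x = Tensor(x)
        if x.shape[-1] != self.spec.input_side or x.shape[-2] != self.spec.input_side:
            raise ValueError(
                f"input side {x.shape[-2:]} != spec {self.spec.input_side}")
        return self.forward(x, taps=True)

    def head_channels(self):
        return [c.cin for c in self.head.convs]

    # -- slimming interface ---------------------------------------------------
    def bn_units(self):
        """(name, ConvBNAct) for every BN-owning unit in the network."""
        return list(self._bns())

    def mask_groups(self):
        return list(self._groups())


class TeacherNet(Detector):
    def __init__(self, spec: NetworkSpec, rng: np.random.Generator | None = None):
        super().__init__()
        spec.validate()
        if spec.backbone != "cspdarknet":
            raise ConfigurationError("teacher requires the cspdarknet backbone")
        self.spec = spec
        rng = rng or np.random.default_rng(spec.seed)
        w, d = spec.width_multiple, spec.depth_multiple
        c1, c2, c3, c4, c5 = (_width(b, w) for b in (64, 128, 256, 512, 1024))
        act = "leaky"
        n = _depth(3, d)
        self.focus = Focus(3, c1, act=act, rng=rng)
        self.conv1 = ConvBNAct(c1, c2, 3, 2, act=act, rng=rng)
        self.csp1 = CSP(c2, c2, n, True, act=act, rng=rng)
        self.conv2 = ConvBNAct(c2, c3, 3, 2, act=act, rng=rng)
        self.csp2 = CSP(c3, c3, n, True, act=act, rng=rng)
        self.conv3 = ConvBNAct(c3, c4, 3, 2, act=act, rng=rng)
        self.csp3 = CSP(c4, c4, n, True, act=act, rng=rng)
        self.conv4 = ConvBNAct(c4, c5, 3, 2, act=act, rng=rng)
        self.spp = SPP(c5, c5, act=act, rng=rng)
        self.csp4 = CSP(c5, c5, n, False, act=act, rng=rng)
        self.neck = Neck(c3, c4, c5, n, act, rng)
        self.head = DetectHead([c3, c4, c5], len(spec.anchors[0]),
                               spec.num_classes, rng=rng)

    def forward(self, x, taps: bool = False):
        if isinstance(x, np.ndarray):
            x = Tensor(x)
        p1 = self.focus(x)
        p2 = self.csp1(self.conv1(p1))
        p3 = self.csp2(self.conv2(p2))
        p4 = self.csp3(self.conv3(p3))
        p5 = self.csp4(self.spp(self.conv4(p4)))
        n1, n2, n3 = self.neck(p3, p4, p5)
        outs = self.head([n1, n2, n3])
        if not taps:
            return outs
        tap = {"backbone.p1": p1, "backbone.p2": p2, "backbone.p3": p3,
               "backbone.p4": p4, "backbone.p5": p5,
               "neck.n1": n1, "neck.n2": n2, "neck.n3": n3,
               "head.out1": outs[0], "head.out2": outs[1], "head.out3": outs[2]}
        return outs, tap

    def _bns(self):
        yield from self.focus.bns("focus")
        for name in ("conv1", "csp1", "conv2", "csp2", "conv3", "csp3",
                     "conv4", "spp", "csp4"):
            yield from getattr(self, name).bns(name)
        yield from self.neck.bns("neck")

    def _groups(self):
        for name in ("csp1", "csp2", "csp3", "csp4"):
            yield from getattr(self, name).mask_groups(name)
        yield from self.neck.mask_groups("neck")

    def prune(self, masks: dict):
        s = PruneState.full(3)
        s = self.focus.prune(s, masks, "focus")
        s = self.csp1.prune(self.conv1.prune(s, masks, "conv1"), masks, "csp1")
        s3 = self.csp2.prune(self.conv2.prune(s, masks, "conv2"), masks, "csp2")
        s4 = self.csp3.prune(self.conv3.prune(s3, masks, "conv3"), masks, "csp3")
        s5 = self.csp4.prune(
            self.spp.prune(self.conv4.prune(s4, masks, "conv4"), masks, "spp"),
            masks, "csp4")
        n1, n2, n3 = self.neck.prune(s3, s4, s5, masks, "neck")
        self.head.prune([n1, n2, n3])
        return self


class StudentNet(Detector):
    """mobilenetv2-backbone student feeding the teacher's neck geometry."""

    def __init__(self, spec: NetworkSpec, rng: np.random.Generator | None = None):
        super().__init__()
        spec.validate()
        if spec.backbone != "mobilenetv2":
            raise ConfigurationError("student requires the mobilenetv2 backbone")
        self.spec = spec
        rng = rng or np.random.default_rng(spec.seed)
        w, d = spec.width_multiple, spec.depth_multiple
        cs = _width(32, w)                       # stem
        ca = _width(16, w)
        cb, cc, cd, ce = (_width(b, w) for b in (24, 32, 64, 96))
        n = _depth(2, d * 3)                     # blocks per downsampling stage
        self.stem = ConvBNAct(3, cs, 3, 2, act="relu6", kind="protected", rng=rng)
        self.stage1 = [InvertedResidual(cs, ca, expand=1, stride=1, rng=rng)]
        self.stage2 = ([InvertedResidual(ca, cb, 6, 2, rng=rng)] +
                       [InvertedResidual(cb, cb, 6, 1, rng=rng)
                        for _ in range(n - 1)])
        self.stage3 = ([InvertedResidual(cb, cc, 6, 2, rng=rng)] +
                       [InvertedResidual(cc, cc, 6, 1, rng=rng)
                        for _ in range(n - 1)])
        self.stage4 = ([InvertedResidual(cc, cd, 6, 2, rng=rng)] +
                       [InvertedResidual(cd, cd, 6, 1, rng=rng)
                        for _ in range(n - 1)])
        self.stage5 = ([InvertedResidual(cd, ce, 6, 2, rng=rng)] +
                       [InvertedResidual(ce, ce, 6, 1, rng=rng)
                        for _ in range(n - 1)])
        self.dropout = nn.Dropout(spec.dropout, seed=spec.seed)
        c3, c4, c5 = cc, cd, ce
        self.neck = Neck(c3, c4, c5, _depth(3, d), "relu6", rng)
        self.head = DetectHead([c3, c4, c5], len(spec.anchors[0]),
                               spec.num_classes, rng=rng)

    def forward(self, x, taps: bool = False):
        if isinstance(x, np.ndarray):
            x = Tensor(x)
        p1 = self.stem(x)
        y = p1
        for b in self.stage1:
            y = b(y)
        for b in self.stage2:
            y = b(y)
        p2 = y
        for b in self.stage3:
            y = b(y)
        p3 = y
        for b in self.stage4:
            y = b(y)
        p4 = y
        for b in self.stage5:
            y = b(y)
        p5 = self.dropout(y)
        n1, n2, n3 = self.neck(p3, p4, p5)
        outs = self.head([n1, n2, n3])
        if not taps:
            return outs
        tap = {"backbone.p1": p1, "backbone.p2": p2, "backbone.p3": p3,
               "backbone.p4": p4, "backbone.p5": p5,
               "neck.n1": n1, "neck.n2": n2, "neck.n3": n3,
               "head.out1": outs[0], "head.out2": outs[1], "head.out3": outs[2]}
        return outs, tap

    def _stages(self):
        for sname in ("stage1", "stage2", "stage3", "stage4", "stage5"):
            yield sname, getattr(self, sname)

    def _bns(self):
        yield from self.stem.bns("stem")
        for sname, stage in self._stages():
            for i, b in enumerate(stage):
                yield from b.bns(f"{sname}.{i}")
        yield from self.neck.bns("neck")

    def _groups(self):
        # chains of stride-1 inverted residuals share the producer's mask
        for sname, stage in self._stages():
            group = []
            for i, b in enumerate(stage):
                if b.use_res:
                    if not group:
                        prod = self._producer_bn(sname, i)
                        group = [prod] if prod else []
                    group.append(f"{sname}.{i}.project")
            if len(group) > 1:
                yield group
        yield from self.neck.mask_groups("neck")

    def _producer_bn(self, sname, i):
        if i > 0:
            return f"{sname}.{i - 1}.project"
        order = ["stage1", "stage2", "stage3", "stage4", "stage5"]
        k = order.index(sname)
        if k == 0:
            return "stem"
        prev = getattr(self, order[k - 1])
        return f"{order[k - 1]}.{len(prev) - 1}.project"

    def prune(self, masks: dict):
        s = self.stem.prune(PruneState.full(3), masks, "stem")
        states = {}
        for sname, stage in self._stages():
            for i, b in enumerate(stage):
                s = b.prune(s, masks, f"{sname}.{i}")
            states[sname] = s
        n1, n2, n3 = self.neck.prune(states["stage3"], states["stage4"],
                                     states["stage5"], masks, "neck")
        self.head.prune([n1, n2, n3])
        return self


def build_teacher(spec: NetworkSpec) -> TeacherNet:
    return TeacherNet(spec)


def build_student(spec: NetworkSpec) -> StudentNet:
    return StudentNet(spec)


def build_network(spec: NetworkSpec) -> Detector:
    return build_teacher(spec) if spec.role == "teacher" else build_student(spec)


def forward_with_taps(net: Detector, img) -> tuple[list, dict]:
    return net.forward_with_taps(img)
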