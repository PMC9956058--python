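"""Building blocks shared by the teacher and student detectors.

Every block that owns batch-norm layers also knows how to *prune* itself:
``prune(in_state, masks)`` slices its convolution weights on input channels
(per the upstream keep-mask) and output channels (per its own mask from the
global threshold), and propagates a :class:`PruneState` downstream.  The state
carries, for each removed channel, the constant activation that channel would
have produced had its BN scale been exactly zero (``act(beta)``); consumers
fold that constant into their effective bias so inference is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .. import nn
from ..nn import Tensor


@dataclass
class PruneState:
    """Keep-mask over a feature map's channels plus, aligned to the *original*
    channel indexing, the constant value carried by each removed channel."""

    mask: np.ndarray          # bool, original channel count
    const: np.ndarray         # float, original channel count; 0 where kept

    @classmethod
    def full(cls, channels: int):
        return cls(np.ones(channels, dtype=bool), np.zeros(channels))

    @property
    def kept(self) -> int:
        return int(self.mask.sum())


def _act(x: Tensor, kind: str) -> Tensor:
    if kind == "leaky":
        return x.leaky_relu(0.1)
    if kind == "relu6":
        return x.relu6()
    if kind == "linear":
        return x
    raise ValueError(f"unknown activation {kind!r}")


def _act_np(x: np.ndarray, kind: str) -> np.ndarray:
    if kind == "leaky":
        return np.where(x > 0, x, 0.1 * x)
    if kind == "relu6":
        return np.clip(x, 0.0, 6.0)
    return x


class ConvBNAct(nn.Module):
    """Conv (no bias) + BN + activation — the prunable unit.

    ``kind`` tags how the slimmer treats the BN: ``prunable`` participates in
    the global threshold, ``protected`` always keeps every channel (stem), and
    depthwise convs are ``follower``s whose mask mirrors their input.
    """

    def __init__(self, cin, cout, k=1, s=1, groups=1, act="leaky",
                 kind="prunable", rng=None):
        super().__init__()
        self.conv = nn.Conv2d(cin, cout, k, s, groups=groups, bias=False, rng=rng)
        self.bn = nn.BatchNorm2d(cout)
        self.act = act
        self.kind = "follower" if groups > 1 else kind
        self.depthwise = groups > 1

    def forward(self, x):
        return _act(self.bn(self.conv(x)), self.act)

    # -- pruning ----------------------------------------------------------------
    def bns(self, prefix):
        yield prefix, self

    def prune(self, in_state: PruneState, masks: dict, name: str) -> PruneState:
        keep = masks.get(name, np.ones(self.bn.channels, dtype=bool)).copy()
        w = self.conv.weight.data
        in_keep = in_state.mask
        if self.depthwise:
            keep = in_keep.copy()
            new_w = w[keep]
            # exact constant flow: removed channel sees only its own (constant)
            # input, so conv -> BN -> act of that constant is itself constant
            conv_const = in_state.const * w.sum(axis=(1, 2, 3))
            self.conv.groups = int(keep.sum())
        else:
            # fold removed-input constants into the BN running mean
            removed = ~in_keep
            fold = (w[:, removed].sum(axis=(2, 3)) @ in_state.const[removed]) \
                if removed.any() else np.zeros(w.shape[0])
            self.bn.running_mean = self.bn.running_mean - fold.astype(
                self.bn.running_mean.dtype)
            new_w = w[keep][:, in_keep]
            conv_const = None
        self.conv.weight.data = np.ascontiguousarray(new_w)
        self.conv.cin = int(in_keep.sum()) if not self.depthwise else int(keep.sum())
        self.conv.cout = int(keep.sum())

        gamma = self.bn.weight.data
        beta = self.bn.bias.data
        sd = np.sqrt(self.bn.running_var + self.bn.eps)
        if self.depthwise and conv_const is not None:
            bn_out = gamma * (conv_const - self.bn.running_mean) / sd + beta
        else:
            # removed channel approximated by its gamma->0 limit: output = beta
            bn_out = beta.astype(np.float64).copy()
        const = np.where(keep, 0.0, _act_np(bn_out, self.act))

        for attr in ("weight", "bias"):
            p = getattr(self.bn, attr)
            p.data = np.ascontiguousarray(p.data[keep])
        self.bn.running_mean = np.ascontiguousarray(self.bn.running_mean[keep])
        self.bn.running_var = np.ascontiguousarray(self.bn.running_var[keep])
        self.bn.channels = int(keep.sum())
        return PruneState(keep, const)


class Bottleneck(nn.Module):
    """1x1 reduce + 3x3 conv, optional residual add."""

    def __init__(self, cin, cout, shortcut=True, act="leaky", rng=None):
        super().__init__()
        self.cv1 = ConvBNAct(cin, cout, 1, act=act, rng=rng)
        self.cv2 = ConvBNAct(cout, cout, 3, act=act, rng=rng)
        self.shortcut = shortcut and cin == cout

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.shortcut else y

    def bns(self, prefix):
        yield from self.cv1.bns(f"{prefix}.cv1")
        yield from self.cv2.bns(f"{prefix}.cv2")

    def prune(self, in_state, masks, name):
        s = self.cv1.prune(in_state, masks, f"{name}.cv1")
        s = self.cv2.prune(s, masks, f"{name}.cv2")
        if self.shortcut:
            if not np.array_equal(s.mask, in_state.mask):
                raise ValueError(f"residual masks not aligned at {name}")
            s = PruneState(s.mask, s.const + in_state.const)
        return s


class CSP(nn.Module):
    """Cross-stage-partial block: split, bottleneck chain, bypass, merge."""

    def __init__(self, cin, cout, n=1, shortcut=True, act="leaky", rng=None):
        super().__init__()
        c_ = cout // 2
        self.cv1 = ConvBNAct(cin, c_, 1, act=act, rng=rng)
        self.cv2 = ConvBNAct(cin, c_, 1, act=act, rng=rng)
        self.blocks = [Bottleneck(c_, c_, shortcut, act=act, rng=rng)
                       for _ in range(n)]
        self.cv3 = ConvBNAct(2 * c_, cout, 1, act=act, rng=rng)
        self.shortcut = shortcut

    def forward(self, x):
        y1 = self.cv1(x)
        for b in self.blocks:
            y1 = b(y1)
        y2 = self.cv2(x)
        return self.cv3(nn.concat([y1, y2], axis=1))

    def bns(self, prefix):
        yield from self.cv1.bns(f"{prefix}.cv1")
        yield from self.cv2.bns(f"{prefix}.cv2")
        for i, b in enumerate(self.blocks):
            yield from b.bns(f"{prefix}.blocks.{i}")
        yield from self.cv3.bns(f"{prefix}.cv3")

    def mask_groups(self, prefix):
        """BNs tied by the residual adds inside the bottleneck chain."""
        if self.shortcut and self.blocks:
            yield [f"{prefix}.cv1"] + [f"{prefix}.blocks.{i}.cv2"
                                       for i in range(len(self.blocks))]

    def prune(self, in_state, masks, name):
        s1 = self.cv1.prune(in_state, masks, f"{name}.cv1")
        for i, b in enumerate(self.blocks):
            s1 = b.prune(s1, masks, f"{name}.blocks.{i}")
        s2 = self.cv2.prune(in_state, masks, f"{name}.cv2")
        cat = PruneState(np.concatenate([s1.mask, s2.mask]),
                         np.concatenate([s1.const, s2.const]))
        return self.cv3.prune(cat, masks, f"{name}.cv3")


class SPP(nn.Module):
    """Spatial pyramid pooling: parallel max-pools, concatenated."""

    def __init__(self, cin, cout, kernels=(5, 9, 13), act="leaky", rng=None):
        super().__init__()
        c_ = cin // 2
        self.cv1 = ConvBNAct(cin, c_, 1, act=act, rng=rng)
        self.cv2 = ConvBNAct(c_ * (len(kernels) + 1), cout, 1, act=act, rng=rng)
        self.kernels = kernels

    def forward(self, x):
        y = self.cv1(x)
        pools = [y] + [nn.max_pool2d(y, k, 1, k // 2) for k in self.kernels]
        return self.cv2(nn.concat(pools, axis=1))

    def bns(self, prefix):
        yield from self.cv1.bns(f"{prefix}.cv1")
        yield from self.cv2.bns(f"{prefix}.cv2")

    def prune(self, in_state, masks, name):
        s = self.cv1.prune(in_state, masks, f"{name}.cv1")
        # max-pool of a constant channel is the same constant
        reps = len(self.kernels) + 1
        cat = PruneState(np.tile(s.mask, reps), np.tile(s.const, reps))
        return self.cv2.prune(cat, masks, f"{name}.cv2")


class Focus(nn.Module):
    """Stride-2 space-to-depth shuffle followed by a 3x3 conv (the stem)."""

    def __init__(self, cin, cout, act="leaky", rng=None):
        super().__init__()
        self.cv = ConvBNAct(4 * cin, cout, 3, act=act, kind="protected", rng=rng)

    def forward(self, x):
        return self.cv(nn.space_to_depth2(x))

    def bns(self, prefix):
        yield from self.cv.bns(f"{prefix}.cv")

    def prune(self, in_state, masks, name):
        s = PruneState(np.tile(in_state.mask, 4), np.tile(in_state.const, 4))
        return self.cv.prune(s, masks, f"{name}.cv")


class InvertedResidual(nn.Module):
    """mobilenetv2 unit: 1x1 expand -> 3x3 depthwise -> 1x1 linear project,
    relu6 activations, residual add when stride 1 and matching channels."""

    def __init__(self, cin, cout, expand=6, stride=1, rng=None):
        super().__init__()
        hidden = cin * expand
        self.expand = ConvBNAct(cin, hidden, 1, act="relu6", rng=rng) \
            if expand != 1 else None
        self.dw = ConvBNAct(hidden, hidden, 3, stride, groups=hidden,
                            act="relu6", rng=rng)
        self.project = ConvBNAct(hidden, cout, 1, act="linear", rng=rng)
        self.use_res = stride == 1 and cin == cout

    def forward(self, x):
        y = x
        if self.expand is not None:
            y = self.expand(y)
        y = self.project(self.dw(y))
        return x + y if self.use_res else y

    def bns(self, prefix):
        if self.expand is not None:
            yield from self.expand.bns(f"{prefix}.expand")
        yield from self.dw.bns(f"{prefix}.dw")
        yield from self.project.bns(f"{prefix}.project")

    def prune(self, in_state, masks, name):
        s = in_state
        if self.expand is not None:
            s = self.expand.prune(s, masks, f"{name}.expand")
        s = self.dw.prune(s, masks, f"{name}.dw")
        s = self.project.prune(s, masks, f"{name}.project")
        if self.use_res:
            if not np.array_equal(s.mask, in_state.mask):
                raise ValueError(f"residual masks not aligned at {name}")
            s = PruneState(s.mask, s.const + in_state.const)
        return s


class DetectHead(nn.Module):
    """Per-level 1x1 prediction convolutions (never pruned on output)."""

    def __init__(self, channels: list[int], num_anchors: int, num_classes: int,
                 rng=None):
        super().__init__()
        self.na = num_anchors
        self.nc = num_classes
        self.convs = [nn.Conv2d(c, num_anchors * (5 + num_classes), 1,
                                bias=True, rng=rng) for c in channels]

    def forward(self, feats):
        return [conv(f) for conv, f in zip(self.convs, feats)]

    def prune(self, in_states: list[PruneState]):
        for conv, st in zip(self.convs, in_states):
            w = conv.weight.data
            removed = ~st.mask
            if removed.any():
                conv.bias.data = conv.bias.data + (
                    w[:, removed].sum(axis=(2, 3)) @ st.const[removed]
                ).astype(conv.bias.data.dtype)
            conv.weight.data = np.ascontiguousarray(w[:, st.mask])
            conv.cin = int(st.mask.sum())
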