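"""Network slimming: BN-scale sparsity, global-threshold masks, reconstruction.

Channel pruning follows the batch-norm scaling-factor recipe: during training
an L1 penalty pushes per-channel BN scales |gamma| toward zero; afterwards a
single *global* quantile of the pooled |gamma| values (default: the 80 %
quantile, i.e. removal of 80 % of prunable channels) sets the threshold, and
every channel whose |gamma| falls below it is cut out of the network.  Layers
whose outputs meet at a tensor addition are kept channel-aligned by taking the
union of their keep-masks; every layer keeps at least one channel; prediction
heads and the stem are never pruned.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .detnet.model import Detector, build_network
from .nn import Tensor


@dataclass
class BNState:
    """Per-channel batch-norm statistics and affine parameters."""

    gamma: np.ndarray
    beta: np.ndarray
    mu: np.ndarray
    var: np.ndarray
    eps: float = 1e-5

    def validate(self):
        if self.eps <= 0:
            raise ValueError("eps must be > 0")
        if np.any(self.var < 0):
            raise ValueError("variance must be >= 0")
        n = np.size(self.gamma)
        if not (np.size(self.beta) == np.size(self.mu) == np.size(self.var) == n):
            raise ValueError("BN parameter vectors must share channel count")
        return self


def bn_forward(x: np.ndarray, s: BNState) -> np.ndarray:
    """z = (x - mu) / sqrt(var + eps); out = gamma * z + beta.

    ``x`` may be scalar-per-channel, (C,), or NCHW; parameters broadcast over
    the channel axis.
    """
    s.validate()
    x = np.asarray(x, dtype=np.float64)
    g, b = np.asarray(s.gamma, dtype=np.float64), np.asarray(s.beta, dtype=np.float64)
    mu, var = np.asarray(s.mu, dtype=np.float64), np.asarray(s.var, dtype=np.float64)
    if x.ndim == 4:
        shape = (1, -1, 1, 1)
        g, b, mu, var = (a.reshape(shape) for a in (g, b, mu, var))
    elif x.ndim not in (0, 1):
        raise ValueError(f"unsupported input rank {x.ndim}")
    z = (x - mu) / np.sqrt(var + s.eps)
    return g * z + b


@dataclass
class PruneMask:
    """Boolean keep-vectors per prunable BN unit plus the provenance."""

    keeps: dict[str, np.ndarray] = field(default_factory=dict)
    global_threshold: float = 0.0
    target_fraction: float = 0.0

    def removed_fraction(self) -> float:
        tot = sum(k.size for k in self.keeps.values())
        rem = sum(int((~k).sum()) for k in self.keeps.values())
        return rem / tot if tot else 0.0


def prunable_units(net: Detector):
    return [(name, unit) for name, unit in net.bn_units()
            if unit.kind == "prunable"]


def collect_gammas(net: Detector) -> np.ndarray:
    """Pooled BN scale vector over all prunable layers."""
    gs = [u.bn.weight.data for _, u in prunable_units(net)]
    if not gs:
        raise ValueError("network has no prunable BN layers")
    return np.concatenate(gs)


def sparsity_penalty(all_gammas, lam: float) -> Tensor:
    """lam * sum |gamma| over the given BN scale tensors (L1, subgradient 0 at 0)."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    total = Tensor(0.0)
    for g in all_gammas:
        t = g if isinstance(g, Tensor) else Tensor(g)
        total = total + t.abs().sum()
    return total * lam


def apply_sparsity_grad(net: Detector, lam: float):
    """Add the L1 subgradient lam*sign(gamma) onto prunable BN scale grads
    (the cheap in-place form used during sparsity training)."""
    for _, u in prunable_units(net):
        g = u.bn.weight
        sub = lam * np.sign(g.data)
        g.grad = sub if g.grad is None else g.grad + sub


def global_threshold(all_gammas: np.ndarray, fraction: float = 0.8) -> float:
    """The ``fraction``-quantile of pooled |gamma|; channels with |gamma|
    strictly below it are marked for removal."""
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must be in [0, 1)")
    pool = np.abs(np.asarray(all_gammas, dtype=np.float64).ravel())
    if pool.size == 0:
        raise ValueError("empty gamma pool")
    return float(np.quantile(pool, fraction))


def align_union(keeps: dict[str, np.ndarray],
                groups: list[list[str]]) -> dict[str, np.ndarray]:
    """Force add-junction partners onto the union of their keep-masks.

    Transitive: overlapping groups are merged before the union is taken.
    Names absent from ``keeps`` (protected layers) are treated as all-kept and
    pull their whole group to all-True.
    """
    merged: list[set] = []
    for g in groups:
        g = set(g)
        hit = [m for m in merged if m & g]
        for m in hit:
            merged.remove(m)
            g |= m
        merged.append(g)
    out = dict(keeps)
    for g in merged:
        members = [n for n in g if n in out]
        if not members:
            continue
        union = np.zeros_like(out[members[0]])
        full = len(members) < len(g)    # a protected partner keeps everything
        for n in members:
            union |= out[n]
        if full:
            union[:] = True
        for n in members:
            out[n] = union.copy()
    return out


def build_masks(net: Detector, threshold: float,
                target_fraction: float = 0.8) -> PruneMask:
    """Keep-vectors per prunable layer: |gamma| >= threshold, with a one-channel
    floor per layer and union alignment across residual-add partners."""
    keeps = {}
    for name, unit in prunable_units(net):
        g = np.abs(unit.bn.weight.data.astype(np.float64))
        keep = g >= threshold
        if not keep.any():
            keep[int(g.argmax())] = True    # floor rule: never empty a layer
        keeps[name] = keep
    keeps = align_union(keeps, net.mask_groups())
    return PruneMask(keeps, float(threshold), float(target_fraction))


def clone_network(net: Detector) -> Detector:
    spec = copy.deepcopy(net.spec)
    fresh = build_network(spec)
    fresh.load_state_dict(net.state_dict())
    fresh.train(net.training)
    return fresh


def reconstruct(net: Detector, mask: PruneMask) -> Detector:
    """Physically remove masked channels and return the rebuilt network.

    Convolutions are sliced on output channels per their own mask and input
    channels per the upstream mask; each removed channel's post-activation
    beta constant is folded into its consumers so eval-mode inference is
    preserved (exactly so when the removed gamma and beta are zero).
    """
    units = dict(net.bn_units())
    for name, keep in mask.keeps.items():
        if name not in units:
            raise ValueError(f"mask refers to unknown layer {name!r}")
        if keep.size != units[name].bn.channels:
            raise ValueError(f"mask length mismatch at {name!r}: "
                             f"{keep.size} vs {units[name].bn.channels}")
    pruned = clone_network(net)
    pruned.prune(mask.keeps)
    return pruned


def prune_report(net: Detector, pruned: Detector, mask: PruneMask) -> list[dict]:
    before = dict(net.bn_units())
    after = dict(pruned.bn_units())
    rows = []
    for name, unit in before.items():
        g = np.abs(unit.bn.weight.data)
        rows.append({
            "layer": name,
            "kind": unit.kind,
            "channels_before": int(unit.bn.channels),
            "channels_after": int(after[name].bn.channels),
            "gamma_min": float(g.min()),
            "gamma_max": float(g.max()),
        })
    return rows


def write_report_tsv(rows: list[dict], path):
    import csv
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=list(rows[0].keys()), delimiter="\t")
        w.writeheader()
        w.writerows(rows)


def prune_network(net: Detector, fraction: float = 0.8):
    """Threshold + mask + reconstruct in one step; returns (pruned, mask, report)."""
    thr = global_threshold(collect_gammas(net), fraction)
    mask = build_masks(net, thr, fraction)
    pruned = reconstruct(net, mask)
    return pruned, mask, prune_report(net, pruned, mask)
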