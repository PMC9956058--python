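"""Reverse-mode automatic differentiation on NumPy arrays.

A deliberately small engine: a :class:`Tensor` wraps an ``ndarray`` and records
the operations applied to it; :meth:`Tensor.backward` walks the tape in reverse
topological order.  Only the operations the detector stack needs are provided
(elementwise arithmetic with broadcasting, matmul, reductions, reshaping,
slicing, 2-D convolution with groups, pooling, nearest upsampling and the
space-to-depth shuffle).  Everything is single-threaded NumPy, so identical
seeds give bit-identical runs.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph recording (inference / target construction)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _as_array(data, dtype=None):
    arr = np.asarray(data)
    if dtype is not None:
        return arr.astype(dtype, copy=False)
    if arr.dtype.kind in "iub":
        return arr.astype(np.float32)
    return arr


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, dtype=None):
        self.data = _as_array(data, dtype)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _from_op(cls, data, parents, backward):
        out = cls(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- basic protocol -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def __len__(self):
        return len(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    # -- autodiff core --------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
        return self

    def _accum(self, grad):
        if not self.requires_grad:
            return
        grad = _unbroadcast(np.asarray(grad), self.data.shape)
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    def zero_grad(self):
        self.grad = None

    # -- elementwise arithmetic ----------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)

        def bw(g):
            self._accum(g)
            other._accum(g)

        return Tensor._from_op(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)

        def bw(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        return Tensor._from_op(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __sub__(self, other):
        other = self._wrap(other)

        def bw(g):
            self._accum(g)
            other._accum(-g)

        return Tensor._from_op(self.data - other.data, (self, other), bw)

    def __rsub__(self, other):
        return self._wrap(other).__sub__(self)

    def __neg__(self):
        def bw(g):
            self._accum(-g)

        return Tensor._from_op(-self.data, (self,), bw)

    def __truediv__(self, other):
        other = self._wrap(other)

        def bw(g):
            self._accum(g / other.data)
            other._accum(-g * self.data / (other.data * other.data))

        return Tensor._from_op(self.data / other.data, (self, other), bw)

    def __rtruediv__(self, other):
        return self._wrap(other).__truediv__(self)

    def __pow__(self, p: float):
        assert np.isscalar(p)

        def bw(g):
            self._accum(g * p * np.power(self.data, p - 1))

        return Tensor._from_op(np.power(self.data, p), (self,), bw)

    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self._accum(g * out_data)

        return Tensor._from_op(out_data, (self,), bw)

    def log(self):
        def bw(g):
            self._accum(g / self.data)

        return Tensor._from_op(np.log(self.data), (self,), bw)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bw(g):
            self._accum(g * 0.5 / out_data)

        return Tensor._from_op(out_data, (self,), bw)

    def abs(self):
        def bw(g):
            self._accum(g * np.sign(self.data))

        return Tensor._from_op(np.abs(self.data), (self,), bw)

    def atan(self):
        def bw(g):
            self._accum(g / (1.0 + self.data * self.data))

        return Tensor._from_op(np.arctan(self.data), (self,), bw)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            self._accum(g * s * (1.0 - s))

        return Tensor._from_op(s, (self,), bw)

    def relu(self):
        mask = self.data > 0

        def bw(g):
            self._accum(g * mask)

        return Tensor._from_op(self.data * mask, (self,), bw)

    def relu6(self):
        mask = (self.data > 0) & (self.data < 6.0)

        def bw(g):
            self._accum(g * mask)

        return Tensor._from_op(np.clip(self.data, 0.0, 6.0), (self,), bw)

    def leaky_relu(self, slope: float = 0.1):
        pos = self.data > 0
        scale = np.where(pos, 1.0, slope)

        def bw(g):
            self._accum(g * scale)

        return Tensor._from_op(self.data * scale, (self,), bw)

    def maximum(self, other):
        other = self._wrap(other)
        take_self = self.data >= other.data

        def bw(g):
            self._accum(g * take_self)
            other._accum(g * ~take_self)

        return Tensor._from_op(np.maximum(self.data, other.data), (self, other), bw)

    def minimum(self, other):
        other = self._wrap(other)
        take_self = self.data <= other.data

        def bw(g):
            self._accum(g * take_self)
            other._accum(g * ~take_self)

        return Tensor._from_op(np.minimum(self.data, other.data), (self, other), bw)

    def clamp(self, lo=None, hi=None):
        out = self
        if lo is not None:
            out = out.maximum(lo)
        if hi is not None:
            out = out.minimum(hi)
        return out

    # -- linear algebra & reductions ------------------------------------------
    def matmul(self, other):
        other = self._wrap(other)

        def bw(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        return Tensor._from_op(self.data @ other.data, (self, other), bw)

    __matmul__ = matmul

    def sum(self, axis=None, keepdims=False):
        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(gg, self.data.shape))

        return Tensor._from_op(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims=False):
        count = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    # -- shape manipulation ----------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def bw(g):
            self._accum(g.reshape(old))

        return Tensor._from_op(self.data.reshape(shape), (self,), bw)

    def transpose(self, axes: Sequence[int]):
        inv = np.argsort(axes)

        def bw(g):
            self._accum(g.transpose(inv))

        return Tensor._from_op(self.data.transpose(axes), (self,), bw)

    def __getitem__(self, idx):
        def bw(g):
            if not self.requires_grad:
                return
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            if self.grad is None:
                self.grad = full
            else:
                self.grad += full

        return Tensor._from_op(self.data[idx], (self,), bw)


# ---------------------------------------------------------------------------
# free functions


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            t._accum(g[tuple(sl)])

    return Tensor._from_op(np.concatenate([t.data for t in tensors], axis=axis), tensors, bw)


def stack_scalars(tensors: Sequence[Tensor]) -> Tensor:
    """Stack 0-d tensors into a 1-d tensor (for softmax over branches)."""
    return concat([t.reshape(1) for t in tensors], axis=0)


def _im2col_view(xp: np.ndarray, kh, kw, sh, sw, ho, wo):
    n, c = xp.shape[:2]
    s = xp.strides
    return np.lib.stride_tricks.as_strided(
        xp,
        (n, c, kh, kw, ho, wo),
        (s[0], s[1], s[2], s[3], s[2] * sh, s[3] * sw),
        writeable=False,
    )


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1,
           padding: int = 0, groups: int = 1) -> Tensor:
    """2-D convolution (cross-correlation), NCHW, square stride/padding."""
    n, cin, h, wd = x.data.shape
    cout, cin_g, kh, kw = w.data.shape
    if cin_g * groups != cin:
        raise ValueError(f"channel mismatch: input {cin}, weight expects {cin_g * groups}")
    sh = sw = stride
    ph = pw = padding
    ho = (h + 2 * ph - kh) // sh + 1
    wo = (wd + 2 * pw - kw) // sw + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if padding else x.data
    view = _im2col_view(xp, kh, kw, sh, sw, ho, wo)
    # (n, g, cin_g*kh*kw, ho*wo)
    cols = np.ascontiguousarray(view).reshape(n, groups, cin_g * kh * kw, ho * wo)
    wr = w.data.reshape(groups, cout // groups, cin_g * kh * kw)
    out = np.matmul(wr[None], cols)
    out = out.reshape(n, cout, ho, wo)
    if b is not None:
        out = out + b.data.reshape(1, cout, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def bw(g):
        gr = g.reshape(n, groups, cout // groups, ho * wo)
        if w.requires_grad:
            gw = np.matmul(gr, cols.transpose(0, 1, 3, 2)).sum(axis=0)
            w._accum(gw.reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gcols = np.matmul(wr.transpose(0, 2, 1)[None], gr)
            gcols = gcols.reshape(n, cin, kh, kw, ho, wo)
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i:i + sh * ho:sh, j:j + sw * wo:sw] += gcols[:, :, i, j]
            if padding:
                gxp = gxp[:, :, ph:ph + h, pw:pw + wd]
            x._accum(gxp)

    return Tensor._from_op(out, parents, bw)


def max_pool2d(x: Tensor, kernel: int, stride: int | None = None, padding: int = 0) -> Tensor:
    stride = stride or kernel
    n, c, h, w = x.data.shape
    ho = (h + 2 * padding - kernel) // stride + 1
    wo = (w + 2 * padding - kernel) // stride + 1
    if padding:
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding,) * 2, (padding,) * 2),
                    constant_values=-np.inf)
    else:
        xp = x.data
    view = _im2col_view(xp, kernel, kernel, stride, stride, ho, wo)
    win = np.ascontiguousarray(view.transpose(0, 1, 4, 5, 2, 3)).reshape(
        n, c, ho, wo, kernel * kernel)
    idx = win.argmax(axis=-1)
    out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def bw(g):
        if not x.requires_grad:
            return
        gxp = np.zeros_like(xp)
        ni, ci, hi, wi = np.indices(idx.shape)
        hh = hi * stride + idx // kernel
        ww = wi * stride + idx % kernel
        np.add.at(gxp, (ni, ci, hh, ww), g)
        if padding:
            gxp = gxp[:, :, padding:padding + h, padding:padding + w]
        x._accum(gxp)

    return Tensor._from_op(out, (x,), bw)


def _adaptive_bins(insize: int, outsize: int):
    starts = (np.arange(outsize) * insize) // outsize
    ends = -((-(np.arange(outsize) + 1) * insize) // outsize)
    return starts, ends


def adaptive_avg_pool2d(x: Tensor, out_size) -> Tensor:
    """Average pool to an exact output raster (PyTorch-style binning)."""
    if np.isscalar(out_size):
        out_size = (int(out_size), int(out_size))
    n, c, h, w = x.data.shape
    oh, ow = out_size
    hs, he = _adaptive_bins(h, oh)
    ws, we = _adaptive_bins(w, ow)
    out = np.empty((n, c, oh, ow), dtype=x.data.dtype)
    for i in range(oh):
        for j in range(ow):
            out[:, :, i, j] = x.data[:, :, hs[i]:he[i], ws[j]:we[j]].mean(axis=(2, 3))

    def bw(g):
        if not x.requires_grad:
            return
        gx = np.zeros_like(x.data)
        for i in range(oh):
            for j in range(ow):
                cnt = (he[i] - hs[i]) * (we[j] - ws[j])
                gx[:, :, hs[i]:he[i], ws[j]:we[j]] += g[:, :, i, j, None, None] / cnt
        x._accum(gx)

    return Tensor._from_op(out, (x,), bw)


def upsample_nearest2x(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    out = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)

    def bw(g):
        x._accum(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    return Tensor._from_op(out, (x,), bw)


def space_to_depth2(x: Tensor) -> Tensor:
    """The stride-2 pixel shuffle used by the Focus stem: (N,C,H,W)->(N,4C,H/2,W/2)."""
    n, c, h, w = x.data.shape
    out = (x.data.reshape(n, c, h // 2, 2, w // 2, 2)
           .transpose(0, 3, 5, 1, 2, 4)
           .reshape(n, 4 * c, h // 2, w // 2))

    def bw(g):
        gx = (g.reshape(n, 2, 2, c, h // 2, w // 2)
              .transpose(0, 3, 4, 1, 5, 2)
              .reshape(n, c, h, w))
        x._accum(gx)

    return Tensor._from_op(np.ascontiguousarray(out), (x,), bw)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Numerically-stable elementwise binary cross-entropy on logits (mean)."""
    t = Tensor(targets)
    return (logits.clamp(lo=0.0) - logits * t
            + ((-logits.abs()).exp() + 1.0).log()).mean()
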