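"""Minimal reverse-mode automatic differentiation on numpy arrays.

This module provides the :class:`Tensor` container and the differentiable
primitives needed by the segmentation network: broadcasting arithmetic,
``exp``/``log``/``relu``/``sigmoid``, reductions, shape ops, batched matrix
multiplication, 3D convolution, 2x max-pooling and nearest-neighbour
upsampling.  Gradients are accumulated into ``Tensor.grad`` by
:meth:`Tensor.backward`, which walks the recorded graph in reverse
topological order.

All data is kept in float64: the networks used here are desk-scale, and the
extra precision keeps oracle comparisons and gradient checks tight.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv3d", "maxpool2x", "upsample2x"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An n-d array plus the bookkeeping for reverse-mode differentiation."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "name")

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple = ()
        self.name = name

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph plumbing -------------------------------------------------------

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None) -> None:
        """Accumulate d(self)/d(leaf) into every reachable leaf's ``.grad``."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t._backward is None:  # leaf
                t.grad = g if t.grad is None else t.grad + g
                continue
            for parent, pg in t._backward(g):
                if not parent.requires_grad:
                    continue
                key = id(parent)
                grads[key] = pg if key not in grads else grads[key] + pg
        # leaves visited with accumulated grads already stored above; roots
        # that are themselves leaves:
        if self._backward is None and self.requires_grad and self.grad is None:
            self.grad = np.asarray(grad, dtype=np.float64)

    def zero_grad(self):
        self.grad = None

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = Tensor._wrap(other)
        data = self.data + other.data

        def backward(g):
            return ((self, _unbroadcast(g, self.data.shape)),
                    (other, _unbroadcast(g, other.data.shape)))

        return self._make(data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = Tensor._wrap(other)
        data = self.data * other.data

        def backward(g):
            return ((self, _unbroadcast(g * other.data, self.data.shape)),
                    (other, _unbroadcast(g * self.data, other.data.shape)))

        return self._make(data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __truediv__(self, other):
        other = Tensor._wrap(other)
        data = self.data / other.data

        def backward(g):
            return ((self, _unbroadcast(g / other.data, self.data.shape)),
                    (other, _unbroadcast(-g * self.data / other.data**2,
                                         other.data.shape)))

        return self._make(data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor._wrap(other) / self

    def __pow__(self, p: float):
        data = self.data**p

        def backward(g):
            return ((self, g * p * self.data**(p - 1)),)

        return self._make(data, (self,), backward)

    # -- elementwise nonlinearities -------------------------------------------

    def exp(self):
        data = np.exp(self.data)

        def backward(g):
            return ((self, g * data),)

        return self._make(data, (self,), backward)

    def log(self):
        data = np.log(self.data)

        def backward(g):
            return ((self, g / self.data),)

        return self._make(data, (self,), backward)

    def sqrt(self):
        data = np.sqrt(self.data)

        def backward(g):
            return ((self, g * 0.5 / data),)

        return self._make(data, (self,), backward)

    def relu(self):
        mask = self.data > 0
        data = self.data * mask

        def backward(g):
            return ((self, g * mask),)

        return self._make(data, (self,), backward)

    def sigmoid(self):
        data = np.where(self.data >= 0,
                        1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500))),
                        np.exp(np.clip(self.data, -500, 500))
                        / (1.0 + np.exp(np.clip(self.data, -500, 500))))

        def backward(g):
            return ((self, g * data * (1.0 - data)),)

        return self._make(data, (self,), backward)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes only where unclipped."""
        data = np.clip(self.data, lo, hi)
        mask = (self.data > lo) & (self.data < hi)

        def backward(g):
            return ((self, g * mask),)

        return self._make(data, (self,), backward)

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                for ax in sorted(a % self.data.ndim for a in axes):
                    g = np.expand_dims(g, ax)
            return ((self, np.broadcast_to(g, self.data.shape).copy()),)

        return self._make(data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops ------------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        data = self.data.reshape(shape)
        src = self.data.shape

        def backward(g):
            return ((self, g.reshape(src)),)

        return self._make(data, (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        data = self.data.transpose(axes)
        inv = np.argsort(axes)

        def backward(g):
            return ((self, g.transpose(inv)),)

        return self._make(data, (self,), backward)

    # -- linear algebra -------------------------------------------------------

    def matmul(self, other):
        """Matrix product, supporting stacked (batched) operands."""
        other = Tensor._wrap(other)
        data = self.data @ other.data

        def backward(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            return ((self, _unbroadcast(ga, self.data.shape)),
                    (other, _unbroadcast(gb, other.data.shape)))

        return self._make(data, (self, other), backward)

    __matmul__ = matmul

    # -- activations built from primitives ------------------------------------

    def softmax(self, axis: int):
        """Numerically stable softmax along ``axis`` (max treated constant)."""
        shift = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shift.exp()
        return e / e.sum(axis=axis, keepdims=True)


# -- structural ops ------------------------------------------------------------


def concat(tensors, axis: int) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        out = []
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            out.append((t, g[tuple(sl)]))
        return tuple(out)

    out = Tensor(data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._prev = tuple(tensors)
        out._backward = backward
    return out


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """3D cross-correlation of ``x`` (N,Ci,D,H,W) with ``w`` (Co,Ci,kd,kh,kw).

    Implemented as im2col + matmul; the backward pass scatters column
    gradients with one vectorised add per kernel offset.
    """
    x = Tensor._wrap(x)
    w = Tensor._wrap(w)
    n, ci, d, h, wd = x.data.shape
    co, ci2, kd, kh, kw = w.data.shape
    if ci != ci2:
        raise ValueError(f"conv3d channel mismatch: input {ci}, weight {ci2}")
    s, p = stride, padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
    do = (d + 2 * p - kd) // s + 1
    ho = (h + 2 * p - kh) // s + 1
    wo = (wd + 2 * p - kw) // s + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kd, kh, kw),
                                                  axis=(2, 3, 4))
    win = win[:, :, ::s, ::s, ::s]            # (N,Ci,Do,Ho,Wo,kd,kh,kw)
    cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(
        n, do * ho * wo, ci * kd * kh * kw)
    wmat = w.data.reshape(co, ci * kd * kh * kw)
    out = cols @ wmat.T                        # (N,L,Co)
    out = out.transpose(0, 2, 1).reshape(n, co, do, ho, wo)
    if b is not None:
        out = out + b.data.reshape(1, co, 1, 1, 1)

    def backward(g):
        gl = g.reshape(n, co, do * ho * wo).transpose(0, 2, 1)  # (N,L,Co)
        gw = np.tensordot(gl, cols, axes=([0, 1], [0, 1])).reshape(w.data.shape)
        gcols = gl @ wmat                      # (N,L,K)
        gwin = gcols.reshape(n, do, ho, wo, ci, kd, kh, kw)
        gwin = gwin.transpose(0, 4, 1, 2, 3, 5, 6, 7)
        gxp = np.zeros_like(xp)
        for i in range(kd):
            for j in range(kh):
                for k in range(kw):
                    gxp[:, :, i:i + s * do:s, j:j + s * ho:s,
                        k:k + s * wo:s] += gwin[..., i, j, k]
        gx = gxp[:, :, p:p + d, p:p + h, p:p + wd] if p else gxp
        grads = [(x, gx), (w, gw)]
        if b is not None:
            grads.append((b, g.sum(axis=(0, 2, 3, 4))))
        return tuple(grads)

    parents = (x, w) if b is None else (x, w, b)
    res = Tensor(out)
    if any(t.requires_grad for t in parents):
        res.requires_grad = True
        res._prev = parents
        res._backward = backward
    return res


def maxpool2x(x: Tensor) -> Tensor:
    """2x2x2 max pooling with stride 2 (spatial dims must be even)."""
    x = Tensor._wrap(x)
    n, c, d, h, w = x.data.shape
    if d % 2 or h % 2 or w % 2:
        raise ValueError(f"maxpool2x needs even spatial dims, got {(d, h, w)}")
    win = x.data.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
    win = win.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(
        n, c, d // 2, h // 2, w // 2, 8)
    idx = win.argmax(axis=-1)
    out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gwin = np.zeros_like(win)
        np.put_along_axis(gwin, idx[..., None], g[..., None], axis=-1)
        gx = gwin.reshape(n, c, d // 2, h // 2, w // 2, 2, 2, 2)
        gx = gx.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(n, c, d, h, w)
        return ((x, gx),)

    res = Tensor(out)
    if x.requires_grad:
        res.requires_grad = True
        res._prev = (x,)
        res._backward = backward
    return res


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour upsampling by 2 in each spatial dimension."""
    x = Tensor._wrap(x)
    n, c, d, h, w = x.data.shape
    out = x.data.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)

    def backward(g):
        gx = g.reshape(n, c, d, 2, h, 2, w, 2).sum(axis=(3, 5, 7))
        return ((x, gx),)

    res = Tensor(out)
    if x.requires_grad:
        res.requires_grad = True
        res._prev = (x,)
        res._backward = backward
    return res
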