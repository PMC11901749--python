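"""Minimal reverse-mode automatic differentiation over numpy arrays.

Everything trainable in this package (convolutional backbone, sensor
transformer, attention stacks, fusion, losses) is built on this engine, so
analytic gradients can be verified against finite differences in one place.
All data is float64: the models are desk-scale and exactness matters more
than speed here.
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional, Sequence, Union

import numpy as np

ArrayLike = Union[np.ndarray, float, int, "Tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    # force numpy to defer to our reflected operators (ndarray op Tensor)
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False,
                 _prev: Sequence["Tensor"] = (),
                 _backward: Optional[Callable[[np.ndarray], None]] = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = bool(requires_grad)
        self._prev = tuple(_prev)
        self._backward = _backward

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def numpy(self) -> np.ndarray:
        return self.data

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        # topological order
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other: ArrayLike) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data + other.data, _prev=(self, other))
        def _bw(g):
            if self.requires_grad or self._prev:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad or other._prev:
                other._accumulate(_unbroadcast(g, other.data.shape))
        out._backward = _bw
        return out

    __radd__ = __add__

    def __mul__(self, other: ArrayLike) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data * other.data, _prev=(self, other))
        def _bw(g):
            if self.requires_grad or self._prev:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad or other._prev:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))
        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __neg__(self) -> "Tensor":
        return self * -1.0

    def __sub__(self, other: ArrayLike) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other: ArrayLike) -> "Tensor":
        return as_tensor(other) + (-self)

    def __truediv__(self, other: ArrayLike) -> "Tensor":
        return self * as_tensor(other) ** -1.0

    def __rtruediv__(self, other: ArrayLike) -> "Tensor":
        return as_tensor(other) * self ** -1.0

    def __pow__(self, p: float) -> "Tensor":
        p = float(p)
        out = Tensor(self.data ** p, _prev=(self,))
        def _bw(g):
            self._accumulate(g * p * self.data ** (p - 1.0))
        out._backward = _bw
        return out

    def __matmul__(self, other: "Tensor") -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))
        def _bw(g):
            if self.requires_grad or self._prev:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.data.shape))
            if other.requires_grad or other._prev:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.data.shape))
        out._backward = _bw
        return out

    # ---------------------------------------------------------- element-wise
    def exp(self) -> "Tensor":
        out = Tensor(np.exp(self.data), _prev=(self,))
        def _bw(g):
            self._accumulate(g * out.data)
        out._backward = _bw
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), _prev=(self,))
        def _bw(g):
            self._accumulate(g / self.data)
        out._backward = _bw
        return out

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), _prev=(self,))
        def _bw(g):
            self._accumulate(g * (self.data > 0))
        out._backward = _bw
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, _prev=(self,))
        def _bw(g):
            self._accumulate(g * s * (1.0 - s))
        out._backward = _bw
        return out

    def tanh(self) -> "Tensor":
        t = np.tanh(self.data)
        out = Tensor(t, _prev=(self,))
        def _bw(g):
            self._accumulate(g * (1.0 - t * t))
        out._backward = _bw
        return out

    def sqrt(self) -> "Tensor":
        return self ** 0.5

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))
        def _bw(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy()
                                 if np.ndim(g) else np.full_like(self.data, g))
            else:
                gg = g
                if not keepdims:
                    axes = axis if isinstance(axis, tuple) else (axis,)
                    axes = tuple(a % self.data.ndim for a in axes)
                    for a in sorted(axes):
                        gg = np.expand_dims(gg, a)
                self._accumulate(np.broadcast_to(gg, self.data.shape).copy())
        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ----------------------------------------------------------- shape moves
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _prev=(self,))
        def _bw(g):
            self._accumulate(g.reshape(self.data.shape))
        out._backward = _bw
        return out

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        if not axes:
            axes = tuple(reversed(range(self.data.ndim)))
        out = Tensor(self.data.transpose(axes), _prev=(self,))
        inv = np.argsort(axes)
        def _bw(g):
            self._accumulate(g.transpose(inv))
        out._backward = _bw
        return out

    def swapaxes(self, a: int, b: int) -> "Tensor":
        axes = list(range(self.data.ndim))
        axes[a], axes[b] = axes[b], axes[a]
        return self.transpose(*axes)

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], _prev=(self,))
        def _bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)
        out._backward = _bw
        return out


def as_tensor(x: ArrayLike) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ------------------------------------------------------------------ functions

def concatenate(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    def _bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(g[tuple(sl)])
    out._backward = _bw
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax (the shift is a constant w.r.t. grad)."""
    shift = np.max(x.data, axis=axis, keepdims=True)
    e = (x - Tensor(shift)).exp()
    return e / e.sum(axis=axis, keepdims=True)


def clip_min(x: Tensor, lo: float) -> Tensor:
    """max(x, lo); gradient passes only where x > lo."""
    out = Tensor(np.maximum(x.data, lo), _prev=(x,))
    def _bw(g):
        x._accumulate(g * (x.data > lo))
    out._backward = _bw
    return out


def conv2d(x: Tensor, w: Tensor, b: Optional[Tensor] = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation. x: (N,C,H,W), w: (Co,Ci,kh,kw), b: (Co,)."""
    x, w = as_tensor(x), as_tensor(w)
    n, c, h, wd = x.data.shape
    co, ci, kh, kw = w.data.shape
    if ci != c:
        raise ValueError(f"conv2d: input has {c} channels, weight expects {ci}")
    s, p = int(stride), int(padding)
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)))
    ho = (h + 2 * p - kh) // s + 1
    wo = (wd + 2 * p - kw) // s + 1
    view = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    view = view[:, :, ::s, ::s][:, :, :ho, :wo]  # (N,C,Ho,Wo,kh,kw)
    out_data = np.einsum("nchwij,ocij->nohw", view, w.data, optimize=True)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]
    prev = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, _prev=prev)

    def _bw(g):
        if w.requires_grad or w._prev:
            w._accumulate(np.einsum("nohw,nchwij->ocij", g, view, optimize=True))
        if b is not None and (b.requires_grad or b._prev):
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._prev:
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += np.einsum(
                        "nohw,oc->nchw", g, w.data[:, :, i, j], optimize=True)
            x._accumulate(gxp[:, :, p:p + h, p:p + wd] if p else gxp)
    out._backward = _bw
    return out
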