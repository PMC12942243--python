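"""Minimal reverse-mode automatic differentiation over numpy arrays.

Every differentiable operation in this package (geometry indices inside
training pipelines, the graph transformer, the keypoint net, the diffusion
denoiser) runs on :class:`Tensor`, a thin wrapper around an ``ndarray`` that
records a backward closure per operation.  The design follows the classic
tape-free topological-sort pattern; broadcasting is handled by summing
gradients back to the parent shape.

Only the primitives this package needs are implemented.  Reported (non
training) metric values are computed on plain numpy and never touch this
module.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concatenate",
    "stack",
    "matmul",
    "solve",
    "softmax",
    "logsumexp",
    "smooth_abs",
    "arccos_clamped",
    "arctan2",
    "where_mask",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` (a broadcasted gradient) back to ``shape``."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self.grad = None
        self._parents = tuple(p for p in parents if p.requires_grad) if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # ---- introspection ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __len__(self):
        return len(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    # ---- graph machinery ----------------------------------------------
    def backward(self, grad=None):
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t._backward is None:
                # leaf: accumulate into .grad (intermediates skip this)
                t.grad = g if t.grad is None else t.grad + g
                continue
            for parent, pg in t._backward(g):
                if not parent.requires_grad:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg

    def zero_grad(self):
        self.grad = None

    # ---- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        a, b = self, other
        out = Tensor(a.data + b.data, parents=(a, b))
        out._backward = lambda g: (
            (a, _unbroadcast(g, a.data.shape)),
            (b, _unbroadcast(g, b.data.shape)),
        ) if out.requires_grad else None
        return out

    __radd__ = __add__

    def __neg__(self):
        a = self
        out = Tensor(-a.data, parents=(a,))
        out._backward = (lambda g: ((a, -g),)) if out.requires_grad else None
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        a, b = self, other
        out = Tensor(a.data * b.data, parents=(a, b))
        out._backward = lambda g: (
            (a, _unbroadcast(g * b.data, a.data.shape)),
            (b, _unbroadcast(g * a.data, b.data.shape)),
        ) if out.requires_grad else None
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        a, b = self, other
        out = Tensor(a.data / b.data, parents=(a, b))
        out._backward = lambda g: (
            (a, _unbroadcast(g / b.data, a.data.shape)),
            (b, _unbroadcast(-g * a.data / (b.data ** 2), b.data.shape)),
        ) if out.requires_grad else None
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        a = self
        out = Tensor(a.data ** p, parents=(a,))
        out._backward = (lambda g: ((a, g * p * a.data ** (p - 1)),)) if out.requires_grad else None
        return out

    def __matmul__(self, other):
        return matmul(self, as_tensor(other))

    def __getitem__(self, idx):
        a = self
        out = Tensor(a.data[idx], parents=(a,))

        def bwd(g):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            return ((a, full),)

        out._backward = bwd if out.requires_grad else None
        return out

    # ---- shape ops ------------------------------------------------------
    def reshape(self, *shape):
        a = self
        out = Tensor(a.data.reshape(*shape), parents=(a,))
        out._backward = (lambda g: ((a, g.reshape(a.data.shape)),)) if out.requires_grad else None
        return out

    def transpose(self, *axes):
        a = self
        axes = axes or tuple(reversed(range(a.ndim)))
        inv = np.argsort(axes)
        out = Tensor(a.data.transpose(axes), parents=(a,))
        out._backward = (lambda g: ((a, g.transpose(inv)),)) if out.requires_grad else None
        return out

    def swapaxes(self, ax1, ax2):
        a = self
        out = Tensor(np.swapaxes(a.data, ax1, ax2), parents=(a,))
        out._backward = (lambda g: ((a, np.swapaxes(g, ax1, ax2)),)) if out.requires_grad else None
        return out

    # ---- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self
        out = Tensor(a.data.sum(axis=axis, keepdims=keepdims), parents=(a,))

        def bwd(g):
            if axis is None:
                return ((a, np.broadcast_to(g, a.data.shape).copy()),)
            g2 = g
            if not keepdims:
                g2 = np.expand_dims(g, axis)
            return ((a, np.broadcast_to(g2, a.data.shape).copy()),)

        out._backward = bwd if out.requires_grad else None
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # ---- elementwise nonlinearities -------------------------------------
    def exp(self):
        a = self
        val = np.exp(a.data)
        out = Tensor(val, parents=(a,))
        out._backward = (lambda g: ((a, g * val),)) if out.requires_grad else None
        return out

    def log(self):
        a = self
        out = Tensor(np.log(a.data), parents=(a,))
        out._backward = (lambda g: ((a, g / a.data),)) if out.requires_grad else None
        return out

    def sqrt(self):
        a = self
        val = np.sqrt(a.data)
        out = Tensor(val, parents=(a,))
        out._backward = (lambda g: ((a, g * 0.5 / val),)) if out.requires_grad else None
        return out

    def tanh(self):
        a = self
        val = np.tanh(a.data)
        out = Tensor(val, parents=(a,))
        out._backward = (lambda g: ((a, g * (1.0 - val ** 2)),)) if out.requires_grad else None
        return out

    def relu(self):
        a = self
        mask = a.data > 0
        out = Tensor(a.data * mask, parents=(a,))
        out._backward = (lambda g: ((a, g * mask),)) if out.requires_grad else None
        return out

    def sigmoid(self):
        a = self
        val = 1.0 / (1.0 + np.exp(-a.data))
        out = Tensor(val, parents=(a,))
        out._backward = (lambda g: ((a, g * val * (1.0 - val)),)) if out.requires_grad else None
        return out

    def sin(self):
        a = self
        out = Tensor(np.sin(a.data), parents=(a,))
        out._backward = (lambda g: ((a, g * np.cos(a.data)),)) if out.requires_grad else None
        return out

    def cos(self):
        a = self
        out = Tensor(np.cos(a.data), parents=(a,))
        out._backward = (lambda g: ((a, -g * np.sin(a.data)),)) if out.requires_grad else None
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data @ b.data, parents=(a, b))

    def bwd(g):
        if a.data.ndim == 1 and b.data.ndim == 1:
            return ((a, g * b.data), (b, g * a.data))
        ad, bd = a.data, b.data
        if ad.ndim == 1:
            ad = ad[None, :]
            ga = (g[..., None, :] @ np.swapaxes(bd, -1, -2)).reshape(-1, ad.shape[-1]).sum(0)
            gb = _unbroadcast(np.swapaxes(ad, -1, -2) @ np.atleast_2d(g), bd.shape)
            return ((a, ga), (b, gb))
        if bd.ndim == 1:
            gb_full = np.swapaxes(ad, -1, -2) @ g[..., None]
            gb = gb_full[..., 0]
            gb = _unbroadcast(gb, bd.shape)
            ga = _unbroadcast(g[..., None] @ bd[None, :], ad.shape)
            return ((a, ga), (b, gb))
        ga = _unbroadcast(g @ np.swapaxes(bd, -1, -2), ad.shape)
        gb = _unbroadcast(np.swapaxes(ad, -1, -2) @ g, bd.shape)
        return ((a, ga), (b, gb))

    out._backward = bwd if out.requires_grad else None
    return out


def solve(A: Tensor, b: Tensor) -> Tensor:
    """Differentiable ``np.linalg.solve`` for a square system ``A x = b``."""
    A, b = as_tensor(A), as_tensor(b)
    x = np.linalg.solve(A.data, b.data)
    out = Tensor(x, parents=(A, b))

    def bwd(g):
        gb = np.linalg.solve(A.data.T, g)
        if x.ndim == 1:
            gA = -np.outer(gb, x)
        else:
            gA = -gb @ x.T
        return ((A, gA), (b, gb))

    out._backward = bwd if out.requires_grad else None
    return out


def concatenate(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        parts = np.split(g, splits, axis=axis)
        return tuple(zip(tensors, parts))

    out._backward = bwd if out.requires_grad else None
    return out


def stack(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), parents=tuple(tensors))

    def bwd(g):
        parts = np.split(g, len(tensors), axis=axis)
        return tuple((t, p.reshape(t.data.shape)) for t, p in zip(tensors, parts))

    out._backward = bwd if out.requires_grad else None
    return out


def logsumexp(t: Tensor, axis=-1, keepdims=False) -> Tensor:
    m = np.max(t.data, axis=axis, keepdims=True)  # detached shift: exact identity
    shifted = t - Tensor(m)
    s = shifted.exp().sum(axis=axis, keepdims=True).log() + Tensor(m)
    if not keepdims:
        s = s.reshape(*np.squeeze(s.data, axis=axis).shape)
    return s


def softmax(t: Tensor, axis=-1) -> Tensor:
    m = np.max(t.data, axis=axis, keepdims=True)
    e = (t - Tensor(m)).exp()
    return e / e.sum(axis=axis, keepdims=True)


def smooth_abs(t: Tensor, eps: float = 1e-6) -> Tensor:
    """C^1 surrogate of |t|: sqrt(t^2 + eps^2) - eps (exact |t| when eps=0)."""
    if eps == 0.0:
        a = t
        val = np.abs(a.data)
        out = Tensor(val, parents=(a,))
        out._backward = (lambda g: ((a, g * np.sign(a.data)),)) if out.requires_grad else None
        return out
    return (t * t + eps * eps) ** 0.5 - eps


def arccos_clamped(t: Tensor, clamp: float = 1e-7) -> Tensor:
    """arccos with the argument clamped to [-1+clamp, 1-clamp] (finite gradient)."""
    a = t
    clipped = np.clip(a.data, -1.0 + clamp, 1.0 - clamp)
    val = np.arccos(clipped)
    out = Tensor(val, parents=(a,))

    def bwd(g):
        d = -1.0 / np.sqrt(1.0 - clipped ** 2)
        inside = (a.data > -1.0 + clamp) & (a.data < 1.0 - clamp)
        return ((a, g * d * inside),)

    out._backward = bwd if out.requires_grad else None
    return out


def arctan2(y: Tensor, x: Tensor) -> Tensor:
    y, x = as_tensor(y), as_tensor(x)
    out = Tensor(np.arctan2(y.data, x.data), parents=(y, x))

    def bwd(g):
        denom = x.data ** 2 + y.data ** 2
        return ((y, g * x.data / denom), (x, -g * y.data / denom))

    out._backward = bwd if out.requires_grad else None
    return out


def where_mask(mask: np.ndarray, a: Tensor, b: Tensor) -> Tensor:
    """Select a where mask else b; mask is a constant boolean array."""
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(np.where(mask, a.data, b.data), parents=(a, b))
    out._backward = (
        lambda g: (
            (a, _unbroadcast(g * mask, a.data.shape)),
            (b, _unbroadcast(g * (~mask), b.data.shape)),
        )
    ) if out.requires_grad else None
    return out
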