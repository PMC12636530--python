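"""Minimal reverse-mode automatic differentiation on numpy arrays.

The model in this package is small enough that a compact tape-based autograd
over float64 numpy arrays is both fast and exactly reproducible on one CPU
thread.  Only the operations the architecture needs are implemented: affine
maps, layer normalization, GELU/SiLU, softmax attention, pooling and the
usual shape plumbing.  Gradients flow to any leaf tensor with
``requires_grad=True``, which is what integrated-gradients attribution needs.
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional, Sequence, Union

import numpy as np
from scipy.special import ndtr

ArrayLike = Union[np.ndarray, float, int, "Tensor"]

_INV_SQRT2 = 1.0 / np.sqrt(2.0)
_INV_SQRT2PI = 1.0 / np.sqrt(2.0 * np.pi)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over the axes that numpy broadcasting introduced."""
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
    __slots__ = ("data", "grad", "requires_grad", "_vjp", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = bool(requires_grad)
        # vector-Jacobian product: upstream grad -> per-parent grads.
        # Stored as a plain function of the grad (never capturing the output
        # tensor itself) so graphs are cycle-free and freed by refcounting.
        self._vjp: Optional[Callable] = None
        self._parents: tuple = ()

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- graph construction --------------------------------------------------
    def _make(self, data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], Iterable[Optional[np.ndarray]]]) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._vjp = backward
        return out

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient "
                                 "requires a scalar tensor")
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=np.float64).reshape(self.data.shape)

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
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        for node in reversed(topo):
            if node._vjp is None or node.grad is None:
                continue
            upstream = node.grad
            grads = node._vjp(upstream)
            for p, g in zip(node._parents, grads):
                if p.requires_grad and g is not None:
                    if p.grad is None:
                        # pass-through grads (g is the upstream array) and
                        # views (split pieces) may alias another edge's
                        # buffer, so they are copied on first assignment
                        p.grad = g.copy() if (g is upstream or g.base is not None) else g
                    else:
                        np.add(p.grad, g, out=p.grad)
            node.grad = None      # free interior gradients as we go

    # -- arithmetic ----------------------------------------------------------
    @staticmethod
    def _coerce(x: ArrayLike) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other: ArrayLike) -> "Tensor":
        o = self._coerce(other)
        return self._make(self.data + o.data, (self, o),
                          lambda g: (_unbroadcast(g, self.shape),
                                     _unbroadcast(g, o.shape)))

    __radd__ = __add__

    def __mul__(self, other: ArrayLike) -> "Tensor":
        o = self._coerce(other)
        return self._make(self.data * o.data, (self, o),
                          lambda g: (_unbroadcast(g * o.data, self.shape),
                                     _unbroadcast(g * self.data, o.shape)))

    __rmul__ = __mul__

    def __neg__(self) -> "Tensor":
        return self * -1.0

    def __sub__(self, other: ArrayLike) -> "Tensor":
        return self + (-self._coerce(other))

    def __rsub__(self, other: ArrayLike) -> "Tensor":
        return self._coerce(other) + (-self)

    def __truediv__(self, other: ArrayLike) -> "Tensor":
        o = self._coerce(other)
        return self._make(self.data / o.data, (self, o),
                          lambda g: (_unbroadcast(g / o.data, self.shape),
                                     _unbroadcast(-g * self.data / (o.data ** 2), o.shape)))

    def __pow__(self, p: float) -> "Tensor":
        return self._make(self.data ** p, (self,),
                          lambda g: (g * p * self.data ** (p - 1),))

    def __matmul__(self, other: ArrayLike) -> "Tensor":
        o = self._coerce(other)

        def _bw(g):
            ga = gb = None
            if self.requires_grad:
                if o.data.ndim == 1:
                    ga = _unbroadcast(np.expand_dims(g, -1) * o.data, self.shape)
                else:
                    ga = _unbroadcast(g @ np.swapaxes(o.data, -1, -2), self.shape)
            if o.requires_grad:
                if self.data.ndim == 1:
                    gb = _unbroadcast(np.outer(self.data, g), o.shape)
                else:
                    gb = _unbroadcast(np.swapaxes(self.data, -1, -2) @ g, o.shape)
            return ga, gb

        return self._make(self.data @ o.data, (self, o), _bw)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def _bw(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.shape).copy(),)

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), _bw)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False) -> "Tensor":
        out = self.data.max(axis=axis, keepdims=True)
        # ties share the gradient equally, keeping the op deterministic
        mask = (self.data == out).astype(np.float64)
        mask /= mask.sum(axis=axis, keepdims=True)

        def _bw(g):
            gg = g if keepdims else np.expand_dims(g, axis)
            return (mask * gg,)

        return self._make(out if keepdims else out.squeeze(axis=axis), (self,), _bw)

    # -- shape plumbing ------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        return self._make(self.data.reshape(shape), (self,),
                          lambda g: (g.reshape(old),))

    def swapaxes(self, a: int, b: int) -> "Tensor":
        return self._make(np.swapaxes(self.data, a, b), (self,),
                          lambda g: (np.swapaxes(g, a, b),))

    def __getitem__(self, idx) -> "Tensor":
        def _bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        return self._make(self.data[idx], (self,), _bw)

    # -- nonlinearities ------------------------------------------------------
    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)
        return self._make(out_data, (self,), lambda g: (g * out_data,))

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)
        return self._make(out_data, (self,), lambda g: (g * (1 - out_data ** 2),))

    def gelu(self) -> "Tensor":
        """Exact Gaussian-CDF GELU: x * Phi(x)."""
        x = self.data
        phi = ndtr(x)
        return self._make(
            x * phi, (self,),
            lambda g: (g * (phi + x * (_INV_SQRT2PI * np.exp(-0.5 * x * x))),))

    def silu(self) -> "Tensor":
        x = self.data
        sig = 1.0 / (1.0 + np.exp(-x))
        return self._make(x * sig, (self,),
                          lambda g: (g * (sig * (1 + x * (1 - sig))),))

    def softmax(self, axis: int = -1) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def _bw(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            return (s * (g - dot),)

        return self._make(s, (self,), _bw)

    def layer_norm(self, eps: float = 1e-5) -> "Tensor":
        """Normalize over the last axis to zero mean, unit variance."""
        mu = self.data.mean(axis=-1, keepdims=True)
        xc = self.data - mu
        var = (xc ** 2).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = xc * inv
        n = self.data.shape[-1]

        def _bw(g):
            gm = g.mean(axis=-1, keepdims=True)
            gx = (g * xhat).mean(axis=-1, keepdims=True)
            return (inv * (g - gm - xhat * gx),)

        return self._make(xhat, (self,), _bw)


def concatenate(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data)
    out.requires_grad = any(t.requires_grad for t in tensors)
    if out.requires_grad:
        out._parents = tuple(tensors)
        out._vjp = lambda g: tuple(np.split(g, splits, axis=axis))
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    expanded = []
    for t in tensors:
        t = Tensor._coerce(t)
        expanded.append(t.reshape(t.shape[:axis] + (1,) + t.shape[axis:]))
    return concatenate(expanded, axis=axis)
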