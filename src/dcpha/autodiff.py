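"""Minimal reverse-mode automatic differentiation over NumPy arrays.

A small tape-based autograd: :class:`Tensor` wraps an ``ndarray`` and records
the operations applied to it; :meth:`Tensor.backward` walks the tape in
reverse topological order and accumulates gradients.  Only the operations the
hashing model and its losses need are implemented (elementwise arithmetic
with broadcasting, matmul, exp/log/sqrt/tanh/relu/abs, reductions, reshape,
transpose, slicing, concatenation and an im2col patch extractor for the
convolutional backbones).

Every functional op in this module also accepts plain ``ndarray`` input and
then simply returns an ``ndarray``, so the similarity/loss formulas can be
written once and evaluated either differentiably (training) or as plain
NumPy (evaluation, tests).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "exp",
    "log",
    "sqrt",
    "tanh",
    "relu",
    "absolute",
    "tsum",
    "tmean",
    "matmul",
    "reshape",
    "transpose",
    "concatenate",
    "softmax",
    "im2col",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes that were added or stretched by broadcasting
    so it matches ``shape``."""
    if grad.shape == shape:
        return grad
    # leading axes that broadcasting prepended
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # axes of size 1 that were stretched
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray with an attached gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # make ndarray <op> Tensor defer to the Tensor reflected operators
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _op(data: np.ndarray, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            return _unbroadcast(g, self.shape), _unbroadcast(g, other.shape)

        return Tensor._op(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._op(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return Tensor._op(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out_data = self.data / other.data

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return Tensor._op(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")
        out_data = self.data**p

        def backward(g):
            return (g * p * self.data ** (p - 1),)

        return Tensor._op(out_data, (self,), backward)

    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            a, b = self.data, other.data
            if a.ndim == 2 and b.ndim == 2:
                return g @ b.T, a.T @ g
            raise NotImplementedError("matmul gradient implemented for 2-D only")

        return Tensor._op(out_data, (self, other), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        return Tensor._op(out_data, (self,), backward)

    # -- reductions and shape ops --------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return Tensor._op(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)
        orig = self.shape
        return Tensor._op(out_data, (self,), lambda g: (g.reshape(orig),))

    @property
    def T(self):
        return Tensor._op(self.data.T, (self,), lambda g: (g.T,))

    def permute(self, axes: tuple[int, ...]):
        inv = tuple(np.argsort(axes))
        return Tensor._op(self.data.transpose(axes), (self,),
                          lambda g: (g.transpose(inv),))

    # -- autograd -------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients of ``self`` (a scalar unless ``grad`` given)
        into ``.grad`` of every reachable tensor with ``requires_grad``."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("grad must be supplied for non-scalar output")
            grad = np.ones_like(self.data)

        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: deep graphs must not hit recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))

        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            parent_grads = node._backward(g)
            for p, pg in zip(node._parents, parent_grads):
                if not p.requires_grad:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg

    def zero_grad(self) -> None:
        self.grad = None


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _is_t(x) -> bool:
    return isinstance(x, Tensor)


# ---------------------------------------------------------------------------
# Functional ops.  Each accepts Tensor or ndarray; ndarray input short-circuits
# to plain NumPy so formulas can be shared with non-differentiable code paths.
# ---------------------------------------------------------------------------

def exp(x):
    if not _is_t(x):
        return np.exp(x)
    out_data = np.exp(x.data)
    return Tensor._op(out_data, (x,), lambda g: (g * out_data,))


def log(x):
    if not _is_t(x):
        return np.log(x)
    return Tensor._op(np.log(x.data), (x,), lambda g: (g / x.data,))


def sqrt(x):
    if not _is_t(x):
        return np.sqrt(x)
    out_data = np.sqrt(x.data)
    return Tensor._op(out_data, (x,), lambda g: (g / (2.0 * out_data),))


def tanh(x):
    if not _is_t(x):
        return np.tanh(x)
    out_data = np.tanh(x.data)
    return Tensor._op(out_data, (x,), lambda g: (g * (1.0 - out_data**2),))


def relu(x):
    if not _is_t(x):
        return np.maximum(x, 0.0)
    mask = x.data > 0
    return Tensor._op(x.data * mask, (x,), lambda g: (g * mask,))


def absolute(x):
    if not _is_t(x):
        return np.abs(x)
    s = np.sign(x.data)  # subgradient: sign(0) = 0
    return Tensor._op(np.abs(x.data), (x,), lambda g: (g * s,))


def tsum(x, axis=None, keepdims: bool = False):
    if not _is_t(x):
        return np.sum(x, axis=axis, keepdims=keepdims)
    return x.sum(axis=axis, keepdims=keepdims)


def tmean(x, axis=None, keepdims: bool = False):
    if not _is_t(x):
        return np.mean(x, axis=axis, keepdims=keepdims)
    return x.mean(axis=axis, keepdims=keepdims)


def matmul(a, b):
    if not _is_t(a) and not _is_t(b):
        return a @ b
    return as_tensor(a) @ as_tensor(b)


def reshape(x, shape):
    if not _is_t(x):
        return np.reshape(x, shape)
    return x.reshape(shape)


def transpose(x):
    return x.T


def permute(x, axes: tuple[int, ...]):
    if not _is_t(x):
        return np.transpose(x, axes)
    return x.permute(tuple(axes))


def concatenate(xs, axis: int = 0):
    if not any(_is_t(x) for x in xs):
        return np.concatenate(xs, axis=axis)
    xs = [as_tensor(x) for x in xs]
    out_data = np.concatenate([x.data for x in xs], axis=axis)
    sizes = [x.shape[axis] for x in xs]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._op(out_data, tuple(xs), backward)


def softmax(x, axis: int = -1):
    """Numerically stable softmax along ``axis``."""
    if not _is_t(x):
        z = x - np.max(x, axis=axis, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=axis, keepdims=True)
    shift = np.max(x.data, axis=axis, keepdims=True)  # constant shift: no grad
    e = exp(x - Tensor(shift))
    return e / e.sum(axis=axis, keepdims=True)


def im2col(x, ksize: int, stride: int = 1):
    """Extract sliding ``ksize``×``ksize`` patches of an (N, C, H, W) input.

    Returns (N, C*ksize*ksize, P) where P is the number of patch positions —
    the standard lowering that turns convolution into a matrix product.
    """
    data = x.data if _is_t(x) else np.asarray(x)
    n, c, h, w = data.shape
    oh = (h - ksize) // stride + 1
    ow = (w - ksize) // stride + 1
    windows = np.lib.stride_tricks.sliding_window_view(data, (ksize, ksize), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride, :, :]  # (N, C, oh, ow, k, k)
    cols = windows.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * ksize * ksize, oh * ow)
    if not _is_t(x):
        return cols

    def backward(g):
        g6 = g.reshape(n, c, ksize, ksize, oh, ow).transpose(0, 1, 4, 5, 2, 3)
        full = np.zeros_like(data)
        for i in range(ksize):
            for j in range(ksize):
                full[:, :, i : i + oh * stride : stride, j : j + ow * stride : stride] += g6[
                    :, :, :, :, i, j
                ]
        return (full,)

    return Tensor._op(np.ascontiguousarray(cols), (x,), backward)
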