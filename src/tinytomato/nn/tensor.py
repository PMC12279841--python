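"""Reverse-mode automatic differentiation on NumPy arrays.

A deliberately small tape-based engine: each :class:`Tensor` wraps a
``float32``/``float64`` ndarray and records a closure that propagates the
upstream gradient to its parents.  ``backward()`` walks the graph in reverse
topological order.  Only the operations the detector components need are
implemented; all support full NumPy broadcasting.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "exp",
    "log",
    "sqrt",
    "square",
    "arctan",
    "arcsin",
    "sin",
    "absolute",
    "maximum",
    "minimum",
    "clip",
    "sigmoid",
    "silu",
    "relu",
    "softmax",
    "concatenate",
    "stack",
    "pad2d",
    "no_grad",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class _NoGrad:
    _depth = 0

    def __enter__(self):
        _NoGrad._depth += 1

    def __exit__(self, *exc):
        _NoGrad._depth -= 1


def no_grad():
    return _NoGrad()


def _grad_enabled() -> bool:
    return _NoGrad._depth == 0


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # make ndarray <op> Tensor defer to the reflected Tensor operators
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=np.float32 if np.asarray(data).dtype.kind != "f" else None)
        if self.data.dtype not in (np.float32, np.float64):
            self.data = self.data.astype(np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _grad_enabled()
        self._backward = None
        self._parents: tuple = ()

    # ---- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _grad_enabled() and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

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
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def __array__(self, dtype=None, copy=None):
        return self.data if dtype is None else self.data.astype(dtype)

    def __float__(self) -> float:
        return float(self.data)

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    # ---- autodiff driver ------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        grad = np.asarray(grad, dtype=self.data.dtype)

        # iterative topological sort (graphs can be deep at large image sizes)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited:
                    stack.append((p, False))

        self.grad = grad if self.grad is None else self.grad + grad
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.copy() if g.base is not None or g.flags.writeable is False else g
        else:
            self.grad = self.grad + g

    # ---- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / (other.data * other.data), other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")
        out_data = self.data ** p

        def backward(g):
            self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(out_data, (self,), backward)

    def __abs__(self):
        out_data = np.abs(self.data)

        def backward(g):
            self._accum(g * np.sign(self.data))

        return Tensor._make(out_data, (self,), backward)

    # comparisons give plain boolean arrays (no gradient)
    def __gt__(self, other):
        return self.data > (other.data if isinstance(other, Tensor) else other)

    def __lt__(self, other):
        return self.data < (other.data if isinstance(other, Tensor) else other)

    def __ge__(self, other):
        return self.data >= (other.data if isinstance(other, Tensor) else other)

    def __le__(self, other):
        return self.data <= (other.data if isinstance(other, Tensor) else other)

    # ---- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).astype(self.data.dtype, copy=True))
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis=None, keepdims=True):
        """Max reduction; gradient flows to (all) argmax positions."""
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        mask = self.data == (out_data if keepdims or axis is None else np.expand_dims(out_data, axis))

        def backward(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            counts = mask.sum(axis=axis, keepdims=True) if axis is not None else mask.sum()
            self._accum(np.where(mask, g / counts, 0.0).astype(self.data.dtype))

        return Tensor._make(out_data, (self,), backward)

    # ---- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            self._accum(g.reshape(orig))

        return Tensor._make(out_data, (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def backward(g):
            self._accum(g.transpose(inv))

        return Tensor._make(out_data, (self,), backward)

    def swapaxes(self, a, b):
        axes = list(range(self.data.ndim))
        axes[a], axes[b] = axes[b], axes[a]
        return self.transpose(*axes)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return Tensor._make(out_data, (self,), backward)

    # ---- linear algebra -------------------------------------------------------
    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---- elementwise functions (work on Tensor or ndarray) ------------------------

def _elementwise(x, fn, dfn):
    if not isinstance(x, Tensor):
        return fn(np.asarray(x))
    out_data = fn(x.data)

    def backward(g):
        x._accum(g * dfn(x.data, out_data))

    return Tensor._make(out_data, (x,), backward)


def exp(x):
    return _elementwise(x, np.exp, lambda d, o: o)


def log(x):
    return _elementwise(x, np.log, lambda d, o: 1.0 / d)


def sqrt(x):
    return _elementwise(x, np.sqrt, lambda d, o: 0.5 / o)


def square(x):
    return _elementwise(x, np.square, lambda d, o: 2.0 * d)


def arctan(x):
    return _elementwise(x, np.arctan, lambda d, o: 1.0 / (1.0 + d * d))


def arcsin(x):
    return _elementwise(x, np.arcsin, lambda d, o: 1.0 / np.sqrt(1.0 - d * d))


def sin(x):
    return _elementwise(x, np.sin, lambda d, o: np.cos(d))


def absolute(x):
    if not isinstance(x, Tensor):
        return np.abs(x)
    return abs(x)


def sigmoid(x):
    def fn(d):
        return np.where(d >= 0, 1.0 / (1.0 + np.exp(-np.abs(d))), np.exp(-np.abs(d)) / (1.0 + np.exp(-np.abs(d))))

    return _elementwise(x, fn, lambda d, o: o * (1.0 - o))


def silu(x):
    """Fused x·σ(x) with a single backward closure (hot path)."""
    def _sig(d):
        e = np.exp(-np.abs(d))
        return np.where(d >= 0, 1.0 / (1.0 + e), e / (1.0 + e))

    if not isinstance(x, Tensor):
        return x * _sig(x)
    s = _sig(x.data)
    out_data = x.data * s

    def backward(g):
        x._accum(g * s * (1.0 + x.data * (1.0 - s)))

    return Tensor._make(out_data, (x,), backward)


def relu(x):
    return _elementwise(x, lambda d: np.maximum(d, 0.0), lambda d, o: (d > 0).astype(d.dtype))


def maximum(a, b):
    if not isinstance(a, Tensor) and not isinstance(b, Tensor):
        return np.maximum(a, b)
    a, b = as_tensor(a), as_tensor(b)
    out_data = np.maximum(a.data, b.data)
    mask = a.data >= b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(np.where(mask, g, 0.0), a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(np.where(mask, 0.0, g), b.data.shape))

    return Tensor._make(out_data, (a, b), backward)


def minimum(a, b):
    if not isinstance(a, Tensor) and not isinstance(b, Tensor):
        return np.minimum(a, b)
    a, b = as_tensor(a), as_tensor(b)
    out_data = np.minimum(a.data, b.data)
    mask = a.data <= b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(np.where(mask, g, 0.0), a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(np.where(mask, 0.0, g), b.data.shape))

    return Tensor._make(out_data, (a, b), backward)


def clip(x, lo, hi):
    if not isinstance(x, Tensor):
        return np.clip(x, lo, hi)
    out_data = np.clip(x.data, lo, hi)
    mask = (x.data >= lo) & (x.data <= hi)

    def backward(g):
        x._accum(np.where(mask, g, 0.0))

    return Tensor._make(out_data, (x,), backward)


def softmax(x, axis=-1):
    if not isinstance(x, Tensor):
        z = x - np.max(x, axis=axis, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=axis, keepdims=True)
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        x._accum(s * (g - dot))

    return Tensor._make(s, (x,), backward)


def concatenate(tensors, axis=0):
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), backward)


def stack(tensors, axis=0):
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    return Tensor._make(out_data, tuple(tensors), backward)


def pad2d(x: Tensor, pad: int):
    """Zero-pad the two trailing (spatial) axes of an NCHW tensor."""
    if pad == 0:
        return x
    if not isinstance(x, Tensor):
        return np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    out_data = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))

    def backward(g):
        x._accum(g[:, :, pad:-pad, pad:-pad])

    return Tensor._make(out_data, (x,), backward)
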