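"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operations the localization network and its losses
need: broadcasting arithmetic, matmul, strided 2-D convolution (im2col),
ReLU/sigmoid/log, clamping, axis reductions (sum/mean/max with
first-index tie-breaking), concatenation, basic slicing and axis flips.
Gradients are accumulated on a tape and resolved in reverse topological
order by :meth:`Tensor.backward`.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "conv2d"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
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
    """A numpy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # make ndarray <op> Tensor defer to the reflected Tensor operators
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False, parents: tuple = (), backward: Callable | None = None):
        if isinstance(data, (int, float)):
            # scalar constants stay float32 so they never promote a
            # float32 network graph; float64 arrays still win promotion
            data = np.float32(data)
        data = np.asarray(data)
        if not np.issubdtype(data.dtype, np.floating):
            data = data.astype(np.float64)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    # -------------------------------------------------------------- basics
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # ---------------------------------------------------------- arithmetic
    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = _make(self.data + other.data, (self, other))

        def backward(g):
            _accum(self, _unbroadcast(g, self.shape))
            _accum(other, _unbroadcast(g, other.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = _make(-self.data, (self,))
        out._backward = lambda g: _accum(self, -g)
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = _make(self.data * other.data, (self, other))

        def backward(g):
            _accum(self, _unbroadcast(g * other.data, self.shape))
            _accum(other, _unbroadcast(g * self.data, other.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = _make(self.data / other.data, (self, other))

        def backward(g):
            _accum(self, _unbroadcast(g / other.data, self.shape))
            _accum(other, _unbroadcast(-g * self.data / other.data**2, other.shape))

        out._backward = backward
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        other = as_tensor(other)
        out = _make(self.data @ other.data, (self, other))

        def backward(g):
            _accum(self, g @ other.data.swapaxes(-1, -2))
            _accum(other, _unbroadcast(self.data.swapaxes(-1, -2) @ g, other.shape))

        out._backward = backward
        return out

    __matmul__ = matmul

    # ------------------------------------------------------- element-wise
    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = _make(np.where(mask, self.data, 0.0), (self,))
        out._backward = lambda g: _accum(self, g * mask)
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = _make(s, (self,))
        out._backward = lambda g: _accum(self, g * s * (1.0 - s))
        return out

    def log(self) -> "Tensor":
        out = _make(np.log(self.data), (self,))
        out._backward = lambda g: _accum(self, g / self.data)
        return out

    def sqrt(self) -> "Tensor":
        s = np.sqrt(self.data)
        out = _make(s, (self,))
        out._backward = lambda g: _accum(self, g * (0.5 / s))
        return out

    def clip(self, lo: float, hi: float) -> "Tensor":
        """Clamp values; gradient is blocked where the clamp is active."""
        mask = (self.data > lo) & (self.data < hi)
        out = _make(np.clip(self.data, lo, hi), (self,))
        out._backward = lambda g: _accum(self, g * mask)
        return out

    # --------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = _make(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def backward(g):
            if axis is None:
                _accum(self, np.broadcast_to(g, self.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                _accum(self, np.broadcast_to(g, self.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod([self.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def amax(self, axis: int, keepdims: bool = False) -> "Tensor":
        """Maximum along one axis; ties route the gradient to the lowest index."""
        idx = np.argmax(self.data, axis=axis)  # first occurrence on ties
        val = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis=axis)
        out_data = val if keepdims else np.squeeze(val, axis=axis)
        out = _make(out_data, (self,))

        def backward(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            dx = np.zeros_like(self.data)
            np.put_along_axis(dx, np.expand_dims(idx, axis), g, axis=axis)
            _accum(self, dx)

        out._backward = backward
        return out

    # ------------------------------------------------------------- shapes
    def reshape(self, *shape) -> "Tensor":
        out = _make(self.data.reshape(*shape), (self,))
        out._backward = lambda g: _accum(self, g.reshape(self.shape))
        return out

    def transpose(self, *axes) -> "Tensor":
        inv = np.argsort(axes)
        out = _make(self.data.transpose(*axes), (self,))
        out._backward = lambda g: _accum(self, g.transpose(*inv))
        return out

    def flip(self, axis: int) -> "Tensor":
        out = _make(np.flip(self.data, axis=axis), (self,))
        out._backward = lambda g: _accum(self, np.flip(g, axis=axis))
        return out

    def __getitem__(self, key) -> "Tensor":
        out = _make(self.data[key], (self,))

        def backward(g):
            dx = np.zeros_like(self.data)
            np.add.at(dx, key, g)
            _accum(self, dx)

        out._backward = backward
        return out

    # ----------------------------------------------------------- backward
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        grad = np.asarray(grad, dtype=self.data.dtype)
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
        self.grad = grad
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None


def _make(data: np.ndarray, parents: tuple) -> Tensor:
    req = any(p.requires_grad or p._parents for p in parents)
    return Tensor(data, requires_grad=False, parents=parents if req else ())


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not (t.requires_grad or t._parents):
        return
    if t.grad is None:
        t.grad = g.astype(t.data.dtype, copy=True)
    else:
        t.grad += g


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            _accum(t, g[tuple(sl)])

    out._backward = backward
    return out


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # n, c, ho, wo, k, k
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
    return np.ascontiguousarray(cols), ho, wo


def _col2im(dcols: np.ndarray, xshape, k: int, stride: int, pad: int, ho: int, wo: int) -> np.ndarray:
    n, c, h, w = xshape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    d6 = dcols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 4, 5, 1, 2)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += d6[:, :, i, j]
    return dxp[:, :, pad : pad + h, pad : pad + w]


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution, NCHW layout, square kernel, via im2col."""
    x, weight = as_tensor(x), as_tensor(weight)
    o, cin, k, _ = weight.shape
    n = x.shape[0]
    cols, ho, wo = _im2col(x.data, k, stride, pad)
    wmat = weight.data.reshape(o, cin * k * k)
    out_data = cols @ wmat.T
    if bias is not None:
        out_data = out_data + bias.data
    out_data = out_data.reshape(n, ho, wo, o).transpose(0, 3, 1, 2)
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = _make(out_data, parents)

    def backward(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, o)
        _accum(weight, (gmat.T @ cols).reshape(weight.shape))
        if bias is not None:
            _accum(bias, gmat.sum(axis=0))
        if x.requires_grad or x._parents:
            dcols = gmat @ wmat
            _accum(x, _col2im(dcols, x.shape, k, stride, pad, ho, wo))

    out._backward = backward
    return out
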