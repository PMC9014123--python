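"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery to train the small fusion network on a CPU: dense and
convolutional primitives, elementwise math, reshaping, and reductions.  Each
op records its parents and a closure that accumulates gradients; ``backward``
runs a topological sort.  Branch selections (masks, clamps, sign) are treated
as locally constant, the usual convention for piecewise-linear losses.
"""

from __future__ import annotations

from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "concat"]


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward_fn")

    # make numpy defer to the reflected operators instead of broadcasting
    # Tensor objects elementwise
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence["Tensor"] = (), backward_fn=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward_fn = backward_fn

    # ---- infrastructure -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: List[Tensor] = []
        seen = set()

        def visit(t: "Tensor"):
            stack = [(t, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    topo.append(node)
                    continue
                if id(node) in seen or not node.requires_grad:
                    continue
                seen.add(id(node))
                stack.append((node, True))
                for p in node._parents:
                    stack.append((p, False))

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward_fn is not None and node.grad is not None:
                node._backward_fn(node.grad)

    # ---- elementwise ----------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward_fn = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward_fn = lambda g: self.requires_grad and self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward_fn = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        return self * other.pow(-1.0)

    def __rtruediv__(self, other):
        return Tensor._lift(other) * self.pow(-1.0)

    def pow(self, exponent: float) -> "Tensor":
        out = Tensor(np.power(self.data, exponent), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * exponent * np.power(self.data, exponent - 1.0))

        out._backward_fn = bw
        return out

    def exp(self) -> "Tensor":
        out = Tensor(np.exp(self.data), parents=(self,))
        out._backward_fn = lambda g: self.requires_grad and self._accum(g * out.data)
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward_fn = lambda g: self.requires_grad and self._accum(g / self.data)
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, parents=(self,))
        out._backward_fn = lambda g: self.requires_grad and self._accum(g * s * (1.0 - s))
        return out

    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = Tensor(self.data * mask, parents=(self,))
        out._backward_fn = lambda g: self.requires_grad and self._accum(g * mask)
        return out

    def clamp(self, lo: float, hi: float) -> "Tensor":
        mask = (self.data > lo) & (self.data < hi)
        out = Tensor(np.clip(self.data, lo, hi), parents=(self,))
        out._backward_fn = lambda g: self.requires_grad and self._accum(g * mask)
        return out

    def abs(self) -> "Tensor":
        sign = np.sign(self.data)
        out = Tensor(np.abs(self.data), parents=(self,))
        out._backward_fn = lambda g: self.requires_grad and self._accum(g * sign)
        return out

    # ---- reductions and shape -------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                g2 = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g2, self.data.shape).copy())

        out._backward_fn = bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward_fn = lambda g: self.requires_grad and self._accum(
            g.reshape(self.data.shape)
        )
        return out

    def transpose(self, axes: Sequence[int]) -> "Tensor":
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), parents=(self,))
        out._backward_fn = lambda g: self.requires_grad and self._accum(g.transpose(inv))
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        other = Tensor._lift(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        out._backward_fn = bw
        return out

    # ---- structured ops -------------------------------------------------

    def conv2d(self, weight: "Tensor", bias: Optional["Tensor"] = None,
               stride: int = 1, padding: int = 0) -> "Tensor":
        """2-D cross-correlation, NCHW input and OIkk weight."""
        x, w = self.data, weight.data
        n, c, h, wd = x.shape
        o, _, k, _ = w.shape
        xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
        y = np.tensordot(win, w, axes=([1, 4, 5], [1, 2, 3])).transpose(0, 3, 1, 2)
        if bias is not None:
            y = y + bias.data.reshape(1, o, 1, 1)
        parents = (self, weight) + ((bias,) if bias is not None else ())
        out = Tensor(np.ascontiguousarray(y), parents=parents)

        def bw(g):
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3)))
            if weight.requires_grad:
                weight._accum(np.tensordot(g, win, axes=([0, 2, 3], [0, 2, 3])))
            if self.requires_grad:
                # dX via k*k shifted scatter-adds; avoids large im2col buffers
                ho, wo = g.shape[2], g.shape[3]
                dxp = np.zeros((n, c, h + 2 * padding, wd + 2 * padding))
                for i in range(k):
                    for j in range(k):
                        # (N,O,Ho,Wo) x (O,C) -> (N,Ho,Wo,C)
                        contrib = np.tensordot(g, w[:, :, i, j], axes=([1], [0]))
                        dxp[:, :, i: i + stride * ho: stride,
                            j: j + stride * wo: stride] += contrib.transpose(0, 3, 1, 2)
                self._accum(dxp[:, :, padding: padding + h, padding: padding + wd])

        out._backward_fn = bw
        return out

    def avg_pool2(self) -> "Tensor":
        """2x2 average pooling (even spatial dims)."""
        n, c, h, w = self.data.shape
        y = self.data.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))
        out = Tensor(y, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) / 4.0)

        out._backward_fn = bw
        return out

    def upsample2(self) -> "Tensor":
        """Nearest-neighbour 2x upsampling."""
        y = np.repeat(np.repeat(self.data, 2, axis=2), 2, axis=3)
        out = Tensor(y, parents=(self,))

        def bw(g):
            if self.requires_grad:
                n, c, h, w = g.shape
                self._accum(g.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5)))

        out._backward_fn = bw
        return out

    def dropout(self, rate: float, rng: np.random.Generator,
                training: bool) -> "Tensor":
        if not training or rate <= 0.0:
            return self
        keep = (rng.random(self.data.shape) >= rate) / (1.0 - rate)
        out = Tensor(self.data * keep, parents=(self,))
        out._backward_fn = lambda g: self.requires_grad and self._accum(g * keep)
        return out


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = list(tensors)
    out = Tensor(np.concatenate([t.data for t in ts], axis=axis), parents=tuple(ts))
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(a, b)
                t._accum(g[tuple(idx)])

    out._backward_fn = bw
    return out
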