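"""Reverse-mode autodiff over numpy arrays.

Only the primitives the decoding network needs are implemented: broadcasted
arithmetic, matmul against 2-D weight matrices, elementwise nonlinearities,
axis reductions, reshaping/slicing/concatenation, softmax, strided 1-D
convolution, 2-x-2 average pooling, and a sliding "attention buffer" gather.
Each primitive records a closure that accumulates gradients into its parents;
``Tensor.backward`` runs them in reverse topological order.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "is_grad_enabled",
    "concat",
    "softmax",
    "conv1d",
    "avgpool2d",
    "pad2d",
    "conv2d_3x3_same",
    "sliding_buffer",
]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, (np.ndarray, np.generic)):
            self.data = np.asarray(data)
        else:
            self.data = np.asarray(data, dtype=np.float64)
        if self.data.dtype not in (np.float32, np.float64):
            self.data = self.data.astype(np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = bool(requires_grad)
        self._parents: Tuple["Tensor", ...] = ()
        self._backward: Optional[Callable[[np.ndarray], None]] = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"], backward) -> "Tensor":
        track = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=track)
        if track:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def _accum(self, grad: np.ndarray) -> None:
        # first contribution aliases the incoming buffer (safe: a node's grad
        # is final before its backward runs); later contributions allocate
        if self.grad is None:
            self.grad = np.asarray(grad)
        else:
            self.grad = self.grad + grad

    # -- arithmetic -----------------------------------------------------------
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=np.float64))

    def _scalar_op(self, c: float, kind: str) -> "Tensor":
        """Fast path for python-scalar arithmetic (keeps float32 float32)."""
        if kind == "add":
            out_data, factor = self.data + c, 1.0
        elif kind == "mul":
            out_data, factor = self.data * c, c
        else:  # div
            out_data, factor = self.data / c, 1.0 / c

        def backward(g):
            if self.requires_grad:
                self._accum(g if factor == 1.0 else g * factor)

        return Tensor._make(out_data, (self,), backward)

    def __add__(self, other):
        if isinstance(other, (int, float)):
            return self._scalar_op(float(other), "add")
        other = self._coerce(other)
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
            if self.requires_grad:
                self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            return self._scalar_op(-float(other), "add")
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        if isinstance(other, (int, float)):
            return (-self)._scalar_op(float(other), "add")
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            return self._scalar_op(float(other), "mul")
        other = self._coerce(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self._scalar_op(float(other), "div")
        other = self._coerce(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data**2, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __matmul__(self, other):
        """Matmul against a 2-D weight matrix: (..., j) @ (j, k)."""
        other = self._coerce(other)
        if other.data.ndim != 2:
            raise ValueError("matmul right operand must be 2-D")
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                a2 = self.data.reshape(-1, self.data.shape[-1])
                g2 = g.reshape(-1, g.shape[-1])
                other._accum(a2.T @ g2)

        return Tensor._make(out_data, (self, other), backward)

    def __pow__(self, p: float):
        out_data = self.data**p

        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(out_data, (self,), backward)

    # -- nonlinearities -------------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data**2))

        return Tensor._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(np.clip(self.data, -700, 700))

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * 0.5 / np.maximum(out_data, 1e-300))

        return Tensor._make(out_data, (self,), backward)

    # -- reductions & shaping -------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                g2 = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g2, self.data.shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)
        old_shape = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old_shape))

        return Tensor._make(out_data, (self,), backward)

    def transpose(self, *axes):
        out_data = self.data.transpose(axes)
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return Tensor._make(out_data, (self,), backward)

    def __getitem__(self, idx):
        """Basic (non-repeating) indexing only."""
        out_data = self.data[idx]

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[idx] += g
                self._accum(full)

        return Tensor._make(out_data, (self,), backward)

    # -- autodiff driver ------------------------------------------------------
    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()
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
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


# -- free-function primitives -------------------------------------------------

def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
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


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if x.requires_grad:
            dot = (g * s).sum(axis=axis, keepdims=True)
            x._accum(s * (g - dot))

    return Tensor._make(s, (x,), backward)


def conv1d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1) -> Tensor:
    """1-D convolution of a batch of single-channel signals.

    x: (B, L); w: (C, K); b: (C,)  ->  (B, C, T) with T = (L-K)//stride + 1.
    """
    B, L = x.data.shape
    C, K = w.data.shape
    cols = np.lib.stride_tricks.sliding_window_view(x.data, K, axis=-1)[:, ::stride]  # (B,T,K)
    out_data = np.einsum("btk,ck->bct", cols, w.data, optimize=True) + b.data[None, :, None]
    T = cols.shape[1]

    def backward(g):
        if w.requires_grad:
            w._accum(np.einsum("btk,bct->ck", cols, g, optimize=True))
        if b.requires_grad:
            b._accum(g.sum(axis=(0, 2)))
        if x.requires_grad:
            dcols = np.einsum("bct,ck->btk", g, w.data, optimize=True)
            dx = np.zeros_like(x.data)
            idx = np.arange(T)[:, None] * stride + np.arange(K)[None, :]
            np.add.at(dx, (np.arange(B)[:, None, None], idx[None, :, :]), dcols)
            x._accum(dx)

    return Tensor._make(out_data, (x, w, b), backward)


def pad2d(x: Tensor, pad: int = 1) -> Tensor:
    """Zero-pad the last two axes of a (B, H, W) tensor."""
    out_data = np.pad(x.data, ((0, 0), (pad, pad), (pad, pad)))

    def backward(g):
        if x.requires_grad:
            x._accum(g[:, pad:-pad, pad:-pad])

    return Tensor._make(out_data, (x,), backward)


def avgpool2d(x: Tensor, k: int = 2) -> Tensor:
    """k-x-k average pooling on (B, H, W); trailing rows/cols are cropped."""
    B, H, W = x.data.shape
    H2, W2 = H // k, W // k
    view = x.data[:, : H2 * k, : W2 * k].reshape(B, H2, k, W2, k)
    out_data = view.mean(axis=(2, 4))

    def backward(g):
        if x.requires_grad:
            dx = np.zeros_like(x.data)
            dx[:, : H2 * k, : W2 * k] = (
                np.repeat(np.repeat(g, k, axis=1), k, axis=2) / (k * k)
            )
            x._accum(dx)

    return Tensor._make(out_data, (x,), backward)


def conv2d_3x3_same(x: Tensor, k: Tensor, b: Tensor) -> Tensor:
    """Single-channel 3x3 'same' convolution on (B, H, W), built from shifts."""
    xp = pad2d(x, 1)
    H, W = x.data.shape[1], x.data.shape[2]
    out = None
    for i in range(3):
        for j in range(3):
            term = xp[:, i : i + H, j : j + W] * k[i, j]
            out = term if out is None else out + term
    return out + b


def sliding_buffer(x: Tensor, size: int = 16) -> Tensor:
    """Causal sliding buffer over the time axis of (S, T, D).

    Returns (S, T, size, D) where slot ``size-1`` is the current vector and
    slot 0 the oldest; positions before the start of the sequence are zero
    (the buffer is zero-initialized).
    """
    S, T, D = x.data.shape
    xp = np.concatenate([np.zeros((S, size - 1, D), dtype=x.data.dtype), x.data], axis=1)
    win = np.lib.stride_tricks.sliding_window_view(xp, size, axis=1)  # (S,T,D,size)
    out_data = np.ascontiguousarray(win.transpose(0, 1, 3, 2))

    def backward(g):
        if x.requires_grad:
            dxp = np.zeros((S, T + size - 1, D), dtype=x.data.dtype)
            for i in range(size):
                dxp[:, i : i + T] += g[:, :, i]
            x._accum(dxp[:, size - 1 :])

    return Tensor._make(out_data, (x,), backward)
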