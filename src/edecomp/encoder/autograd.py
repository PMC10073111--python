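"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for a small 1-D convolution + transformer network:
broadcast-aware elementwise ops, batched matmul, reductions, reshapes, a
conv1d primitive, and a numerically stable binary cross-entropy-with-logits
loss.  Gradients flow through a topologically sorted tape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "conv1d", "bce_with_logits", "softmax", "layer_norm"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    # -- bookkeeping --------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: "Tensor") -> None:
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
        for t in topo:
            t.grad = np.zeros_like(t.data)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # -- elementwise --------------------------------------------------------

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g, other.data.shape)

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g * other.data, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g * self.data, other.data.shape)

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._wrap(other) ** -1.0

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self.grad += g * exponent * self.data ** (exponent - 1.0)

        out._backward = bw
        return out

    def exp(self):
        out = Tensor(np.exp(self.data), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self.grad += g * out.data

        out._backward = bw
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self.grad += g * (1.0 - out.data**2)

        out._backward = bw
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self.grad += g * (self.data > 0)

        out._backward = bw
        return out

    def gelu(self):
        """tanh-approximation GELU."""
        c = np.sqrt(2.0 / np.pi)
        inner = (self * c) + (self**3.0) * (0.044715 * c)
        return self * 0.5 * (inner.tanh() + 1.0)

    def sigmoid(self):
        x = self.data
        val = np.where(x >= 0, 1.0 / (1.0 + np.exp(-x)),
                       np.exp(x) / (1.0 + np.exp(x)))
        out = Tensor(val, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self.grad += g * out.data * (1.0 - out.data)

        out._backward = bw
        return out

    # -- shape --------------------------------------------------------------

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self.grad += g.reshape(self.data.shape)

        out._backward = bw
        return out

    def transpose(self, *axes):
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(*axes), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self.grad += g.transpose(*inv)

        out._backward = bw
        return out

    # -- reductions ---------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self.grad += np.broadcast_to(g, self.data.shape)
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self.grad += np.broadcast_to(gg, self.data.shape)

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- matmul -------------------------------------------------------------

    def matmul(self, other: "Tensor"):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self.grad += _unbroadcast(ga, self.data.shape)
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other.grad += _unbroadcast(gb, other.data.shape)

        out._backward = bw
        return out

    __matmul__ = matmul


# ---------------------------------------------------------------------------
# Composite / primitive operators
# ---------------------------------------------------------------------------


def softmax(x: Tensor) -> Tensor:
    """Softmax over the last axis (max-shifted for stability)."""
    shift = Tensor(x.data.max(axis=-1, keepdims=True))
    e = (x - shift).exp()
    return e * e.sum(axis=-1, keepdims=True) ** -1.0


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalisation over the last axis."""
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered**2.0).mean(axis=-1, keepdims=True)
    return centered * (var + eps) ** -0.5 * gain + bias


def conv1d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, padding: int = 0) -> Tensor:
    """1-D convolution: x (B, Cin, L), w (Cout, Cin, K), b (Cout,)."""
    B, Cin, L = x.data.shape
    Cout, _, K = w.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding)))
    Lout = (L + 2 * padding - K) // stride + 1
    windows = np.lib.stride_tricks.sliding_window_view(xp, K, axis=2)[
        :, :, :: stride, :
    ][:, :, :Lout, :]
    y = np.einsum("bclk,ock->bol", windows, w.data, optimize=True) + b.data[:, None]
    out = Tensor(y, parents=(x, w, b))

    def bw(g):
        if w.requires_grad:
            w.grad += np.einsum("bol,bclk->ock", g, windows, optimize=True)
        if b.requires_grad:
            b.grad += g.sum(axis=(0, 2))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for k in range(K):
                sl = slice(k, k + stride * (Lout - 1) + 1, stride)
                gxp[:, :, sl] += np.einsum(
                    "bol,oc->bcl", g, w.data[:, :, k], optimize=True
                )
            x.grad += gxp[:, :, padding : padding + L] if padding else gxp

    out._backward = bw
    return out


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on raw logits (numerically stable)."""
    y = np.asarray(targets, dtype=np.float64)
    z = logits.data
    loss_val = np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z))))
    out = Tensor(loss_val, parents=(logits,))

    def bw(g):
        if logits.requires_grad:
            p = np.where(z >= 0, 1.0 / (1.0 + np.exp(-z)),
                         np.exp(z) / (1.0 + np.exp(z)))
            logits.grad += g * (p - y) / y.size

    out._backward = bw
    return out
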