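"""A minimal reverse-mode automatic-differentiation engine over NumPy arrays.

Supports exactly the operations the epsilon-prediction U-Net needs: broadcast
arithmetic, (batched) matmul, 2-D convolution via im2col, nearest-neighbor
upsampling, reductions, reshapes, softmax and the SiLU nonlinearity.  Tensors
record their parents and a backward closure; ``Tensor.backward`` runs the tape
in reverse topological order.

Gradients through broadcasting are reduced back to the parent shape with
``_unbroadcast``; every op's gradient is verified against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "upsample_nearest"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast from ``shape``."""
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

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        def backward(g):
            return _unbroadcast(g, self.shape), _unbroadcast(g, other.shape)
        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )
        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )
        return self._make(self.data / other.data, (self, other), backward)

    def __pow__(self, p: float):
        def backward(g):
            return (g * p * self.data ** (p - 1),)
        return self._make(self.data**p, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        def backward(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            return _unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape)
        return self._make(self.data @ other.data, (self, other), backward)

    # -- reductions & shaping -------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            ax = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, ax)
            return (np.broadcast_to(g, self.shape).copy(),)
        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        def backward(g):
            return (g.reshape(self.shape),)
        return self._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        def backward(g):
            return (g.transpose(inv),)
        return self._make(self.data.transpose(axes), (self,), backward)

    # -- nonlinearities -------------------------------------------------------
    def relu(self):
        mask = self.data > 0
        return self._make(self.data * mask, (self,), lambda g: (g * mask,))

    def silu(self):
        sig = 1.0 / (1.0 + np.exp(-self.data))
        out = self.data * sig
        def backward(g):
            return (g * (sig + out * (1.0 - sig)),)
        return self._make(out, (self,), backward)

    def exp(self):
        out = np.exp(self.data)
        return self._make(out, (self,), lambda g: (g * out,))

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        def backward(g):
            return (s * (g - (g * s).sum(axis=axis, keepdims=True)),)
        return self._make(s, (self,), backward)

    # -- backprop -------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient needs a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: the tape can exceed recursion depth
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, pg in zip(node._parents, node._backward(node.grad)):
                if not parent.requires_grad or pg is None:
                    continue
                if parent.grad is None:
                    parent.grad = pg
                else:
                    parent.grad = parent.grad + pg

    def zero_grad(self) -> None:
        self.grad = None

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    """Concatenate along ``axis``; backward splits the gradient."""
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    def backward(g):
        return tuple(
            np.take(g, np.arange(offsets[i], offsets[i + 1]), axis=axis)
            for i in range(len(tensors))
        )
    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward
    )


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (n, c, ho, wo, kh, kw)
    ho, wo = win.shape[2], win.shape[3]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
    return np.ascontiguousarray(cols), ho, wo


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int = 1) -> Tensor:
    """2-D convolution, NCHW layout, weight shape (Cout, Cin, kh, kw)."""
    n, cin, h, hw = x.shape
    cout, cin_w, kh, kw = w.shape
    if cin != cin_w:
        raise ValueError(f"conv2d channel mismatch: input {cin}, weight {cin_w}")
    cols, ho, wo = _im2col(x.data, kh, kw, stride, pad)
    wmat = w.data.reshape(cout, cin * kh * kw)
    out = cols @ wmat.T
    if b is not None:
        out = out + b.data
    out = out.reshape(n, ho, wo, cout).transpose(0, 3, 1, 2)

    def backward(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, cout)
        gw = (gmat.T @ cols).reshape(w.shape)
        gcols = gmat @ wmat  # (n*ho*wo, cin*kh*kw)
        gcols = gcols.reshape(n, ho, wo, cin, kh, kw).transpose(0, 3, 1, 2, 4, 5)
        hp, wp = h + 2 * pad, hw + 2 * pad
        gx = np.zeros((n, cin, hp, wp))
        for i in range(kh):  # scatter-add each kernel offset back onto the image
            for j in range(kw):
                gx[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += (
                    gcols[:, :, :, :, i, j]
                )
        gx = gx[:, :, pad : pad + h, pad : pad + hw] if pad else gx
        if b is not None:
            return gx, gw, gmat.sum(axis=0)
        return gx, gw

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out, parents, backward)


def upsample_nearest(x: Tensor, factor: int = 2) -> Tensor:
    """Nearest-neighbor spatial upsampling for NCHW tensors."""
    out = x.data.repeat(factor, axis=2).repeat(factor, axis=3)
    n, c, h, w = x.shape
    def backward(g):
        return (
            g.reshape(n, c, h, factor, w, factor).sum(axis=(3, 5)),
        )
    return Tensor._make(out, (x,), backward)
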