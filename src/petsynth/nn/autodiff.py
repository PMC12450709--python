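"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is the numerical core behind the 3-D encoder-decoder network: a small
set of differentiable tensor operations (broadcast-aware arithmetic, matmul,
reductions, reshapes, sigmoid/exp/log, concatenation) plus two convolution
primitives (strided grouped 3-D convolution and transposed 3-D convolution)
with hand-derived backward passes. Everything is float32.

The convolution primitives avoid materializing im2col patch matrices: both
forward and backward loop over the k^3 kernel offsets and perform one
channel-mixing einsum per offset on strided views, which keeps peak memory
proportional to the activations rather than activations x kernel volume.
"""
from __future__ import annotations

import contextlib
from itertools import product
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = ["Tensor", "no_grad", "is_grad_enabled", "concat", "conv3d", "conv_transpose3d"]

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


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a gradient over axes that were broadcast in the forward pass."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple["Tensor", ...] = ()

    # -- construction of graph nodes -------------------------------------
    @staticmethod
    def _result(data: np.ndarray, parents: Sequence["Tensor"], backward) -> "Tensor":
        track = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=track)
        if track:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float32, copy=True)
        else:
            self.grad += grad

    # -- basic protocol ---------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -------------------------------------------------------
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))

    def __add__(self, other):
        other = Tensor._wrap(other)
        out_data = self.data + other.data

        def backward(grad):
            self._accum(_unbroadcast(grad, self.data.shape))
            other._accum(_unbroadcast(grad, other.data.shape))

        return Tensor._result(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(grad):
            self._accum(-grad)

        return Tensor._result(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __mul__(self, other):
        other = Tensor._wrap(other)
        out_data = self.data * other.data

        def backward(grad):
            self._accum(_unbroadcast(grad * other.data, self.data.shape))
            other._accum(_unbroadcast(grad * self.data, other.data.shape))

        return Tensor._result(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * Tensor._wrap(other) ** -1.0

    def __rtruediv__(self, other):
        return Tensor._wrap(other) * self**-1.0

    def __pow__(self, exponent: float):
        exponent = float(exponent)
        out_data = self.data**exponent

        def backward(grad):
            self._accum(grad * exponent * self.data ** (exponent - 1.0))

        return Tensor._result(out_data, (self,), backward)

    def __matmul__(self, other):
        other = Tensor._wrap(other)
        out_data = np.matmul(self.data, other.data)

        def backward(grad):
            a, b = self.data, other.data
            ga = np.matmul(grad, np.swapaxes(b, -1, -2))
            gb = np.matmul(np.swapaxes(a, -1, -2), grad)
            self._accum(_unbroadcast(ga, a.shape))
            other._accum(_unbroadcast(gb, b.shape))

        return Tensor._result(out_data, (self, other), backward)

    # -- reductions and shape ops ----------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(grad):
            g = np.asarray(grad)
            if axis is not None and not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                for ax in sorted(a % self.data.ndim for a in axes):
                    g = np.expand_dims(g, ax)
            self._accum(np.broadcast_to(g, self.data.shape))

        return Tensor._result(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            count = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)

        def backward(grad):
            self._accum(grad.reshape(self.data.shape))

        return Tensor._result(out_data, (self,), backward)

    def transpose(self, axes: Sequence[int]):
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))
        out_data = self.data.transpose(axes)

        def backward(grad):
            self._accum(grad.transpose(inv))

        return Tensor._result(out_data, (self,), backward)

    # -- pointwise nonlinearities -----------------------------------------
    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(grad):
            self._accum(grad * out_data * (1.0 - out_data))

        return Tensor._result(out_data, (self,), backward)

    def swish(self):
        """x * sigmoid(x) (a.k.a. SiLU)."""
        sig = 1.0 / (1.0 + np.exp(-self.data))
        out_data = self.data * sig

        def backward(grad):
            self._accum(grad * (sig * (1.0 + self.data * (1.0 - sig))))

        return Tensor._result(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(grad):
            self._accum(grad * out_data)

        return Tensor._result(out_data, (self,), backward)

    def log(self):
        out_data = np.log(self.data)

        def backward(grad):
            self._accum(grad / self.data)

        return Tensor._result(out_data, (self,), backward)

    def sqrt(self):
        return self**0.5

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient is zero outside the interval."""
        out_data = np.clip(self.data, lo, hi)
        inside = ((self.data >= lo) & (self.data <= hi)).astype(np.float32)

        def backward(grad):
            self._accum(grad * inside)

        return Tensor._result(out_data, (self,), backward)

    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        s = e / e.sum(axis=axis, keepdims=True)

        def backward(grad):
            # d softmax: s * (g - sum(g * s))
            dot = (grad * s).sum(axis=axis, keepdims=True)
            self._accum(s * (grad - dot))

        return Tensor._result(s, (self,), backward)

    # -- backprop ----------------------------------------------------------
    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        self._accum(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    """Concatenate tensors along an axis."""
    tensors = [Tensor._wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(grad):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * grad.ndim
            sl[axis] = slice(int(lo), int(hi))
            t._accum(grad[tuple(sl)])

    return Tensor._result(out_data, tensors, backward)


# ---------------------------------------------------------------------------
# Convolution primitives
# ---------------------------------------------------------------------------

def _pad5(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))


def conv3d(
    x: Tensor,
    w: Tensor,
    b: Optional[Tensor] = None,
    stride: int = 1,
    padding: int = 0,
    groups: int = 1,
) -> Tensor:
    """Grouped, strided 3-D convolution (cross-correlation).

    x: (N, Cin, D, H, W); w: (Cout, Cin // groups, kd, kh, kw); b: (Cout,).
    Depthwise convolution is groups == Cin with Cin//groups == 1.
    """
    N, Cin, D, H, W = x.data.shape
    Cout, Cg, kd, kh, kw = w.data.shape
    if Cin % groups or Cout % groups or Cg != Cin // groups:
        raise ValueError("channel counts incompatible with groups")
    s, p = int(stride), int(padding)
    Do = (D + 2 * p - kd) // s + 1
    Ho = (H + 2 * p - kh) // s + 1
    Wo = (W + 2 * p - kw) // s + 1
    Og = Cout // groups

    depthwise = Og == 1 and Cg == 1  # one spatial filter per channel
    xp = _pad5(x.data, p)
    wg = w.data.reshape(groups, Og, Cg, kd, kh, kw)

    def x_slice(i: int, j: int, k: int) -> np.ndarray:
        return xp[:, :, i : i + Do * s : s, j : j + Ho * s : s, k : k + Wo * s : s]

    if depthwise:
        out_data = np.zeros((N, Cout, Do, Ho, Wo), dtype=np.float32)
        for i, j, k in product(range(kd), range(kh), range(kw)):
            out_data += x_slice(i, j, k) * w.data[None, :, 0, i, j, k, None, None, None]
    else:
        out = np.zeros((N, groups, Og, Do, Ho, Wo), dtype=np.float32)
        xg = xp.reshape(N, groups, Cg, *xp.shape[2:])
        for i, j, k in product(range(kd), range(kh), range(kw)):
            xs = xg[:, :, :, i : i + Do * s : s, j : j + Ho * s : s, k : k + Wo * s : s]
            out += np.einsum("ngcxyz,goc->ngoxyz", xs, wg[:, :, :, i, j, k], optimize=True)
        out_data = out.reshape(N, Cout, Do, Ho, Wo)
    if b is not None:
        out_data += b.data.reshape(1, Cout, 1, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def backward(grad):
        if b is not None:
            b._accum(grad.sum(axis=(0, 2, 3, 4)))
        if depthwise:
            if w.requires_grad:
                gw = np.empty_like(w.data)
                for i, j, k in product(range(kd), range(kh), range(kw)):
                    gw[:, 0, i, j, k] = (x_slice(i, j, k) * grad).sum(axis=(0, 2, 3, 4))
                w._accum(gw)
            if x.requires_grad:
                gxp = np.zeros_like(xp)
                for i, j, k in product(range(kd), range(kh), range(kw)):
                    gxp[:, :, i : i + Do * s : s, j : j + Ho * s : s, k : k + Wo * s : s] += (
                        grad * w.data[None, :, 0, i, j, k, None, None, None]
                    )
                if p:
                    gxp = gxp[:, :, p:-p, p:-p, p:-p]
                x._accum(gxp)
            return
        g = grad.reshape(N, groups, Og, Do, Ho, Wo)
        xg = xp.reshape(N, groups, Cg, *xp.shape[2:])
        if w.requires_grad:
            gw = np.empty_like(w.data)
            gwg = gw.reshape(groups, Og, Cg, kd, kh, kw)
            for i, j, k in product(range(kd), range(kh), range(kw)):
                xs = xg[:, :, :, i : i + Do * s : s, j : j + Ho * s : s, k : k + Wo * s : s]
                gwg[:, :, :, i, j, k] = np.einsum("ngcxyz,ngoxyz->goc", xs, g, optimize=True)
            w._accum(gw)
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            gxg = gxp.reshape(N, groups, Cg, *xp.shape[2:])
            for i, j, k in product(range(kd), range(kh), range(kw)):
                gxg[:, :, :, i : i + Do * s : s, j : j + Ho * s : s, k : k + Wo * s : s] += (
                    np.einsum("ngoxyz,goc->ngcxyz", g, wg[:, :, :, i, j, k], optimize=True)
                )
            if p:
                gxp = gxp[:, :, p:-p, p:-p, p:-p]
            x._accum(gxp)

    return Tensor._result(out_data, parents, backward)


def conv_transpose3d(
    x: Tensor,
    w: Tensor,
    b: Optional[Tensor] = None,
    stride: int = 2,
    padding: int = 1,
) -> Tensor:
    """Transposed 3-D convolution (fractionally strided upsampling).

    x: (N, Cin, D, H, W); w: (Cin, Cout, kd, kh, kw); b: (Cout,).
    Output extent per axis: (D - 1) * stride - 2 * padding + kernel.
    """
    N, Cin, D, H, W = x.data.shape
    Ci2, Cout, kd, kh, kw = w.data.shape
    if Ci2 != Cin:
        raise ValueError("weight input channels do not match input")
    s, p = int(stride), int(padding)
    Do = (D - 1) * s - 2 * p + kd
    Ho = (H - 1) * s - 2 * p + kh
    Wo = (W - 1) * s - 2 * p + kw

    full = np.zeros((N, Cout, Do + 2 * p, Ho + 2 * p, Wo + 2 * p), dtype=np.float32)
    for i, j, k in product(range(kd), range(kh), range(kw)):
        full[:, :, i : i + D * s : s, j : j + H * s : s, k : k + W * s : s] += np.einsum(
            "ncxyz,co->noxyz", x.data, w.data[:, :, i, j, k], optimize=True
        )
    out_data = full[:, :, p : p + Do, p : p + Ho, p : p + Wo]
    out_data = np.ascontiguousarray(out_data)
    if b is not None:
        out_data = out_data + b.data.reshape(1, Cout, 1, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def backward(grad):
        if b is not None:
            b._accum(grad.sum(axis=(0, 2, 3, 4)))
        gfull = _pad5(grad, p)
        if w.requires_grad:
            gw = np.empty_like(w.data)
            for i, j, k in product(range(kd), range(kh), range(kw)):
                gs = gfull[:, :, i : i + D * s : s, j : j + H * s : s, k : k + W * s : s]
                gw[:, :, i, j, k] = np.einsum("ncxyz,noxyz->co", x.data, gs, optimize=True)
            w._accum(gw)
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            for i, j, k in product(range(kd), range(kh), range(kw)):
                gs = gfull[:, :, i : i + D * s : s, j : j + H * s : s, k : k + W * s : s]
                gx += np.einsum("noxyz,co->ncxyz", gs, w.data[:, :, i, j, k], optimize=True)
            x._accum(gx)

    return Tensor._result(out_data, parents, backward)
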