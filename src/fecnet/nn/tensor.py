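"""Reverse-mode automatic differentiation on NumPy arrays.

A deliberately small define-by-run engine: each op builds a node holding a
closure that maps the output gradient to parent gradients.  Gradients are
accumulated on every node (not only leaves), which is what makes activation
gradients available for class-activation mapping without a hook system.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "conv2d",
    "maxpool2d",
    "stack",
]

_DT = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(
        i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1
    )
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """N-d array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=_DT)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            # always copy: closures may hand over views or shared buffers
            self.grad = g.astype(_DT) if g.dtype != _DT else g.copy()
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Back-propagate from this tensor through the recorded graph."""
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        # iterative DFS; recursion depth would blow up on deep networks
        while stack:
            node = stack.pop()
            if id(node) in seen:
                continue
            pending = [p for p in node._parents if id(p) not in seen]
            if pending:
                stack.append(node)
                stack.extend(pending)
            else:
                seen.add(id(node))
                topo.append(node)
        self._accumulate(np.asarray(grad, dtype=_DT))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        out = _node(self.data + other.data, (self, other))

        def bw(g):
            self._accumulate(_unbroadcast(g, self.shape))
            other._accumulate(_unbroadcast(g, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _node(-self.data, (self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = _node(self.data * other.data, (self, other))

        def bw(g):
            self._accumulate(_unbroadcast(g * other.data, self.shape))
            other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = _node(self.data / other.data, (self, other))

        def bw(g):
            self._accumulate(_unbroadcast(g / other.data, self.shape))
            other._accumulate(
                _unbroadcast(-g * self.data / (other.data**2), other.shape)
            )

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out = _node(self.data**p, (self,))
        out._backward = lambda g: self._accumulate(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = _node(self.data @ other.data, (self, other))

        def bw(g):
            a, b = self.data, other.data
            if a.ndim == 1:
                a = a[None, :]
            if b.ndim == 1:
                ga = np.outer(g, b) if self.data.ndim > 1 else g * b
                gb = a.T @ g if g.ndim else a.ravel() * g
                self._accumulate(_unbroadcast(np.asarray(ga), self.shape))
                other._accumulate(_unbroadcast(np.asarray(gb), other.shape))
                return
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            self._accumulate(_unbroadcast(ga, self.shape))
            other._accumulate(_unbroadcast(gb, other.shape))

        out._backward = bw
        return out

    # ------------------------------------------------------------- elementwise
    def exp(self):
        out = _node(np.exp(self.data), (self,))
        out._backward = lambda g: self._accumulate(g * out.data)
        return out

    def log(self):
        out = _node(np.log(self.data), (self,))
        out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def relu(self):
        mask = self.data > 0
        out = _node(self.data * mask, (self,))
        out._backward = lambda g: self._accumulate(g * mask)
        return out

    def sigmoid(self):
        with np.errstate(over="ignore"):
            s = 1.0 / (1.0 + np.exp(-self.data))
        out = _node(s, (self,))
        out._backward = lambda g: self._accumulate(g * out.data * (1.0 - out.data))
        return out

    def sqrt(self):
        return self**0.5

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = _node(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bw(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).astype(_DT))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).astype(_DT))

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ------------------------------------------------------------------ shape
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = _node(self.data.reshape(shape), (self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.shape))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = _node(self.data.transpose(axes), (self,))
        out._backward = lambda g: self._accumulate(g.transpose(inv))
        return out

    def narrow(self, axis: int, start: int, length: int):
        """Contiguous slice ``[start, start+length)`` along ``axis``."""
        idx = [slice(None)] * self.ndim
        idx[axis] = slice(start, start + length)
        idx = tuple(idx)
        out = _node(self.data[idx], (self,))

        def bw(g):
            full = np.zeros(self.shape, dtype=_DT)
            full[idx] = g
            self._accumulate(full)

        out._backward = bw
        return out

    def split(self, sections: int, axis: int) -> list["Tensor"]:
        if self.shape[axis] % sections:
            raise ValueError("axis not divisible into equal sections")
        step = self.shape[axis] // sections
        return [self.narrow(axis, i * step, step) for i in range(sections)]

    # ------------------------------------------------------- composite helpers
    def softmax(self, axis: int):
        z = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = z.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def log_softmax(self, axis: int):
        z = self - Tensor(self.data.max(axis=axis, keepdims=True))
        return z - z.exp().sum(axis=axis, keepdims=True).log()


def _node(data: np.ndarray, parents: Sequence[Tensor]) -> Tensor:
    out = Tensor(data)
    out._parents = tuple(parents)
    out.requires_grad = any(p.requires_grad for p in parents)
    return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Sequence[Tensor], axis: int) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = _node(np.concatenate([t.data for t in tensors], axis=axis), tensors)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.concatenate([[0], np.cumsum(sizes)])

    def bw(g):
        for t, o, s in zip(tensors, offsets, sizes):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(int(o), int(o + s))
            t._accumulate(g[tuple(idx)])

    out._backward = bw
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    expanded = []
    for t in tensors:
        shape = list(t.shape)
        shape.insert(axis, 1)
        expanded.append(t.reshape(*shape))
    return concat(expanded, axis=axis)


# --------------------------------------------------------------- convolutions
def _pair(v) -> tuple[int, int]:
    return (v, v) if isinstance(v, int) else tuple(v)


def conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None = None,
    stride=1,
    padding=0,
    groups: int = 1,
) -> Tensor:
    """2-d cross-correlation, NCHW layout, grouped.

    ``weight`` has shape (N, C/groups, kh, kw).  Implemented as im2col plus a
    per-group matmul; the backward pass scatters column gradients back with a
    kh*kw loop (cheap: kernel area iterations over contiguous strided views).
    """
    sh, sw = _pair(stride)
    ph, pw = _pair(padding)
    B, C, H, W = x.shape
    N, Cg, kh, kw = weight.shape
    g = groups
    if C != Cg * g or N % g:
        raise ValueError("channel/group mismatch")
    Ng = N // g
    xp = (
        np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
        if (ph or pw)
        else x.data
    )
    Ho = (H + 2 * ph - kh) // sh + 1
    Wo = (W + 2 * pw - kw) // sw + 1

    if g == C and Cg == 1 and Ng == 1:
        return _conv2d_depthwise(x, weight, bias, xp, (sh, sw), (ph, pw), Ho, Wo)
    if kh == 1 and kw == 1:
        return _conv2d_pointwise(x, weight, bias, xp, (sh, sw), (ph, pw), Ho, Wo, g)

    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::sh, ::sw]  # (B, C, Ho, Wo, kh, kw)
    cols = (
        win.reshape(B, g, Cg, Ho * Wo, kh * kw)
        .transpose(1, 0, 3, 2, 4)
        .reshape(g, B * Ho * Wo, Cg * kh * kw)
    )
    wmat = weight.data.reshape(g, Ng, Cg * kh * kw)
    y = cols @ wmat.transpose(0, 2, 1)  # (g, B*Ho*Wo, Ng)
    y = (
        y.reshape(g, B, Ho * Wo, Ng)
        .transpose(1, 0, 3, 2)
        .reshape(B, N, Ho, Wo)
    )
    if bias is not None:
        y = y + bias.data.reshape(1, N, 1, 1)
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = _node(y, parents)

    def bw(gout):
        go = (
            gout.reshape(B, g, Ng, Ho * Wo)
            .transpose(1, 0, 3, 2)
            .reshape(g, B * Ho * Wo, Ng)
        )
        if weight.requires_grad or weight._parents:
            gw = np.swapaxes(go, 1, 2) @ cols  # (g, Ng, Cg*kh*kw)
            weight._accumulate(gw.reshape(weight.shape))
        if bias is not None:
            bias._accumulate(gout.sum(axis=(0, 2, 3)))
        gcols = go @ wmat  # (g, B*Ho*Wo, Cg*kh*kw)
        gcols = (
            gcols.reshape(g, B, Ho * Wo, Cg, kh * kw)
            .transpose(1, 0, 3, 2, 4)
            .reshape(B, C, Ho, Wo, kh, kw)
        )
        gxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                gxp[:, :, i : i + Ho * sh : sh, j : j + Wo * sw : sw] += gcols[
                    :, :, :, :, i, j
                ]
        if ph or pw:
            gxp = gxp[:, :, ph : ph + H, pw : pw + W]
        x._accumulate(gxp)

    out._backward = bw
    return out


def _conv2d_depthwise(x, weight, bias, xp, stride, pad, Ho, Wo):
    """Per-channel convolution via kernel-position accumulation (no im2col)."""
    sh, sw = stride
    ph, pw = pad
    B, C, H, W = x.shape
    _, _, kh, kw = weight.shape
    w = weight.data  # (C, 1, kh, kw)
    y = np.zeros((B, C, Ho, Wo), dtype=_DT)
    for i in range(kh):
        for j in range(kw):
            y += w[:, 0, i, j][None, :, None, None] * xp[
                :, :, i : i + Ho * sh : sh, j : j + Wo * sw : sw
            ]
    if bias is not None:
        y += bias.data.reshape(1, C, 1, 1)
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = _node(y, parents)

    def bw(gout):
        gw = np.empty_like(w)
        gxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                sl = xp[:, :, i : i + Ho * sh : sh, j : j + Wo * sw : sw]
                gw[:, 0, i, j] = (gout * sl).sum(axis=(0, 2, 3))
                gxp[:, :, i : i + Ho * sh : sh, j : j + Wo * sw : sw] += (
                    w[:, 0, i, j][None, :, None, None] * gout
                )
        weight._accumulate(gw)
        if bias is not None:
            bias._accumulate(gout.sum(axis=(0, 2, 3)))
        if ph or pw:
            gxp = gxp[:, :, ph : ph + H, pw : pw + W]
        x._accumulate(gxp)

    out._backward = bw
    return out


def _conv2d_pointwise(x, weight, bias, xp, stride, pad, Ho, Wo, g):
    """1×1 (grouped) convolution as a batched channel matmul."""
    sh, sw = stride
    B, C, H, W = x.shape
    N = weight.shape[0]
    Cg, Ng = C // g, N // g
    xs = xp[:, :, ::sh, ::sw]
    L = Ho * Wo
    x2 = np.ascontiguousarray(xs).reshape(B, g, Cg, L)
    w2 = weight.data.reshape(g, Ng, Cg)
    y = np.matmul(w2[None], x2)  # (B, g, Ng, L)
    y = y.reshape(B, N, Ho, Wo)
    if bias is not None:
        y += bias.data.reshape(1, N, 1, 1)
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = _node(y, parents)

    def bw(gout):
        go = gout.reshape(B, g, Ng, L)
        gw = np.einsum("bgnl,bgcl->gnc", go, x2, optimize=True)
        weight._accumulate(gw.reshape(weight.shape))
        if bias is not None:
            bias._accumulate(gout.sum(axis=(0, 2, 3)))
        gx2 = np.matmul(np.swapaxes(w2, 1, 2)[None], go)  # (B, g, Cg, L)
        gxs = gx2.reshape(B, C, Ho, Wo)
        if sh == 1 and sw == 1:
            gx = gxs
        else:
            gx = np.zeros((B, C, xp.shape[2], xp.shape[3]), dtype=_DT)
            gx[:, :, ::sh, ::sw] = gxs
        ph, pw = pad
        if ph or pw:
            gx = gx[:, :, ph : ph + H, pw : pw + W]
        x._accumulate(gx)

    out._backward = bw
    return out


def maxpool2d(x: Tensor, kernel: int = 3, stride: int = 2, padding: int = 1) -> Tensor:
    """Max pooling, NCHW; padded entries are -inf so they never win."""
    kh, kw = _pair(kernel)
    sh, sw = _pair(stride)
    ph, pw = _pair(padding)
    B, C, H, W = x.shape
    xp = np.pad(
        x.data,
        ((0, 0), (0, 0), (ph, ph), (pw, pw)),
        constant_values=-np.inf,
    )
    Ho = (H + 2 * ph - kh) // sh + 1
    Wo = (W + 2 * pw - kw) // sw + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::sh, ::sw].reshape(B, C, Ho, Wo, kh * kw)
    arg = win.argmax(axis=-1)
    y = np.take_along_axis(win, arg[..., None], axis=-1)[..., 0]
    out = _node(y, (x,))

    def bw(g):
        gxp = np.zeros_like(xp)
        for t in range(kh * kw):
            i, j = divmod(t, kw)
            mask = (arg == t) * g
            gxp[:, :, i : i + Ho * sh : sh, j : j + Wo * sw : sw] += mask
        gxp = gxp[:, :, ph : ph + H, pw : pw + W]
        x._accumulate(gxp)

    out._backward = bw
    return out
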