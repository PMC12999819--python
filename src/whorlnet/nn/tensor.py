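"""Reverse-mode autodiff over numpy arrays.

A deliberately small engine: float32 tensors, a handful of fused ops
(convolution, batch/layer norm, softmax, nearest upsampling) chosen to cover
an anchor-free convolutional detector, and a global MAC counter used by the
complexity audit. Multiply-accumulate counts follow the usual profiler
convention: convolutions and matrix products count, normalization (folded at
inference) and element-wise ops do not.
"""
from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np
from scipy.special import erf

_MAC_COUNTER: list[int] | None = None


@contextlib.contextmanager
def count_macs_ctx():
    """Context manager that accumulates MACs of every op run inside it."""
    global _MAC_COUNTER
    prev = _MAC_COUNTER
    _MAC_COUNTER = [0]
    try:
        yield _MAC_COUNTER
    finally:
        _MAC_COUNTER = prev


def _add_macs(n: int) -> None:
    if _MAC_COUNTER is not None:
        _MAC_COUNTER[0] += int(n)


def _as_array(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x.astype(np.float32, copy=False)
    return np.asarray(x, dtype=np.float32)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph bookkeeping ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
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
        self._accum(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    # -- helpers ----------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return self._make(data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        inv = 1.0 / other.data
        data = self.data * inv

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * inv, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data * inv * inv, other.data.shape))

        return self._make(data, (self, other), backward)

    def __pow__(self, p: float):
        data = self.data ** p

        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return self._make(data, (self,), backward)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)
        data = np.matmul(self.data, other.data)
        _add_macs(data.size * self.data.shape[-1])

        def backward(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.data.shape))

        return self._make(data, (self, other), backward)

    __matmul__ = matmul

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        data = self.data.reshape(shape)

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        return self._make(data, (self,), backward)

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        data = self.data.transpose(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return self._make(data, (self,), backward)

    def __getitem__(self, idx) -> "Tensor":
        data = self.data[idx]

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        return self._make(data, (self,), backward)

    # -- reductions ---------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return self._make(data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities -----------------------------------------------------
    def relu(self) -> "Tensor":
        mask = self.data > 0
        data = self.data * mask

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return self._make(data, (self,), backward)

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accum(g * s * (1.0 - s))

        return self._make(s, (self,), backward)

    def silu(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        data = self.data * s

        def backward(g):
            if self.requires_grad:
                self._accum(g * (s + self.data * s * (1.0 - s)))

        return self._make(data, (self,), backward)

    def gelu(self) -> "Tensor":
        x = self.data
        cdf = 0.5 * (1.0 + erf(x / np.sqrt(2.0, dtype=np.float32)))

        def backward(g):
            if self.requires_grad:
                pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
                self._accum((g * (cdf + x * pdf)).astype(np.float32))

        return self._make((x * cdf).astype(np.float32), (self,), backward)

    def atan(self) -> "Tensor":
        data = np.arctan(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g / (1.0 + self.data * self.data))

        return self._make(data, (self,), backward)

    def exp(self) -> "Tensor":
        data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * data)

        return self._make(data, (self,), backward)

    def log(self) -> "Tensor":
        data = np.log(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return self._make(data, (self,), backward)

    def softmax(self, axis: int = -1) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            if self.requires_grad:
                dot = (g * s).sum(axis=axis, keepdims=True)
                self._accum(s * (g - dot))

        return self._make(s, (self,), backward)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient g down to `shape` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# fused functional ops
# ---------------------------------------------------------------------------

def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accum(p)

    out = Tensor(data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = backward
    return out


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0, groups: int = 1) -> Tensor:
    """2-D cross-correlation, NCHW, grouped. Shift-accumulation algorithm:
    one channel-contraction per kernel tap, vectorized over the map."""
    b, cin, h, w = x.data.shape
    cout, cin_g, kh, kw = weight.data.shape
    if cin != cin_g * groups:
        raise ValueError(f"conv2d: input channels {cin} != {cin_g}*{groups}")
    oh = (h + 2 * padding - kh) // stride + 1
    ow = (w + 2 * padding - kw) // stride + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) \
        if padding else x.data
    og = cout // groups
    xg = xp.reshape(b, groups, cin_g, *xp.shape[2:])
    wg = weight.data.reshape(groups, og, cin_g, kh, kw)
    out = np.zeros((b, groups, og, oh, ow), dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            patch = xg[:, :, :, i:i + stride * oh:stride, j:j + stride * ow:stride]
            out += np.einsum("bgchw,goc->bgohw", patch, wg[:, :, :, i, j],
                             optimize=True)
    out = out.reshape(b, cout, oh, ow)
    _add_macs(b * cout * oh * ow * cin_g * kh * kw)
    if bias is not None:
        out += bias.data.reshape(1, cout, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        g5 = g.reshape(b, groups, og, oh, ow)
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            dxg = dxp.reshape(b, groups, cin_g, *xp.shape[2:])
            for i in range(kh):
                for j in range(kw):
                    dxg[:, :, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += \
                        np.einsum("bgohw,goc->bgchw", g5, wg[:, :, :, i, j],
                                  optimize=True)
            if padding:
                dxp = dxp[:, :, padding:padding + h, padding:padding + w]
            x._accum(dxp.reshape(b, cin, h, w))
        if weight.requires_grad:
            dw = np.zeros_like(wg)
            for i in range(kh):
                for j in range(kw):
                    patch = xg[:, :, :, i:i + stride * oh:stride, j:j + stride * ow:stride]
                    dw[:, :, :, i, j] = np.einsum("bgohw,bgchw->goc", g5, patch,
                                                  optimize=True)
            weight._accum(dw.reshape(cout, cin_g, kh, kw))
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))

    res = Tensor(out)
    if any(p.requires_grad for p in parents):
        res.requires_grad = True
        res._parents = parents
        res._backward = backward
    return res


def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                 running_mean: np.ndarray, running_var: np.ndarray,
                 training: bool, momentum: float = 0.03, eps: float = 1e-3) -> Tensor:
    """Batch normalization over (B, H, W) per channel; updates running stats
    in place in training mode."""
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= (1 - momentum)
        running_mean += momentum * mean
        running_var *= (1 - momentum)
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean.reshape(1, -1, 1, 1)) * inv.reshape(1, -1, 1, 1)
    out = gamma.data.reshape(1, -1, 1, 1) * xhat + beta.data.reshape(1, -1, 1, 1)

    def backward(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gi = gamma.data.reshape(1, -1, 1, 1) * inv.reshape(1, -1, 1, 1)
            if training:
                n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
                gsum = g.sum(axis=(0, 2, 3), keepdims=True)
                gxsum = (g * xhat).sum(axis=(0, 2, 3), keepdims=True)
                gx = gi * (g - gsum.reshape(1, -1, 1, 1) / n
                           - xhat * gxsum.reshape(1, -1, 1, 1) / n)
            else:
                gx = gi * g
            x._accum(gx.astype(np.float32))

    res = Tensor(out.astype(np.float32))
    if x.requires_grad or gamma.requires_grad or beta.requires_grad:
        res.requires_grad = True
        res._parents = (x, gamma, beta)
        res._backward = backward
    return res


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis."""
    mean = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean) * inv
    out = gamma.data * xhat + beta.data

    def backward(g):
        if gamma.requires_grad:
            red = tuple(range(g.ndim - 1))
            gamma._accum((g * xhat).sum(axis=red))
        if beta.requires_grad:
            red = tuple(range(g.ndim - 1))
            beta._accum(g.sum(axis=red))
        if x.requires_grad:
            n = x.data.shape[-1]
            gh = g * gamma.data
            gx = inv * (gh - gh.mean(axis=-1, keepdims=True)
                        - xhat * (gh * xhat).mean(axis=-1, keepdims=True))
            x._accum(gx.astype(np.float32))

    res = Tensor(out.astype(np.float32))
    if any(t.requires_grad for t in (x, gamma, beta)):
        res.requires_grad = True
        res._parents = (x, gamma, beta)
        res._backward = backward
    return res


def upsample_nearest2x(x: Tensor) -> Tensor:
    data = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        if x.requires_grad:
            b, c, h2, w2 = g.shape
            gg = g.reshape(b, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))
            x._accum(gg)

    return x._make(data, (x,), backward)


def stack_params(values: Iterable[float]) -> np.ndarray:
    return np.asarray(list(values), dtype=np.float32)
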