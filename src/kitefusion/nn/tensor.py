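"""Minimal reverse-mode autodiff on NumPy arrays.

The engine supports exactly the operator set the segmentation/classification
models need: broadcast arithmetic, reductions, matmul, 2-D convolution
(im2col), separable bilinear/nearest resize, channel concatenation, softmax
and clamped log.  Gradients are accumulated into ``Tensor.grad`` by
``Tensor.backward()`` over a topologically sorted graph.

Float32 is the working precision for model parameters; the graph preserves
the dtype of its inputs, so float64 inputs give float64 gradients (used by
the loss-function oracle tests).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

__all__ = ["Tensor", "concat", "interp_matrix", "batch_norm"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (the inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(np.float32)
        self.data = arr
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def _make(self, data, prev, backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in prev)
        if out.requires_grad:
            out._prev = tuple(prev)
            out._backward = backward
        return out

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return self._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) / self

    def pow(self, p: float):
        out_data = self.data**p

        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return self._make(out_data, (self,), backward)

    def sqrt(self):
        return self.pow(0.5)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return self._make(out_data, (self,), backward)

    def clamp_min(self, lo: float):
        mask = self.data >= lo

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return self._make(np.maximum(self.data, lo), (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return self._make(self.data * mask, (self,), backward)

    # -- reductions / shaping -------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            gg = g
            if not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                for ax in sorted(a % self.data.ndim for a in axes):
                    gg = np.expand_dims(gg, ax)
            self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        return self._make(out_data, (self,), backward)

    def transpose(self, axes):
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), backward)

    def matmul(self, other: "Tensor"):
        other = Tensor.as_tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return self._make(out_data, (self, other), backward)

    # -- neural-net primitives ------------------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor", stride: int = 1, pad: int = 1):
        """2-D convolution, NCHW layout, square kernel.

        Computed as one GEMM per kernel tap on shifted views of the padded
        input (kh*kw small GEMMs), which avoids materializing the kh*kw-fold
        im2col copy; the padded input is cached for the backward pass.
        """
        x, w = self.data, weight.data
        n, c, h, wid = x.shape
        o, c2, kh, kw = w.shape
        if c != c2:
            raise ValueError(f"conv2d channel mismatch: input {c}, weight {c2}")
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
        oh = (h + 2 * pad - kh) // stride + 1
        ow = (wid + 2 * pad - kw) // stride + 1

        def tap(ki, kj):
            """(N, C, OH*OW) contiguous slice of the padded input."""
            s = xp[:, :, ki : ki + stride * oh : stride, kj : kj + stride * ow : stride]
            return np.ascontiguousarray(s).reshape(n, c, oh * ow)

        out = np.zeros((n, o, oh * ow), dtype=x.dtype)
        for ki in range(kh):
            for kj in range(kw):
                out += np.matmul(w[:, :, ki, kj], tap(ki, kj))
        out = out.reshape(n, o, oh, ow)
        if bias is not None:
            out = out + bias.data.reshape(1, o, 1, 1)

        def backward(g):
            g2 = g.reshape(n, o, oh * ow)
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3)))
            dxp = np.zeros_like(xp) if self.requires_grad else None
            for ki in range(kh):
                for kj in range(kw):
                    if weight.requires_grad:
                        t = tap(ki, kj)
                        weight.grad = (
                            np.zeros_like(w) if weight.grad is None else weight.grad
                        )
                        weight.grad[:, :, ki, kj] += np.einsum(
                            "nop,ncp->oc", g2, t, optimize=True
                        )
                    if dxp is not None:
                        ds = np.matmul(w[:, :, ki, kj].T, g2).reshape(n, c, oh, ow)
                        dxp[
                            :,
                            :,
                            ki : ki + stride * oh : stride,
                            kj : kj + stride * ow : stride,
                        ] += ds
            if dxp is not None:
                if pad:
                    dxp = dxp[:, :, pad:-pad, pad:-pad]
                self._accum(dxp)

        prev = [self, weight] + ([bias] if bias is not None else [])
        return self._make(out, prev, backward)

    def resize(self, out_hw: tuple, mode: str = "bilinear"):
        """Spatial resize of an NCHW tensor via separable interpolation matrices."""
        oh, ow = out_hw
        n, c, h, w = self.data.shape
        if (oh, ow) == (h, w):
            return self
        dt = self.data.dtype
        a = interp_matrix(oh, h, mode).astype(dt)  # (oh, h)
        b = interp_matrix(ow, w, mode).astype(dt)  # (ow, w)
        out = np.matmul(np.matmul(a, self.data), b.T)

        def backward(g):
            if self.requires_grad:
                self._accum(np.matmul(np.matmul(a.T, g), b))

        return self._make(out, (self,), backward)

    def softmax(self, axis: int = 1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        out = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            if self.requires_grad:
                inner = (g * out).sum(axis=axis, keepdims=True)
                self._accum(out * (g - inner))

        return self._make(out, (self,), backward)

    # -- graph execution ------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo, seen = [], set()
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
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def item(self) -> float:
        return float(self.data)


def concat(tensors, axis: int = 1) -> Tensor:
    """Concatenate tensors along `axis` (used for skip connections / fusion)."""
    tensors = [Tensor.as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accum(p)

    out = Tensor(out_data)
    out.requires_grad = any(t.requires_grad for t in tensors)
    if out.requires_grad:
        out._prev = tuple(tensors)
        out._backward = backward
    return out


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5):
    """Batch normalization over (N, H, W) per channel, as a fused primitive.

    Returns (normalized Tensor, batch_mean, batch_var); the statistics are
    plain arrays for the caller's running-average bookkeeping.
    """
    xd = x.data
    mu = xd.mean(axis=(0, 2, 3))
    var = xd.var(axis=(0, 2, 3))
    inv = (1.0 / np.sqrt(var + eps)).astype(xd.dtype)
    xhat = (xd - mu.reshape(1, -1, 1, 1).astype(xd.dtype)) * inv.reshape(1, -1, 1, 1)
    out_data = gamma.data.reshape(1, -1, 1, 1) * xhat + beta.data.reshape(1, -1, 1, 1)

    def backward(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gh = g * gamma.data.reshape(1, -1, 1, 1)
            m1 = gh.mean(axis=(0, 2, 3), keepdims=True)
            m2 = (gh * xhat).mean(axis=(0, 2, 3), keepdims=True)
            x._accum(inv.reshape(1, -1, 1, 1) * (gh - m1 - xhat * m2))

    out = Tensor(out_data)
    out.requires_grad = x.requires_grad or gamma.requires_grad or beta.requires_grad
    if out.requires_grad:
        out._prev = (x, gamma, beta)
        out._backward = backward
    return out, mu, var


@lru_cache(maxsize=256)
def interp_matrix(out_n: int, in_n: int, mode: str = "bilinear") -> np.ndarray:
    """1-D resize operator as a dense (out_n, in_n) matrix.

    Uses the half-pixel-center convention: src = (i + 0.5) * in/out - 0.5,
    clipped to the valid range, so up- and down-sampling are both handled.
    """
    m = np.zeros((out_n, in_n), dtype=np.float64)
    src = (np.arange(out_n) + 0.5) * (in_n / out_n) - 0.5
    src = np.clip(src, 0.0, in_n - 1.0)
    if mode == "nearest":
        idx = np.clip(np.floor(src + 0.5).astype(int), 0, in_n - 1)
        m[np.arange(out_n), idx] = 1.0
    elif mode == "bilinear":
        lo = np.floor(src).astype(int)
        hi = np.minimum(lo + 1, in_n - 1)
        frac = src - lo
        m[np.arange(out_n), lo] += 1.0 - frac
        m[np.arange(out_n), hi] += frac
    else:
        raise ValueError(f"unknown resize mode {mode!r}")
    return m
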