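"""Reverse-mode automatic differentiation over numpy arrays.

A small tape-based engine providing exactly the operations the
segmentation network needs: stride-1 (dilated) 2-D convolution, 2x2 max
pooling, bilinear resampling, batch normalization, channel/spatial
pooling reductions, pointwise nonlinearities and arithmetic.  Tensors
wrap float32 numpy arrays; calling :meth:`Tensor.backward` on a scalar
result accumulates gradients into every upstream tensor created with
``requires_grad=True``.

The engine is intentionally minimal: stride is always 1 (the network
resamples explicitly with pooling/interpolation), convolutions use
same-padding, and there is no graph retention across backward calls.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "as_tensor",
    "no_grad",
    "concat",
    "conv2d",
    "max_pool2x2",
    "upsample_bilinear",
    "batch_norm",
    "relu",
    "sigmoid",
    "log",
    "clamp",
    "channel_mean",
    "channel_max",
    "spatial_mean",
    "spatial_max",
]

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the block (inference mode)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


class Tensor:
    """A numpy array plus the bookkeeping for reverse-mode autodiff."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _grad_enabled
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    # -- graph plumbing -------------------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        return _binary(self, other, np.add, _add_back)

    __radd__ = __add__

    def __mul__(self, other):
        return _binary(self, other, np.multiply, _mul_back)

    __rmul__ = __mul__

    def __sub__(self, other):
        return self + (-1.0) * as_tensor(other)

    def __rsub__(self, other):
        return as_tensor(other) + (-1.0) * self

    def __truediv__(self, other):
        other = as_tensor(other)
        return self * _reciprocal(other)

    def __neg__(self):
        return (-1.0) * self

    def sum(self) -> "Tensor":
        out = _make(np.sum(self.data, keepdims=False), (self,))
        if out.requires_grad:
            shape = self.data.shape

            def back(g, self=self, shape=shape):
                self._accumulate(np.broadcast_to(g, shape))

            out._backward = back
        return out

    def mean(self) -> "Tensor":
        return self.sum() * (1.0 / self.data.size)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: Sequence[Tensor]) -> Tensor:
    out = Tensor(data)
    if _grad_enabled and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(p for p in parents if p.requires_grad)
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def _add_back(a: Tensor, b: Tensor, g: np.ndarray) -> None:
    if a.requires_grad:
        a._accumulate(_unbroadcast(g, a.data.shape))
    if b.requires_grad:
        b._accumulate(_unbroadcast(g, b.data.shape))


def _mul_back(a: Tensor, b: Tensor, g: np.ndarray) -> None:
    if a.requires_grad:
        a._accumulate(_unbroadcast(g * b.data, a.data.shape))
    if b.requires_grad:
        b._accumulate(_unbroadcast(g * a.data, b.data.shape))


def _binary(a, b, fwd, back) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = _make(fwd(a.data, b.data), (a, b))
    if out.requires_grad:
        out._backward = lambda g: back(a, b, g)
    return out


def _reciprocal(a: Tensor) -> Tensor:
    out = _make(1.0 / a.data, (a,))
    if out.requires_grad:

        def back(g, a=a, out=out):
            a._accumulate(-g * out.data * out.data)

        out._backward = back
    return out


# -- pointwise nonlinearities -------------------------------------------------


def relu(x: Tensor) -> Tensor:
    out = _make(np.maximum(x.data, 0.0), (x,))
    if out.requires_grad:

        def back(g, x=x):
            x._accumulate(g * (x.data > 0))

        out._backward = back
    return out


def sigmoid(x: Tensor) -> Tensor:
    # numerically stable on both tails
    s = np.where(x.data >= 0, 1.0 / (1.0 + np.exp(-x.data)),
                 np.exp(x.data) / (1.0 + np.exp(x.data)))
    out = _make(s.astype(np.float32), (x,))
    if out.requires_grad:

        def back(g, x=x, s=out.data):
            x._accumulate(g * s * (1.0 - s))

        out._backward = back
    return out


def log(x: Tensor) -> Tensor:
    out = _make(np.log(x.data), (x,))
    if out.requires_grad:

        def back(g, x=x):
            x._accumulate(g / x.data)

        out._backward = back
    return out


def clamp(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clip to [lo, hi]; gradient passes only where the input is in range."""
    out = _make(np.clip(x.data, lo, hi), (x,))
    if out.requires_grad:
        mask = (x.data >= lo) & (x.data <= hi)

        def back(g, x=x, mask=mask):
            x._accumulate(g * mask)

        out._backward = back
    return out


# -- structural ops -----------------------------------------------------------


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    out = _make(np.concatenate([t.data for t in ts], axis=axis), ts)
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in ts]
        splits = np.cumsum(sizes)[:-1]

        def back(g, ts=ts, splits=splits, axis=axis):
            for t, piece in zip(ts, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accumulate(piece)

        out._backward = back
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, dilation: int = 1) -> Tensor:
    """Stride-1 same-padded 2-D convolution (cross-correlation).

    x: [B, C, H, W]; w: [O, C, k, k] with k odd; padding = dilation*(k-1)/2
    so the spatial size is preserved at any dilation rate.
    """
    k = w.data.shape[2]
    if k % 2 == 0:
        raise ValueError("kernel must be odd")
    if x.data.shape[1] != w.data.shape[1]:
        raise ValueError(
            f"channel mismatch: input has {x.data.shape[1]}, kernel expects {w.data.shape[1]}"
        )
    d = int(dilation)
    pad = d * (k - 1) // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    keff = d * (k - 1) + 1
    win = sliding_window_view(xp, (keff, keff), axis=(2, 3))[..., ::d, ::d]
    data = np.einsum("bchwij,ocij->bohw", win, w.data, optimize=True)
    if b is not None:
        data = data + b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)
    out = _make(data.astype(np.float32), parents)
    if out.requires_grad:
        B, C, H, W = x.data.shape

        def back(g, x=x, w=w, b=b, win=win, k=k, d=d, pad=pad, H=H, W=W):
            if b is not None and b.requires_grad:
                b._accumulate(g.sum(axis=(0, 2, 3)))
            if w.requires_grad:
                w._accumulate(
                    np.einsum("bchwij,bohw->ocij", win, g, optimize=True))
            if x.requires_grad:
                gxp = np.zeros(
                    (g.shape[0], w.data.shape[1], H + 2 * pad, W + 2 * pad),
                    dtype=np.float32)
                for i in range(k):
                    for j in range(k):
                        gxp[:, :, i * d:i * d + H, j * d:j * d + W] += np.einsum(
                            "bohw,oc->bchw", g, w.data[:, :, i, j],
                            optimize=True)
                if pad:
                    gxp = gxp[:, :, pad:-pad, pad:-pad]
                x._accumulate(gxp)

        out._backward = back
    return out


def max_pool2x2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2; spatial dims must be even."""
    B, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError("max_pool2x2 requires even spatial dimensions")
    xr = x.data.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = xr.reshape(B, C, H // 2, W // 2, 4)
    idx = xr.argmax(axis=-1)
    out = _make(np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0], (x,))
    if out.requires_grad:

        def back(g, x=x, idx=idx, B=B, C=C, H=H, W=W):
            gr = np.zeros((B, C, H // 2, W // 2, 4), dtype=np.float32)
            np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
            gr = gr.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            x._accumulate(gr.reshape(B, C, H, W))

        out._backward = back
    return out


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """1-D linear interpolation matrix, half-pixel-centre convention."""
    A = np.zeros((n_out, n_in), dtype=np.float32)
    if n_in == 1:
        A[:, 0] = 1.0
        return A
    src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    i0 = np.floor(src).astype(int)
    t = (src - i0).astype(np.float32)
    lo = np.clip(i0, 0, n_in - 1)
    hi = np.clip(i0 + 1, 0, n_in - 1)
    rows = np.arange(n_out)
    np.add.at(A, (rows, lo), 1.0 - t)
    np.add.at(A, (rows, hi), t)
    return A


def upsample_bilinear(x: Tensor, size: tuple[int, int]) -> Tensor:
    """Bilinear resize of [B,C,H,W] to spatial ``size`` (Ho, Wo)."""
    Ho, Wo = size
    B, C, H, W = x.data.shape
    if (Ho, Wo) == (H, W):
        return x
    Ah = _interp_matrix(Ho, H)
    Aw = _interp_matrix(Wo, W)
    tmp = np.tensordot(x.data, Ah, axes=([2], [1]))  # B,C,W,Ho
    data = np.tensordot(tmp, Aw, axes=([2], [1]))    # B,C,Ho,Wo
    out = _make(data.astype(np.float32), (x,))
    if out.requires_grad:

        def back(g, x=x, Ah=Ah, Aw=Aw):
            tmp = np.tensordot(g, Ah, axes=([2], [0]))  # B,C,Wo,H
            gx = np.tensordot(tmp, Aw, axes=([2], [0]))  # B,C,H,W
            x._accumulate(gx.astype(np.float32))

        out._backward = back
    return out


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               running_mean: np.ndarray, running_var: np.ndarray,
               training: bool, momentum: float = 0.1,
               eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization over (batch, height, width).

    In training mode normalizes with batch statistics and updates the
    running buffers in place; in evaluation mode uses the buffers.
    """
    axes = (0, 2, 3)
    if training:
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        unbiased = var * (n / max(n - 1, 1))
        running_var *= 1.0 - momentum
        running_var += momentum * unbiased
    else:
        mu = running_mean
        var = running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * inv_std[None, :, None, None]
    data = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
    out = _make(data.astype(np.float32), (x, gamma, beta))
    if out.requires_grad:
        n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

        def back(g, x=x, gamma=gamma, beta=beta, xhat=xhat,
                 inv_std=inv_std, training=training, n=n):
            if beta.requires_grad:
                beta._accumulate(g.sum(axis=(0, 2, 3)))
            if gamma.requires_grad:
                gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
            if x.requires_grad:
                gs = g * gamma.data[None, :, None, None]
                if training:
                    m1 = gs.mean(axis=(0, 2, 3), keepdims=True)
                    m2 = (gs * xhat).mean(axis=(0, 2, 3), keepdims=True)
                    gx = (gs - m1 - xhat * m2) * inv_std[None, :, None, None]
                else:
                    gx = gs * inv_std[None, :, None, None]
                x._accumulate(gx.astype(np.float32))

        out._backward = back
    return out


# -- pooling reductions used by the attention modules -------------------------


def channel_mean(x: Tensor) -> Tensor:
    """Mean over the channel axis, keepdims: [B,C,H,W] -> [B,1,H,W]."""
    C = x.data.shape[1]
    out = _make(x.data.mean(axis=1, keepdims=True), (x,))
    if out.requires_grad:

        def back(g, x=x, C=C):
            x._accumulate(np.broadcast_to(g / C, x.data.shape))

        out._backward = back
    return out


def channel_max(x: Tensor) -> Tensor:
    """Max over the channel axis, keepdims: [B,C,H,W] -> [B,1,H,W]."""
    idx = x.data.argmax(axis=1, keepdims=True)
    out = _make(np.take_along_axis(x.data, idx, axis=1), (x,))
    if out.requires_grad:

        def back(g, x=x, idx=idx):
            gx = np.zeros_like(x.data)
            np.put_along_axis(gx, idx, g, axis=1)
            x._accumulate(gx)

        out._backward = back
    return out


def spatial_mean(x: Tensor) -> Tensor:
    """Global mean over H and W: [B,C,H,W] -> [B,C,1,1]."""
    n = x.data.shape[2] * x.data.shape[3]
    out = _make(x.data.mean(axis=(2, 3), keepdims=True), (x,))
    if out.requires_grad:

        def back(g, x=x, n=n):
            x._accumulate(np.broadcast_to(g / n, x.data.shape))

        out._backward = back
    return out


def spatial_max(x: Tensor) -> Tensor:
    """Global max over H and W: [B,C,H,W] -> [B,C,1,1]."""
    B, C, H, W = x.data.shape
    flat = x.data.reshape(B, C, H * W)
    idx = flat.argmax(axis=-1)
    out = _make(
        np.take_along_axis(flat, idx[..., None], axis=-1).reshape(B, C, 1, 1),
        (x,))
    if out.requires_grad:

        def back(g, x=x, idx=idx, B=B, C=C, H=H, W=W):
            gf = np.zeros((B, C, H * W), dtype=np.float32)
            np.put_along_axis(gf, idx[..., None], g.reshape(B, C, 1), axis=-1)
            x._accumulate(gf.reshape(B, C, H, W))

        out._backward = back
    return out
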