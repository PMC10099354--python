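"""Reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine sufficient for convolutional encoder-decoder
networks: every op records a closure that propagates the upstream gradient
to its inputs.  Arrays are float32 in NCHW layout.  Gradients are exact
(checked against central finite differences in the test suite).
"""

from __future__ import annotations

import contextlib
from typing import Callable, Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable tape recording (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def grad_enabled() -> bool:
    return _GRAD_ENABLED


class Tensor:
    """An array plus (optionally) a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._backward: Optional[Callable[[], None]] = None
        self._prev: tuple = ()

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss tensor")
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for child in node._prev:
                if id(child) not in visited:
                    stack.append((child, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()
        # dismantle the tape: the closures capture their output tensor,
        # forming reference cycles that would otherwise pin every
        # intermediate activation until a gc pass
        for node in topo:
            if node._prev:
                node._backward = None
                node._prev = ()
                node.grad = None


def _make(data: np.ndarray, parents: Sequence[Tensor],
          backward: Callable[[Tensor], Callable[[], None]]) -> Tensor:
    """Build an op output; record the tape entry only when grads are on."""
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad or p._prev for p in parents):
        out.requires_grad = True
        out._prev = tuple(parents)
        out._backward = backward(out)
    return out


# ---------------------------------------------------------------- elementwise

def relu(x: Tensor) -> Tensor:
    y = np.maximum(x.data, 0.0)

    def bw(out: Tensor):
        def run():
            x._accumulate(out.grad * (x.data > 0))
        return run

    return _make(y, [x], bw)


def sigmoid(x: Tensor) -> Tensor:
    z = np.clip(x.data, -60.0, 60.0)
    y = 1.0 / (1.0 + np.exp(-z))

    def bw(out: Tensor):
        def run():
            x._accumulate(out.grad * y * (1.0 - y))
        return run

    return _make(y, [x], bw)


def add(a: Tensor, b: Tensor) -> Tensor:
    if a.data.shape != b.data.shape:
        raise ValueError(f"add shape mismatch {a.data.shape} vs {b.data.shape}")
    y = a.data + b.data

    def bw(out: Tensor):
        def run():
            if a.requires_grad or a._prev:
                a._accumulate(out.grad)
            if b.requires_grad or b._prev:
                b._accumulate(out.grad)
        return run

    return _make(y, [a, b], bw)


def scale(x: Tensor, s: float) -> Tensor:
    """Multiply by a python scalar constant."""
    y = x.data * np.float32(s)

    def bw(out: Tensor):
        def run():
            x._accumulate(out.grad * np.float32(s))
        return run

    return _make(y, [x], bw)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient over axes that were broadcast from size 1."""
    axes = tuple(i for i, (gs, s) in enumerate(zip(g.shape, shape)) if s == 1 and gs != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def mul(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise product with broadcasting (used by attention gating)."""
    y = a.data * b.data

    def bw(out: Tensor):
        def run():
            if a.requires_grad or a._prev:
                a._accumulate(_unbroadcast(out.grad * b.data, a.data.shape))
            if b.requires_grad or b._prev:
                b._accumulate(_unbroadcast(out.grad * a.data, b.data.shape))
        return run

    return _make(y, [a, b], bw)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    y = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(out: Tensor):
        def run():
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                idx = [slice(None)] * y.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(out.grad[tuple(idx)])
        return run

    return _make(y, list(tensors), bw)


# -------------------------------------------------------------- convolutional

def conv2d(x: Tensor, w: Tensor, b: Optional[Tensor] = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation, NCHW input, (Cout, Cin, kh, kw) weight.

    Computed as a sum over kernel offsets of strided input slices times the
    corresponding 1x1 weight slice — plain slices keep the matmuls on
    contiguous memory, which is much faster in numpy than materializing an
    im2col tensor from a strided window view.
    """
    n, c, h, wd = x.data.shape
    co, ci, kh, kw = w.data.shape
    if ci != c:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight {ci}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    hp, wp = xp.shape[2], xp.shape[3]
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    # channels-last working copy; one GEMM over *all* padded positions with
    # the kernel offsets unrolled into the output width avoids any gather of
    # the input (slices of the GEMM result are summed with strided views)
    xt = np.ascontiguousarray(xp.transpose(0, 2, 3, 1))  # N,Hp,Wp,C
    xflat = xt.reshape(-1, c)
    w2 = np.ascontiguousarray(
        w.data.transpose(1, 2, 3, 0).reshape(c, kh * kw * co))
    z = (xflat @ w2).reshape(n, hp, wp, kh, kw, co)
    acc = np.zeros((n, ho, wo, co), dtype=np.float32)
    hi = stride * (ho - 1) + 1
    wi = stride * (wo - 1) + 1
    for i in range(kh):
        for j in range(kw):
            acc += z[:, i:i + hi:stride, j:j + wi:stride, i, j, :]
    del z
    y = np.ascontiguousarray(acc.transpose(0, 3, 1, 2))
    if b is not None:
        y += b.data.reshape(1, -1, 1, 1)

    def bw(out: Tensor):
        def run():
            g = np.ascontiguousarray(out.grad.transpose(0, 2, 3, 1))  # N,Ho,Wo,Co
            gm = g.reshape(-1, co)
            if w.requires_grad or w._prev:
                dw = np.empty((co, c, kh, kw), dtype=np.float32)
                for i in range(kh):
                    for j in range(kw):
                        xs = np.ascontiguousarray(
                            xt[:, i:i + hi:stride, j:j + wi:stride, :]
                        ).reshape(-1, c)
                        dw[:, :, i, j] = gm.T @ xs
                w._accumulate(dw)
            if b is not None:
                b._accumulate(gm.sum(axis=0))
            if x.requires_grad or x._prev:
                # one GEMM for all offsets, then strided scatter-adds
                wr = np.ascontiguousarray(
                    w.data.transpose(0, 2, 3, 1).reshape(co, kh * kw * c))
                gz = (gm @ wr).reshape(n, ho, wo, kh, kw, c)
                dxt = np.zeros_like(xt)
                for i in range(kh):
                    for j in range(kw):
                        dxt[:, i:i + hi:stride, j:j + wi:stride, :] += \
                            gz[:, :, :, i, j, :]
                dxp = dxt.transpose(0, 3, 1, 2)
                if padding:
                    dxp = dxp[:, :, padding:-padding, padding:-padding]
                x._accumulate(np.ascontiguousarray(dxp))
        return run

    parents = [x, w] if b is None else [x, w, b]
    return _make(y, parents, bw)


def max_pool2d(x: Tensor, kernel: int = 2, stride: Optional[int] = None,
               padding: int = 0) -> Tensor:
    """Max pooling; padded positions use -inf and never win the max."""
    stride = stride or kernel
    n, c, h, w = x.data.shape
    if kernel == 2 and stride == 2 and padding == 0:
        return _max_pool2x2(x)
    if padding:
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                    constant_values=-np.inf)
    else:
        xp = x.data
    win = sliding_window_view(xp, (kernel, kernel), axis=(2, 3))[:, :, ::stride, ::stride]
    ho, wo = win.shape[2], win.shape[3]
    flat = win.reshape(n, c, ho, wo, kernel * kernel)
    arg = flat.argmax(axis=-1)
    y = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def bw(out: Tensor):
        def run():
            ai, aj = np.divmod(arg, kernel)
            ni, ci_, oi, oj = np.indices(arg.shape, sparse=False)
            rows = oi * stride + ai - padding
            cols = oj * stride + aj - padding
            dx = np.zeros_like(x.data)
            np.add.at(dx, (ni.ravel(), ci_.ravel(), rows.ravel(), cols.ravel()),
                      out.grad.ravel())
            x._accumulate(dx)
        return run

    return _make(np.ascontiguousarray(y), [x], bw)


def _max_pool2x2(x: Tensor) -> Tensor:
    """Non-overlapping 2x2 pooling: vectorized argmax scatter, no add.at."""
    n, c, h, w = x.data.shape
    win = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = win.reshape(n, c, h // 2, w // 2, 4)
    arg = flat.argmax(axis=-1)
    y = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def bw(out: Tensor):
        def run():
            d6 = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
            np.put_along_axis(d6, arg[..., None], out.grad[..., None], axis=-1)
            dx = d6.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            x._accumulate(np.ascontiguousarray(dx.reshape(n, c, h, w)))
        return run

    return _make(np.ascontiguousarray(y), [x], bw)


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial up-sampling."""
    y = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def bw(out: Tensor):
        def run():
            n, c, h2, w2 = out.grad.shape
            g = out.grad.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))
            x._accumulate(g)
        return run

    return _make(y, [x], bw)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               running_mean: np.ndarray, running_var: np.ndarray,
               training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization.

    In training mode statistics come from the batch and the running buffers
    are updated in place; in eval mode the buffers are used directly.
    """
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= (1.0 - momentum)
        running_mean += momentum * mean
        running_var *= (1.0 - momentum)
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean.reshape(1, -1, 1, 1)) * inv.reshape(1, -1, 1, 1)
    y = gamma.data.reshape(1, -1, 1, 1) * xhat + beta.data.reshape(1, -1, 1, 1)

    def bw(out: Tensor):
        def run():
            g = out.grad
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
            beta._accumulate(g.sum(axis=(0, 2, 3)))
            if x.requires_grad or x._prev:
                gi = (gamma.data * inv).reshape(1, -1, 1, 1)
                if training:
                    m = g.shape[0] * g.shape[2] * g.shape[3]
                    sum_g = g.sum(axis=(0, 2, 3), keepdims=True)
                    sum_gx = (g * xhat).sum(axis=(0, 2, 3)).reshape(1, -1, 1, 1)
                    dx = gi * (g - sum_g / m - xhat * sum_gx / m)
                else:
                    dx = gi * g
                x._accumulate(dx)
        return run

    return _make(y, [x, gamma, beta], bw)


# ---------------------------------------------------------------------- heads

def softmax_channel(logits: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the channel axis (plain numpy)."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: Tensor, target: np.ndarray) -> Tensor:
    """Mean 2-class cross-entropy over all pixels.

    ``logits`` is (N, 2, H, W); ``target`` is (N, H, W) integer labels in
    {0, 1}.  Softmax over the two channels trained with cross-entropy is
    equivalent to binary cross-entropy on the foreground probability.
    """
    n, k, h, w = logits.data.shape
    target = np.asarray(target)
    if target.shape != (n, h, w):
        raise ValueError(f"target shape {target.shape} != {(n, h, w)}")
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    m = n * h * w
    picked = np.take_along_axis(p, target[:, None, :, :], axis=1)[:, 0]
    loss = -np.log(np.maximum(picked, 1e-12)).sum() / m

    def bw(out: Tensor):
        def run():
            onehot = np.zeros_like(p)
            np.put_along_axis(onehot, target[:, None, :, :], 1.0, axis=1)
            logits._accumulate(out.grad * (p - onehot) / m)
        return run

    return _make(np.float32(loss), [logits], bw)
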