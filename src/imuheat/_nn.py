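"""Minimal reverse-mode automatic differentiation for the classifiers.

A small, dependency-free computational-graph engine providing exactly the
operations the recurrent/convolutional-recurrent architectures need: dense
and convolutional affine maps (2D and 1D, 'same' padding, via im2col),
max-pooling, elementwise gates, and a fused softmax cross-entropy. Gradients
are checked against central finite differences in the test suite.

Everything is float64 and single-threaded numpy, so identical inputs and
seeds give bit-identical training runs.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "add", "mul", "matmul", "sigmoid", "tanh", "relu",
    "reshape", "narrow", "stack",
    "conv2d", "conv1d", "maxpool2d", "maxpool1d",
    "softmax", "softmax_cross_entropy", "Adam",
]


class Tensor:
    """Node in the computation graph."""

    __slots__ = ("data", "grad", "parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.parents = tuple(parents)
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in self.parents)

    @property
    def shape(self):
        return self.data.shape

    def accumulate(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self):
        """Reverse-accumulate d(self)/d(leaves), seeding with ones."""
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen or not node.requires_grad:
                return
            seen.add(id(node))
            for p in node.parents:
                visit(p)
            topo.append(node)

        visit(self)
        self.accumulate(np.ones_like(self.data))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)


def _unbroadcast(grad, shape):
    """Sum a gradient over axes that were broadcast in the forward pass."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g, b.data.shape))

    return Tensor(out_data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g * a.data, b.data.shape))

    return Tensor(out_data, (a, b), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate(g @ b.data.T)
        if b.requires_grad:
            b.accumulate(a.data.T @ g)

    return Tensor(out_data, (a, b), backward)


def sigmoid(x: Tensor) -> Tensor:
    s = np.empty_like(x.data)
    pos = x.data >= 0
    s[pos] = 1.0 / (1.0 + np.exp(-x.data[pos]))
    e = np.exp(x.data[~pos])
    s[~pos] = e / (1.0 + e)

    def backward(g):
        if x.requires_grad:
            x.accumulate(g * s * (1.0 - s))

    return Tensor(s, (x,), backward)


def tanh(x: Tensor) -> Tensor:
    t = np.tanh(x.data)

    def backward(g):
        if x.requires_grad:
            x.accumulate(g * (1.0 - t * t))

    return Tensor(t, (x,), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g):
        if x.requires_grad:
            x.accumulate(g * mask)

    return Tensor(x.data * mask, (x,), backward)


def reshape(x: Tensor, shape) -> Tensor:
    def backward(g):
        if x.requires_grad:
            x.accumulate(g.reshape(x.data.shape))

    return Tensor(x.data.reshape(shape), (x,), backward)


def narrow(x: Tensor, axis: int, start: int, length: int) -> Tensor:
    """Contiguous slice along one axis."""
    idx = [slice(None)] * x.data.ndim
    idx[axis] = slice(start, start + length)
    idx = tuple(idx)

    def backward(g):
        if x.requires_grad:
            full = np.zeros_like(x.data)
            full[idx] = g
            x.accumulate(full)

    return Tensor(x.data[idx], (x,), backward)


def stack(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        parts = np.moveaxis(g, axis, 0)
        for t, gt in zip(tensors, parts):
            if t.requires_grad:
                t.accumulate(gt)

    return Tensor(out_data, tuple(tensors), backward)


def _im2col2d(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(N, C, H, W) -> (N, H*W, C*kh*kw) with 'same' zero padding."""
    n, c, h, w = x.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # (N,C,H,W,kh,kw)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n, h * w, c * kh * kw)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """'Same'-padded 2D convolution (cross-correlation): x (N,C,H,W) with
    filters w (F,C,kh,kw) and optional bias (F,)."""
    n, c, h, wd = x.data.shape
    f, c2, kh, kw = w.data.shape
    assert c == c2, "channel mismatch"
    cols = _im2col2d(x.data, kh, kw)  # (N, HW, C*kh*kw)
    wm = w.data.reshape(f, -1)
    out = cols @ wm.T  # (N, HW, F)
    if b is not None:
        out += b.data
    out_data = out.transpose(0, 2, 1).reshape(n, f, h, wd)
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        dmat = g.reshape(n, f, h * wd).transpose(0, 2, 1)  # (N, HW, F)
        if w.requires_grad:
            dW = np.tensordot(dmat, cols, axes=([0, 1], [0, 1]))  # (F, C*kh*kw)
            w.accumulate(dW.reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b.accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = dmat @ wm  # (N, HW, C*kh*kw)
            dcols = dcols.reshape(n, h, wd, c, kh, kw)
            ph, pw = kh // 2, kw // 2
            dxp = np.zeros((n, c, h + 2 * ph, wd + 2 * pw))
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i : i + h, j : j + wd] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            x.accumulate(dxp[:, :, ph : ph + h, pw : pw + wd])

    return Tensor(out_data, parents, backward)


def conv1d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """'Same'-padded 1D convolution: x (N,C,L), filters (F,C,k)."""
    n, c, length = x.data.shape
    f, c2, k = w.data.shape
    assert c == c2, "channel mismatch"
    p = k // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p)))
    win = sliding_window_view(xp, k, axis=2)  # (N, C, L, k)
    cols = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(n, length, c * k)
    wm = w.data.reshape(f, -1)
    out = cols @ wm.T
    if b is not None:
        out += b.data
    out_data = out.transpose(0, 2, 1)  # (N, F, L)
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        dmat = g.transpose(0, 2, 1)  # (N, L, F)
        if w.requires_grad:
            dW = np.tensordot(dmat, cols, axes=([0, 1], [0, 1]))
            w.accumulate(dW.reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b.accumulate(g.sum(axis=(0, 2)))
        if x.requires_grad:
            dcols = (dmat @ wm).reshape(n, length, c, k)
            dxp = np.zeros((n, c, length + 2 * p))
            for i in range(k):
                dxp[:, :, i : i + length] += dcols[:, :, :, i].transpose(0, 2, 1)
            x.accumulate(dxp[:, :, p : p + length])

    return Tensor(out_data, parents, backward)


def maxpool2d(x: Tensor, size: int = 2) -> Tensor:
    """Non-overlapping spatial max pooling; ties resolved to the first
    element in (row-major) order for determinism."""
    n, c, h, w = x.data.shape
    if h % size or w % size:
        raise ValueError(f"spatial dims must be divisible by pool size {size}")
    ho, wo = h // size, w // size
    xr = (
        x.data.reshape(n, c, ho, size, wo, size)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, c, ho, wo, size * size)
    )
    idx = np.argmax(xr, axis=-1)
    out_data = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        dxr = np.zeros((n, c, ho, wo, size * size))
        np.put_along_axis(dxr, idx[..., None], g[..., None], axis=-1)
        dx = (
            dxr.reshape(n, c, ho, wo, size, size)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )
        x.accumulate(dx)

    return Tensor(out_data, (x,), backward)


def maxpool1d(x: Tensor, size: int = 2) -> Tensor:
    n, c, length = x.data.shape
    if length % size:
        raise ValueError(f"length must be divisible by pool size {size}")
    lo = length // size
    xr = x.data.reshape(n, c, lo, size)
    idx = np.argmax(xr, axis=-1)
    out_data = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        dxr = np.zeros((n, c, lo, size))
        np.put_along_axis(dxr, idx[..., None], g[..., None], axis=-1)
        x.accumulate(dxr.reshape(n, c, length))

    return Tensor(out_data, (x,), backward)


def softmax(scores: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the last axis (plain numpy)."""
    z = np.asarray(scores, float)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean categorical cross-entropy of (N, C) logits against integer
    targets, fused with softmax via log-sum-exp."""
    z = logits.data
    n = z.shape[0]
    targets = np.asarray(targets, int)
    zmax = z.max(axis=1, keepdims=True)
    lse = zmax[:, 0] + np.log(np.exp(z - zmax).sum(axis=1))
    losses = lse - z[np.arange(n), targets]
    probs = softmax(z)

    def backward(g):
        if logits.requires_grad:
            dz = probs.copy()
            dz[np.arange(n), targets] -= 1.0
            logits.accumulate(g * dz / n)

    return Tensor(losses.mean(), (logits,), backward)


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[k] = b1 * self.m[k] + (1 - b1) * p.grad
            self.v[k] = b2 * self.v[k] + (1 - b2) * p.grad**2
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
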