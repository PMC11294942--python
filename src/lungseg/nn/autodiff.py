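"""Minimal reverse-mode automatic differentiation over numpy arrays.

Exactly the operations a small segmentation CNN needs: same-padding
convolution, 2x2 stride-2 transposed convolution, 2x2 max-pooling, ReLU,
sigmoid, channel concatenation, dropout, and the scalar arithmetic required
for a Dice loss.  Everything runs single-threaded on numpy and is therefore
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "conv2d", "conv_transpose2x2", "maxpool2x2", "relu",
           "sigmoid", "concat", "dropout"]


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._backward = None
        self._prev = tuple(_prev)

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self):
        """Reverse-accumulate gradients from this (scalar) node."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can exceed the recursion limit
            node, processed = stack.pop()
            if processed:
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
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- scalar/elementwise arithmetic ------------------------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = _bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-other if isinstance(other, Tensor) else -np.asarray(other))

    def __rsub__(self, other):
        return (-self) + other

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data / other.data, _prev=(self, other))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        out._backward = _bw
        return out

    def sum(self):
        out = Tensor(self.data.sum(), _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = _bw
        return out

    def item(self) -> float:
        return float(self.data)


def _unbroadcast(g, shape):
    """Sum gradient ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-padding stride-1 convolution; x (n,c,h,w), w (o,c,k,k), b (o,)."""
    k = w.data.shape[2]
    pad = k // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = sliding_window_view(xp, (k, k), axis=(2, 3))
    y = np.einsum("nchwkl,ockl->nohw", cols, w.data, optimize=True)
    y += b.data[None, :, None, None]
    out = Tensor(y, _prev=(x, w, b))

    def _bw(g):
        if w.requires_grad:
            w._accumulate(np.einsum("nchwkl,nohw->ockl", cols, g, optimize=True))
        if b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gp = np.pad(g, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
            gcols = sliding_window_view(gp, (k, k), axis=(2, 3))
            wf = w.data[:, :, ::-1, ::-1]
            x._accumulate(np.einsum("nohwkl,ockl->nchw", gcols, wf, optimize=True))

    out._backward = _bw
    return out


def conv_transpose2x2(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """2x2 stride-2 transposed convolution (non-overlapping upsampling).

    x (n,c,h,w), w (c,o,2,2), b (o,); output (n,o,2h,2w).
    """
    n, c, h, wd = x.data.shape
    o = w.data.shape[1]
    y = np.einsum("ncij,cokl->noikjl", x.data, w.data, optimize=True)
    y = y.reshape(n, o, 2 * h, 2 * wd) + b.data[None, :, None, None]
    out = Tensor(y, _prev=(x, w, b))

    def _bw(g):
        gr = g.reshape(n, o, h, 2, wd, 2)  # axes: n,o,i,k,j,l
        if b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            w._accumulate(np.einsum("noikjl,ncij->cokl", gr, x.data, optimize=True))
        if x.requires_grad:
            x._accumulate(np.einsum("noikjl,cokl->ncij", gr, w.data, optimize=True))

    out._backward = _bw
    return out


def maxpool2x2(x: Tensor) -> Tensor:
    """Non-overlapping 2x2 max pooling; ties route to the first maximum."""
    n, c, h, w = x.data.shape
    xr = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = xr.reshape(n, c, h // 2, w // 2, 4)
    idx = flat.argmax(axis=-1)
    y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    out = Tensor(y, _prev=(x,))

    def _bw(g):
        if x.requires_grad:
            gf = np.zeros_like(flat)
            np.put_along_axis(gf, idx[..., None], g[..., None], axis=-1)
            gx = gf.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            x._accumulate(gx.reshape(n, c, h, w))

    out._backward = _bw
    return out


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = Tensor(x.data * mask, _prev=(x,))

    def _bw(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    out._backward = _bw
    return out


def sigmoid(x: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-np.clip(x.data, -500, 500)))
    out = Tensor(y, _prev=(x,))

    def _bw(g):
        if x.requires_grad:
            x._accumulate(g * y * (1.0 - y))

    out._backward = _bw
    return out


def concat(tensors, axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out._backward = _bw
    return out


def dropout(x: Tensor, rate: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or rate <= 0:
        return x
    mask = (rng.random(x.data.shape) >= rate) / (1.0 - rate)
    out = Tensor(x.data * mask, _prev=(x,))

    def _bw(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    out._backward = _bw
    return out


def softmax2(x: Tensor) -> Tensor:
    """Two-class channel softmax returning the class-1 probability map.

    For a 2-channel input this equals sigmoid(x[:,1] - x[:,0]) and keeps a
    single output channel, matching the binary segmentation head.
    """
    d = x.data[:, 1:2] - x.data[:, 0:1]
    p = 1.0 / (1.0 + np.exp(-np.clip(d, -500, 500)))
    out = Tensor(p, _prev=(x,))

    def _bw(g):
        if x.requires_grad:
            gd = g * p * (1.0 - p)
            gx = np.concatenate([-gd, gd], axis=1)
            x._accumulate(gx)

    out._backward = _bw
    return out
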