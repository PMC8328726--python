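"""Reverse-mode autodiff over numpy arrays.

A :class:`Tensor` wraps an ndarray plus the closure that routes its
gradient to its parents.  Calling :meth:`Tensor.backward` on a scalar
result topologically sorts the graph and accumulates gradients into
every tensor with ``requires_grad``.  Convolution is stride-1 im2col
with 'same' padding; spatial downsampling is done by pooling layers.
"""

from __future__ import annotations

from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

__all__ = ["Tensor", "concat"]


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # defer mixed ndarray <op> Tensor expressions to the Tensor operators
    __array_ufunc__ = None

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: Tuple["Tensor", ...] = (),
        backward: Optional[Callable] = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    # -- graph machinery -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: List[Tensor] = []
        seen = set()

        def build(t: "Tensor") -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                build(p)
            topo.append(t)

        build(self)
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ------------------------------------------------------

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))

    @staticmethod
    def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
        if grad.shape == shape:
            return grad
        extra = grad.ndim - len(shape)
        if extra > 0:
            grad = grad.sum(axis=tuple(range(extra)))
        axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
        if axes:
            grad = grad.sum(axis=axes, keepdims=True)
        return grad

    def __add__(self, other) -> "Tensor":
        other = self._wrap(other)
        out_data = self.data + other.data

        def bw(g):
            _accum(self, self._unbroadcast(g, self.data.shape))
            _accum(other, self._unbroadcast(g, other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=bw)

    __radd__ = __add__

    def __mul__(self, other) -> "Tensor":
        other = self._wrap(other)
        out_data = self.data * other.data

        def bw(g):
            _accum(self, self._unbroadcast(g * other.data, self.data.shape))
            _accum(other, self._unbroadcast(g * self.data, other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=bw)

    __rmul__ = __mul__

    def __neg__(self) -> "Tensor":
        return self * -1.0

    def __sub__(self, other) -> "Tensor":
        return self + (-self._wrap(other))

    def __rsub__(self, other) -> "Tensor":
        return self._wrap(other) + (-self)

    def __pow__(self, exponent: float) -> "Tensor":
        c = float(exponent)
        out_data = self.data**c

        def bw(g):
            _accum(self, g * c * self.data ** (c - 1.0))

        return Tensor(out_data, parents=(self,), backward=bw)

    def __truediv__(self, other) -> "Tensor":
        other = self._wrap(other)
        return self * other**-1.0

    def __rtruediv__(self, other) -> "Tensor":
        return self._wrap(other) * self**-1.0

    # -- pointwise nonlinearities ---------------------------------------

    def relu(self) -> "Tensor":
        out_data = np.maximum(self.data, 0.0)

        def bw(g):
            _accum(self, g * (self.data > 0))

        return Tensor(out_data, parents=(self,), backward=bw)

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60.0, 60.0)))

        def bw(g):
            _accum(self, g * s * (1.0 - s))

        return Tensor(s, parents=(self,), backward=bw)

    def logsigmoid(self) -> "Tensor":
        """Numerically stable log(sigmoid(x)); gradient sigmoid(-x)."""
        x = self.data
        out_data = np.minimum(x, 0.0) - np.log1p(np.exp(-np.abs(x)))

        def bw(g):
            _accum(self, g * (1.0 / (1.0 + np.exp(np.clip(x, -60.0, 60.0)))))

        return Tensor(out_data, parents=(self,), backward=bw)

    def log(self) -> "Tensor":
        out_data = np.log(self.data)

        def bw(g):
            _accum(self, g / self.data)

        return Tensor(out_data, parents=(self,), backward=bw)

    # -- reductions ------------------------------------------------------

    def sum(self) -> "Tensor":
        def bw(g):
            _accum(self, np.broadcast_to(g, self.data.shape).copy())

        return Tensor(self.data.sum(), parents=(self,), backward=bw)

    def mean(self) -> "Tensor":
        n = self.data.size

        def bw(g):
            _accum(self, np.broadcast_to(g / n, self.data.shape).copy())

        return Tensor(self.data.mean(), parents=(self,), backward=bw)

    # -- spatial ops (NCHW) ---------------------------------------------

    def conv2d(self, weight: "Tensor", bias: "Tensor", dilation: int = 1) -> "Tensor":
        """Stride-1 'same' convolution; weight (F, C, kh, kw), bias (F,)."""
        x = self.data
        N, C, H, W = x.shape
        F, Cw, kh, kw = weight.data.shape
        assert C == Cw, f"channel mismatch {C} vs {Cw}"
        pad = dilation * (kh - 1) // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        Ho = H + 2 * pad - dilation * (kh - 1)
        Wo = W + 2 * pad - dilation * (kw - 1)
        cols = np.empty((N, C, kh * kw, Ho * Wo))
        t = 0
        for i in range(kh):
            for j in range(kw):
                cols[:, :, t, :] = xp[
                    :, :, i * dilation : i * dilation + Ho, j * dilation : j * dilation + Wo
                ].reshape(N, C, -1)
                t += 1
        cols2 = cols.reshape(N, C * kh * kw, Ho * Wo)
        W2 = weight.data.reshape(F, C * kh * kw)
        out = np.matmul(W2, cols2)  # (N, F, Ho*Wo)
        out = out.reshape(N, F, Ho, Wo) + bias.data[None, :, None, None]

        def bw(g):
            g2 = g.reshape(N, F, Ho * Wo)
            if bias.requires_grad:
                _accum(bias, g2.sum(axis=(0, 2)))
            if weight.requires_grad:
                dW2 = np.matmul(g2, cols2.transpose(0, 2, 1)).sum(axis=0)
                _accum(weight, dW2.reshape(F, C, kh, kw))
            if self.requires_grad:
                dcols = np.matmul(W2.T, g2).reshape(N, C, kh * kw, Ho * Wo)
                dxp = np.zeros_like(xp)
                tt = 0
                for i in range(kh):
                    for j in range(kw):
                        dxp[
                            :,
                            :,
                            i * dilation : i * dilation + Ho,
                            j * dilation : j * dilation + Wo,
                        ] += dcols[:, :, tt, :].reshape(N, C, Ho, Wo)
                        tt += 1
                _accum(self, dxp[:, :, pad : pad + H, pad : pad + W] if pad else dxp)

        return Tensor(out, parents=(self, weight, bias), backward=bw)

    def maxpool2x2(self) -> "Tensor":
        N, C, H, W = self.data.shape
        assert H % 2 == 0 and W % 2 == 0
        xr = (
            self.data.reshape(N, C, H // 2, 2, W // 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(N, C, H // 2, W // 2, 4)
        )
        idx = np.argmax(xr, axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

        def bw(g):
            dxr = np.zeros((N, C, H // 2, W // 2, 4))
            np.put_along_axis(dxr, idx[..., None], g[..., None], axis=-1)
            dx = (
                dxr.reshape(N, C, H // 2, W // 2, 2, 2)
                .transpose(0, 1, 2, 4, 3, 5)
                .reshape(N, C, H, W)
            )
            _accum(self, dx)

        return Tensor(out, parents=(self,), backward=bw)

    def upsample(self, factor: int = 2) -> "Tensor":
        """Nearest-neighbour upsampling by an integer factor."""
        N, C, H, W = self.data.shape
        out = np.repeat(np.repeat(self.data, factor, axis=2), factor, axis=3)

        def bw(g):
            _accum(self, g.reshape(N, C, H, factor, W, factor).sum(axis=(3, 5)))

        return Tensor(out, parents=(self,), backward=bw)

    def avgpool_to(self, size: int) -> "Tensor":
        """Adaptive average pooling onto a size x size grid (H, W divisible)."""
        N, C, H, W = self.data.shape
        assert H % size == 0 and W % size == 0
        bh, bw_ = H // size, W // size
        out = self.data.reshape(N, C, size, bh, size, bw_).mean(axis=(3, 5))

        def bw(g):
            dx = np.repeat(np.repeat(g, bh, axis=2), bw_, axis=3) / (bh * bw_)
            _accum(self, dx)

        return Tensor(out, parents=(self,), backward=bw)


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    # accumulation always rebinds (never mutates in place), so sharing g
    # between siblings is safe
    if t.grad is None:
        t.grad = g
    else:
        t.grad = t.grad + g


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    """Concatenate along an axis (channel axis for feature maps)."""
    tensors = list(tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            _accum(t, piece)

    return Tensor(out, parents=tuple(tensors), backward=bw)
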