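"""Reverse-mode automatic differentiation on NumPy arrays.

This module implements the small tensor engine that powers the
convolutional models in this package.  It is deliberately minimal: dense
arrays only, eager evaluation, and a static set of operations (arithmetic,
matmul, 3x3/1x1 convolution, pooling, resampling, and the pointwise
nonlinearities the models need).  Every intermediate ``Tensor`` retains its
gradient after ``backward()``, which is what Grad-CAM needs to read
activations' gradients at an arbitrary internal layer.

Conventions
-----------
* Image batches are NCHW.
* Dtypes follow the input: float32 stays float32 (training), float64 stays
  float64 (oracle/gradient-check precision).  Integer input is promoted to
  float64.
* ``bilinear_resize`` uses half-pixel sample centres with edge clipping,
  expressed as two fixed interpolation matrices so that the adjoint is the
  exact transpose of the forward map.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "bilinear_resize"]


def _as_float(x) -> np.ndarray:
    a = np.asarray(x)
    if not np.issubdtype(a.dtype, np.floating):
        a = a.astype(np.float64)
    return a


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (adjoint of NumPy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


class Tensor:
    """A NumPy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_prev", "_backward")

    # keep NumPy from intercepting `ndarray op Tensor`
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data: np.ndarray = _as_float(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._prev: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helper used by every op --------------------------------
    @classmethod
    def _from_op(cls, data, prev: Sequence["Tensor"], backward) -> "Tensor":
        out = cls(data)
        out.requires_grad = any(p.requires_grad for p in prev)
        if out.requires_grad:
            out._prev = tuple(prev)
            out._backward = backward
        return out

    # -- basic protocol -------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.grad is not None})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- autodiff -------------------------------------------------------------
    def backward(self, grad=None) -> None:
        """Backpropagate from this tensor through the recorded graph."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        if grad is None:
            grad = np.ones_like(self.data)
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------------
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other) -> "Tensor":
        a, b = self, self._wrap(other)

        def bwd(g):
            a._accum(_unbroadcast(g, a.shape))
            b._accum(_unbroadcast(g, b.shape))

        return Tensor._from_op(a.data + b.data, (a, b), bwd)

    __radd__ = __add__

    def __mul__(self, other) -> "Tensor":
        a, b = self, self._wrap(other)

        def bwd(g):
            a._accum(_unbroadcast(g * b.data, a.shape))
            b._accum(_unbroadcast(g * a.data, b.shape))

        return Tensor._from_op(a.data * b.data, (a, b), bwd)

    __rmul__ = __mul__

    def __neg__(self) -> "Tensor":
        a = self
        return Tensor._from_op(-a.data, (a,), lambda g: a._accum(-g))

    def __sub__(self, other) -> "Tensor":
        return self + (-self._wrap(other))

    def __rsub__(self, other) -> "Tensor":
        return self._wrap(other) + (-self)

    def __truediv__(self, other) -> "Tensor":
        a, b = self, self._wrap(other)

        def bwd(g):
            a._accum(_unbroadcast(g / b.data, a.shape))
            b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.shape))

        return Tensor._from_op(a.data / b.data, (a, b), bwd)

    def __rtruediv__(self, other) -> "Tensor":
        return self._wrap(other) / self

    def __pow__(self, p: float) -> "Tensor":
        a = self
        p = float(p)

        def bwd(g):
            a._accum(g * p * a.data ** (p - 1.0))

        return Tensor._from_op(a.data**p, (a,), bwd)

    def __matmul__(self, other) -> "Tensor":
        a, b = self, self._wrap(other)

        def bwd(g):
            a._accum(g @ b.data.T)
            b._accum(a.data.T @ g)

        return Tensor._from_op(a.data @ b.data, (a, b), bwd)

    # -- pointwise nonlinearities ---------------------------------------------
    def exp(self) -> "Tensor":
        a = self
        out_data = np.exp(a.data)

        def bwd(g):
            a._accum(g * out_data)

        return Tensor._from_op(out_data, (a,), bwd)

    def log(self) -> "Tensor":
        a = self

        def bwd(g):
            a._accum(g / a.data)

        return Tensor._from_op(np.log(a.data), (a,), bwd)

    def relu(self) -> "Tensor":
        a = self
        mask = a.data > 0

        def bwd(g):
            a._accum(g * mask)

        return Tensor._from_op(np.where(mask, a.data, 0.0), (a,), bwd)

    def sigmoid(self) -> "Tensor":
        a = self
        s = 1.0 / (1.0 + np.exp(-a.data))

        def bwd(g):
            a._accum(g * s * (1.0 - s))

        return Tensor._from_op(s, (a,), bwd)

    def clip(self, lo: float, hi: float) -> "Tensor":
        """Clamp values; the gradient is passed through strictly inside the range."""
        a = self
        mask = (a.data > lo) & (a.data < hi)

        def bwd(g):
            a._accum(g * mask)

        return Tensor._from_op(np.clip(a.data, lo, hi), (a,), bwd)

    # -- reductions / shape ----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accum(np.broadcast_to(gg, a.shape).copy())

        return Tensor._from_op(out_data, (a,), bwd)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.shape[i] for i in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape) -> "Tensor":
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def bwd(g):
            a._accum(g.reshape(a.shape))

        return Tensor._from_op(a.data.reshape(shape), (a,), bwd)

    def transpose(self, *axes) -> "Tensor":
        a = self
        inv = np.argsort(axes)

        def bwd(g):
            a._accum(g.transpose(inv))

        return Tensor._from_op(a.data.transpose(axes), (a,), bwd)

    # -- convolution / pooling / resampling ------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor" | None = None,
               padding: int = 0) -> "Tensor":
        """2-D cross-correlation, stride 1, NCHW.

        ``weight`` is (O, C, kh, kw); ``bias`` is (O,) or None.  Implemented
        by im2col + matmul; the backward pass scatters back through the same
        column view, so the adjoint is exact.
        """
        a, w = self, weight
        N, C, H, W = a.shape
        O, Cw, kh, kw = w.shape
        if Cw != C:
            raise ValueError(f"channel mismatch: input {C}, weight {Cw}")
        p = int(padding)
        xp = np.pad(a.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else a.data
        Ho, Wo = xp.shape[2] - kh + 1, xp.shape[3] - kw + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            N * Ho * Wo, C * kh * kw
        )
        wf = w.data.reshape(O, -1)
        out = cols @ wf.T
        if bias is not None:
            out = out + bias.data
        out = out.reshape(N, Ho, Wo, O).transpose(0, 3, 1, 2)
        prev = (a, w) if bias is None else (a, w, bias)

        def bwd(g):
            go = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, O)
            w._accum((go.T @ cols).reshape(w.shape))
            if bias is not None:
                bias._accum(go.sum(axis=0))
            dcols = go @ wf
            dwin = dcols.reshape(N, Ho, Wo, C, kh, kw).transpose(0, 3, 1, 2, 4, 5)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + Ho, j:j + Wo] += dwin[:, :, :, :, i, j]
            a._accum(dxp[:, :, p:p + H, p:p + W] if p else dxp)

        return Tensor._from_op(out, prev, bwd)

    def maxpool2d(self, k: int = 2) -> "Tensor":
        a = self
        N, C, H, W = a.shape
        if H % k or W % k:
            raise ValueError(f"spatial size {(H, W)} not divisible by pool {k}")
        Ho, Wo = H // k, W // k
        r = a.data.reshape(N, C, Ho, k, Wo, k).transpose(0, 1, 2, 4, 3, 5)
        r = np.ascontiguousarray(r).reshape(N, C, Ho, Wo, k * k)
        idx = r.argmax(axis=-1)
        out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]

        def bwd(g):
            dr = np.zeros((N, C, Ho, Wo, k * k), dtype=g.dtype)
            np.put_along_axis(dr, idx[..., None], g[..., None], axis=-1)
            dr = dr.reshape(N, C, Ho, Wo, k, k).transpose(0, 1, 2, 4, 3, 5)
            a._accum(dr.reshape(N, C, H, W))

        return Tensor._from_op(out, (a,), bwd)

    def upsample_nearest(self, k: int = 2) -> "Tensor":
        a = self
        N, C, H, W = a.shape

        def bwd(g):
            a._accum(g.reshape(N, C, H, k, W, k).sum(axis=(3, 5)))

        return Tensor._from_op(a.data.repeat(k, axis=2).repeat(k, axis=3), (a,), bwd)


def _interp_matrix(n_in: int, n_out: int, dtype) -> np.ndarray:
    """Bilinear interpolation matrix (n_out x n_in), half-pixel centres."""
    s = (np.arange(n_out, dtype=np.float64) + 0.5) * n_in / n_out - 0.5
    s = np.clip(s, 0.0, n_in - 1.0)
    i0 = np.floor(s).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    w = s - i0
    A = np.zeros((n_out, n_in), dtype=np.float64)
    rows = np.arange(n_out)
    np.add.at(A, (rows, i0), 1.0 - w)
    np.add.at(A, (rows, i1), w)
    return A.astype(dtype)


def bilinear_resize(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Differentiable bilinear resize of an NCHW tensor to ``out_hw``.

    The resize is a fixed linear map ``out = A x Bᵀ``; its adjoint
    ``dx = Aᵀ g B`` makes the operation exactly self-consistent under
    gradient checking.  Identity when the size already matches.
    """
    if x.ndim != 4:
        raise ValueError("bilinear_resize expects an NCHW tensor")
    H2, W2 = out_hw
    N, C, H, W = x.shape
    if (H, W) == (H2, W2):
        return x
    A = _interp_matrix(H, H2, x.dtype)
    B = _interp_matrix(W, W2, x.dtype)
    out = np.einsum("oh,nchw,pw->ncop", A, x.data, B, optimize=True)

    def bwd(g):
        x._accum(np.einsum("oh,ncop,pw->nchw", A, g, B, optimize=True))

    return Tensor._from_op(out, (x,), bwd)


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    ts = list(tensors)
    sizes = [t.shape[axis] for t in ts]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(ts, np.split(g, splits, axis=axis)):
            t._accum(piece)

    return Tensor._from_op(np.concatenate([t.data for t in ts], axis=axis), ts, bwd)
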