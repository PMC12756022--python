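"""Reverse-mode automatic differentiation over numpy arrays.

A small tape-based engine in the micrograd style, extended with the
volumetric operations the model needs: 3D convolution (stride 1, "same"
padding, computed as im2col + GEMM in memory-bounded chunks), 2x max
pooling, adaptive max pooling to a target grid, and batch normalization.

Gradients are accumulated on every node of the graph during
:meth:`Tensor.backward`, which makes intermediate activations directly
inspectable (used by Grad-CAM). A module-level :func:`no_grad` context
disables graph construction for inference-only passes so large volumes
do not retain their activation history.
"""

from __future__ import annotations

import contextlib
import math

import numpy as np
from scipy.special import erf

__all__ = [
    "Tensor",
    "no_grad",
    "cat",
    "conv3d",
    "maxpool3d",
    "adaptive_maxpool3d",
    "batchnorm",
    "dropout",
    "softmax",
]

_GRAD_ENABLED = True

# col buffers for im2col are capped at ~150 MB so paper-scale volumes fit
# comfortably in memory; chunking is over the first spatial axis.
_COL_BUDGET_BYTES = 150_000_000


@contextlib.contextmanager
def no_grad():
    """Context manager that disables graph construction."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing ---------------------------------------------------

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=self.data.dtype)
        self.grad += grad.astype(self.data.dtype, copy=False)

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node (defaults to a gradient of ones)."""
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accum(np.asarray(grad))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- convenience ------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- elementwise arithmetic -------------------------------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return Tensor._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __pow__(self, p: float):
        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(self.data**p, (self,), backward)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return Tensor._make(self.data @ other.data, (self, other), backward)

    # -- nonlinearities ---------------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * 0.5 / out_data)

        return Tensor._make(out_data, (self,), backward)

    def relu(self):
        out_data = np.maximum(self.data, 0)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (self.data > 0))

        return Tensor._make(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data**2))

        return Tensor._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward)

    def gelu(self):
        """Exact GELU, x * Phi(x) with the Gaussian CDF Phi."""
        x = self.data
        phi_cdf = 0.5 * (1.0 + erf(x / math.sqrt(2.0)))
        out_data = x * phi_cdf

        def backward(g):
            if self.requires_grad:
                pdf = np.exp(-0.5 * x**2) / math.sqrt(2.0 * math.pi)
                self._accum(g * (phi_cdf + x * pdf))

        return Tensor._make(out_data, (self,), backward)

    # -- reductions / shape ------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else axis
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        """Maximum along one axis; gradient flows to the first argmax."""
        am = self.data.argmax(axis=axis)
        out_data = np.take_along_axis(self.data, np.expand_dims(am, axis), axis)
        if not keepdims:
            out_data = np.squeeze(out_data, axis)

        def backward(g):
            if not self.requires_grad:
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            full = np.zeros_like(self.data)
            np.put_along_axis(full, np.expand_dims(am, axis), g, axis)
            self._accum(full)

        return Tensor._make(out_data, (self,), backward)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.data.ndim)))
        elif len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        return Tensor._make(self.data[idx], (self,), backward)

    def astype(self, dtype):
        def backward(g):
            if self.requires_grad:
                self._accum(g.astype(self.data.dtype))

        return Tensor._make(self.data.astype(dtype), (self,), backward)


def cat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    """Concatenate tensors along ``axis``."""
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
    )


def softmax(x: Tensor, axis: int = 0) -> Tensor:
    """Numerically stable softmax (the shift is a constant, gradient-free)."""
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def dropout(x: Tensor, rate: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate == 0."""
    if not training or rate <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= rate).astype(x.data.dtype) / (1.0 - rate)
    return x * Tensor(mask)


# -- 3D convolution -------------------------------------------------------


def _im2col(xpad: np.ndarray, k: int, lo: int, hi: int) -> np.ndarray:
    """Column matrix for output rows ``lo:hi`` along the first spatial axis.

    ``xpad`` is one padded sample of shape (C, D1p, D2p, D3p); the result has
    shape ((hi-lo) * D2 * D3, C * k**3) where D2/D3 are the output sizes.
    """
    c = xpad.shape[0]
    win = np.lib.stride_tricks.sliding_window_view(
        xpad[:, lo : hi + k - 1], (k, k, k), axis=(1, 2, 3)
    )
    # win: (C, d1, D2, D3, k, k, k) -> (d1*D2*D3, C*k^3)
    win = win.transpose(1, 2, 3, 0, 4, 5, 6)
    return win.reshape(-1, c * k**3)


def _conv3d_raw(x: np.ndarray, w: np.ndarray, b: np.ndarray | None) -> np.ndarray:
    """Stride-1 "same" 3D correlation via chunked im2col + GEMM.

    x: (N, C, D1, D2, D3); w: (O, C, k, k, k); returns (N, O, D1, D2, D3).
    """
    n, c, d1, d2, d3 = x.shape
    o, _, k, _, _ = w.shape
    p = k // 2
    wmat = w.reshape(o, c * k**3).T  # (C*k^3, O)
    out = np.empty((n, o, d1, d2, d3), dtype=x.dtype)
    rows_per_slab = max(1, _COL_BUDGET_BYTES // (c * k**3 * d2 * d3 * x.itemsize))
    for i in range(n):
        xpad = np.pad(x[i], ((0, 0), (p, p), (p, p), (p, p)))
        for lo in range(0, d1, rows_per_slab):
            hi = min(lo + rows_per_slab, d1)
            col = _im2col(xpad, k, lo, hi)
            res = col @ wmat  # (rows, O)
            out[i, :, lo:hi] = res.reshape(hi - lo, d2, d3, o).transpose(3, 0, 1, 2)
    if b is not None:
        out += b.reshape(1, o, 1, 1, 1)
    return out


def _conv3d_grad_w(x: np.ndarray, gout: np.ndarray, k: int) -> np.ndarray:
    """dL/dW for the stride-1 same convolution."""
    n, c, d1, d2, d3 = x.shape
    o = gout.shape[1]
    p = k // 2
    dw = np.zeros((o, c * k**3), dtype=x.dtype)
    rows_per_slab = max(1, _COL_BUDGET_BYTES // (c * k**3 * d2 * d3 * x.itemsize))
    for i in range(n):
        xpad = np.pad(x[i], ((0, 0), (p, p), (p, p), (p, p)))
        for lo in range(0, d1, rows_per_slab):
            hi = min(lo + rows_per_slab, d1)
            col = _im2col(xpad, k, lo, hi)
            gslab = gout[i, :, lo:hi].reshape(o, -1)  # (O, rows)
            dw += gslab @ col
    return dw.reshape(o, c, k, k, k)


def conv3d(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """3D convolution, stride 1, zero "same" padding, odd kernel."""
    bt = b

    def backward(g):
        if bt is not None and bt.requires_grad:
            bt._accum(g.sum(axis=(0, 2, 3, 4)))
        if w.requires_grad:
            w._accum(_conv3d_grad_w(x.data, g, w.data.shape[2]))
        if x.requires_grad:
            # dx is the same-padded correlation of g with flipped kernels,
            # with in/out channel roles swapped.
            wflip = w.data[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
            x._accum(_conv3d_raw(g, np.ascontiguousarray(wflip), None))

    parents = (x, w) if bt is None else (x, w, bt)
    return Tensor._make(
        _conv3d_raw(x.data, w.data, None if bt is None else bt.data),
        parents,
        backward,
    )


# -- pooling ---------------------------------------------------------------


def maxpool3d(x: Tensor) -> Tensor:
    """2x2x2 max pooling with stride 2; odd trailing voxels are cropped."""
    n, c, d1, d2, d3 = x.data.shape
    m1, m2, m3 = d1 // 2, d2 // 2, d3 // 2
    xc = x.data[:, :, : 2 * m1, : 2 * m2, : 2 * m3]
    blocks = xc.reshape(n, c, m1, 2, m2, 2, m3, 2)
    out_data = blocks.max(axis=(3, 5, 7))

    def backward(g):
        if not x.requires_grad:
            return
        mask = blocks == out_data[:, :, :, None, :, None, :, None]
        gb = mask * g[:, :, :, None, :, None, :, None]
        full = np.zeros_like(x.data)
        full[:, :, : 2 * m1, : 2 * m2, : 2 * m3] = gb.reshape(
            n, c, 2 * m1, 2 * m2, 2 * m3
        )
        x._accum(full)

    return Tensor._make(out_data, (x,), backward)


def pool_bin_edges(size: int, bins: int) -> np.ndarray:
    """Left-closed bin edges used by adaptive pooling: floor(i * size / bins).

    The final edge is ``size`` so remainder voxels fall in the last bin and
    the bins tile the axis exactly.
    """
    if bins > size:
        raise ValueError(f"cannot split axis of size {size} into {bins} bins")
    return np.array([(i * size) // bins for i in range(bins)] + [size])


def adaptive_maxpool3d(x: Tensor, out_shape: tuple[int, int, int]) -> Tensor:
    """Max pooling onto a fixed output grid with floor-partition bins."""
    n, c, d1, d2, d3 = x.data.shape
    t1, t2, t3 = out_shape
    e1, e2, e3 = pool_bin_edges(d1, t1), pool_bin_edges(d2, t2), pool_bin_edges(d3, t3)
    out_data = np.empty((n, c, t1, t2, t3), dtype=x.data.dtype)
    argmax = np.empty((n, c, t1, t2, t3), dtype=np.int64)
    flat = x.data.reshape(n, c, -1)
    for i in range(t1):
        for j in range(t2):
            for l in range(t3):
                cell = x.data[:, :, e1[i] : e1[i + 1], e2[j] : e2[j + 1], e3[l] : e3[l + 1]]
                cf = cell.reshape(n, c, -1)
                am = cf.argmax(axis=2)
                out_data[:, :, i, j, l] = np.take_along_axis(
                    cf, am[:, :, None], axis=2
                )[:, :, 0]
                # recover flat voxel index within the full grid
                s2 = e2[j + 1] - e2[j]
                s3 = e3[l + 1] - e3[l]
                a1 = am // (s2 * s3) + e1[i]
                a2 = (am // s3) % s2 + e2[j]
                a3 = am % s3 + e3[l]
                argmax[:, :, i, j, l] = (a1 * d2 + a2) * d3 + a3

    def backward(g):
        if not x.requires_grad:
            return
        full = np.zeros((n, c, d1 * d2 * d3), dtype=x.data.dtype)
        gi = g.reshape(n, c, -1)
        ai = argmax.reshape(n, c, -1)
        for b_ in range(n):
            for ch in range(c):
                np.add.at(full[b_, ch], ai[b_, ch], gi[b_, ch])
        x._accum(full.reshape(x.data.shape))

    del flat
    return Tensor._make(out_data, (x,), backward)


# -- batch normalization ---------------------------------------------------


def batchnorm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalization over (batch, spatial) axes.

    ``running_mean``/``running_var`` are plain arrays owned by the calling
    module and are updated in place during training.
    """
    c = x.data.shape[1]
    axes = (0,) + tuple(range(2, x.data.ndim))
    bshape = (1, c) + (1,) * (x.data.ndim - 2)
    if training:
        mean = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    invstd = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean.reshape(bshape)) * invstd.reshape(bshape)
    out_data = gamma.data.reshape(bshape) * xhat + beta.data.reshape(bshape)

    def backward(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta._accum(g.sum(axis=axes))
        if not x.requires_grad:
            return
        gx = g * gamma.data.reshape(bshape)
        if training:
            m = x.data.size // c
            s1 = gx.sum(axis=axes, keepdims=True)
            s2 = (gx * xhat).sum(axis=axes, keepdims=True)
            dx = (gx - s1 / m - xhat * s2 / m) * invstd.reshape(bshape)
        else:
            dx = gx * invstd.reshape(bshape)
        x._accum(dx)

    return Tensor._make(out_data, (x, gamma, beta), backward)
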