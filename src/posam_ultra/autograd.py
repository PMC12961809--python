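"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine provides exactly the operations the segmentation network needs:
broadcast-aware arithmetic, reductions, 2-D convolution (im2col), batch
normalization, max/average pooling, bilinear resampling, concatenation and
channel dropout.  All tensors are float64 ``N x C x H x W`` (or any shape for
pointwise ops); gradients are accumulated by topological traversal of the
recorded graph, micrograd-style.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "conv2d",
    "maxpool2d",
    "avgpool2d",
    "global_avg_pool",
    "global_max_pool",
    "channel_mean",
    "channel_max",
    "upsample_bilinear",
    "dropout2d",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents = _parents
        self._backward = _backward

    # -- basic protocol ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autodiff ----------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, visited = [], set()

        def build(t):
            if id(t) in visited:
                return
            visited.add(id(t))
            for p in t._parents:
                build(p)
            topo.append(t)

        build(self)
        for t in topo:
            t.grad = None
        self.grad = np.asarray(grad, dtype=np.float64)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, grad):
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bwd(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bwd(g):
            self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def bwd(g):
            self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            other._accumulate(
                _unbroadcast(-g * self.data / other.data**2, other.data.shape)
            )

        out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, _parents=(self,))

        def bwd(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def bwd(g):
            self._accumulate(_unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.data.shape))
            other._accumulate(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.data.shape))

        out._backward = bwd
        return out

    # -- pointwise nonlinearities -----------------------------------------
    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _parents=(self,))
        mask = self.data > 0

        def bwd(g):
            self._accumulate(g * mask)

        out._backward = bwd
        return out

    def sigmoid(self):
        x = np.clip(self.data, -60.0, 60.0)
        y = 1.0 / (1.0 + np.exp(-x))
        out = Tensor(y, _parents=(self,))

        def bwd(g):
            self._accumulate(g * y * (1.0 - y))

        out._backward = bwd
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))

        def bwd(g):
            self._accumulate(g / self.data)

        out._backward = bwd
        return out

    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, _parents=(self,))

        def bwd(g):
            self._accumulate(g * y)

        out._backward = bwd
        return out

    def clip(self, lo: float, hi: float):
        out = Tensor(np.clip(self.data, lo, hi), _parents=(self,))
        mask = (self.data >= lo) & (self.data <= hi)

        def bwd(g):
            self._accumulate(g * mask)

        out._backward = bwd
        return out

    # -- reductions & reshaping -------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def bwd(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False):
        idx = np.argmax(self.data, axis=axis)
        val = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis)
        out = Tensor(val if keepdims else np.squeeze(val, axis), _parents=(self,))

        def bwd(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            dx = np.zeros_like(self.data)
            np.put_along_axis(dx, np.expand_dims(idx, axis), g, axis)
            self._accumulate(dx)

        out._backward = bwd
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _parents=(self,))

        def bwd(g):
            self._accumulate(g.reshape(self.data.shape))

        out._backward = bwd
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], _parents=(self,))

        def bwd(g):
            dx = np.zeros_like(self.data)
            np.add.at(dx, key, g)
            self._accumulate(dx)

        out._backward = bwd
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- structural ops --------------------------------------------------------

def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            t._accumulate(g[tuple(sl)])

    out._backward = bwd
    return out


# -- convolution -----------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (w + 2 * pad - kw) // stride + 1
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    cols = np.empty((n, c, kh, kw, oh, ow), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride]
    return cols, oh, ow


def _col2im(dcols: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x_shape
    oh, ow = dcols.shape[-2:]
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += dcols[:, :, i, j]
    return dxp[:, :, pad : pad + h, pad : pad + w] if pad else dxp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation, weight shaped ``(C_out, C_in, kh, kw)``."""
    x, weight = as_tensor(x), as_tensor(weight)
    co, ci, kh, kw = weight.shape
    if x.shape[1] != ci:
        raise ValueError(f"conv2d: expected {ci} input channels, got {x.shape[1]}")
    cols, oh, ow = _im2col(x.data, kh, kw, stride, padding)
    n = x.shape[0]
    cols2 = cols.reshape(n, ci * kh * kw, oh * ow)
    wmat = weight.data.reshape(co, ci * kh * kw)
    out_data = np.matmul(wmat[None], cols2).reshape(n, co, oh, ow)
    parents = (x, weight) if bias is None else (x, weight, bias)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, co, 1, 1)
    out = Tensor(out_data, _parents=parents)

    def bwd(g):
        gmat = g.reshape(n, co, oh * ow)
        dw = np.matmul(gmat, cols2.transpose(0, 2, 1)).sum(axis=0).reshape(weight.shape)
        weight._accumulate(dw)
        if bias is not None:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        dcols = np.matmul(wmat.T[None], gmat).reshape(n, ci, kh, kw, oh, ow)
        x._accumulate(_col2im(dcols, x.shape, kh, kw, stride, padding))

    out._backward = bwd
    return out


# -- pooling ---------------------------------------------------------------

def maxpool2d(x: Tensor, k: int = 2) -> Tensor:
    x = as_tensor(x)
    n, c, h, w = x.shape
    if h % k or w % k:
        raise ValueError(f"maxpool2d: spatial dims must be divisible by {k}")
    oh, ow = h // k, w // k
    xr = x.data.reshape(n, c, oh, k, ow, k).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, oh, ow, k * k)
    idx = np.argmax(xr, axis=-1)
    out = Tensor(np.take_along_axis(xr, idx[..., None], -1)[..., 0], _parents=(x,))

    def bwd(g):
        dxr = np.zeros_like(xr)
        np.put_along_axis(dxr, idx[..., None], g[..., None], -1)
        dx = dxr.reshape(n, c, oh, ow, k, k).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
        x._accumulate(dx)

    out._backward = bwd
    return out


def avgpool2d(x: Tensor, k: int) -> Tensor:
    x = as_tensor(x)
    n, c, h, w = x.shape
    if h % k or w % k:
        raise ValueError(f"avgpool2d: spatial dims must be divisible by {k}")
    oh, ow = h // k, w // k
    out = Tensor(x.data.reshape(n, c, oh, k, ow, k).mean(axis=(3, 5)), _parents=(x,))

    def bwd(g):
        dx = np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k)
        x._accumulate(dx)

    out._backward = bwd
    return out


def global_avg_pool(x: Tensor) -> Tensor:
    return x.mean(axis=(2, 3), keepdims=True)


def global_max_pool(x: Tensor) -> Tensor:
    n, c, h, w = x.shape
    return x.reshape(n, c, h * w).max(axis=2, keepdims=True).reshape(n, c, 1, 1)


def channel_mean(x: Tensor) -> Tensor:
    return x.mean(axis=1, keepdims=True)


def channel_max(x: Tensor) -> Tensor:
    return x.max(axis=1, keepdims=True)


# -- bilinear resampling ---------------------------------------------------

_INTERP_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Dense 1-D bilinear interpolation operator (half-pixel centres)."""
    key = (n_in, n_out)
    if key in _INTERP_CACHE:
        return _INTERP_CACHE[key]
    a = np.zeros((n_out, n_in))
    scale = n_in / n_out
    for o in range(n_out):
        src = (o + 0.5) * scale - 0.5
        i0 = int(np.floor(src))
        t = src - i0
        i0c = min(max(i0, 0), n_in - 1)
        i1c = min(max(i0 + 1, 0), n_in - 1)
        a[o, i0c] += 1.0 - t
        a[o, i1c] += t
    _INTERP_CACHE[key] = a
    return a


def upsample_bilinear(x: Tensor, size: tuple[int, int]) -> Tensor:
    """Bilinear resample to ``size`` (works for down- as well as up-sampling)."""
    x = as_tensor(x)
    n, c, h, w = x.shape
    oh, ow = size
    if (oh, ow) == (h, w):
        return x
    ar = _interp_matrix(h, oh)       # (oh, h)
    ac = _interp_matrix(w, ow)       # (ow, w)
    y = np.einsum("oh,nchw,pw->ncop", ar, x.data, ac, optimize=True)
    out = Tensor(y, _parents=(x,))

    def bwd(g):
        dx = np.einsum("oh,ncop,pw->nchw", ar, g, ac, optimize=True)
        x._accumulate(dx)

    out._backward = bwd
    return out


def dropout2d(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Channel dropout: zero whole feature maps with probability ``p``."""
    if not training or p <= 0.0:
        return as_tensor(x)
    x = as_tensor(x)
    n, c = x.shape[:2]
    keep = rng.random((n, c, 1, 1)) >= p
    scale = keep / (1.0 - p)
    return x * Tensor(scale)
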