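"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the primitives a 3D encoder/decoder segmentation
network needs: broadcasting arithmetic, matmul, reductions, ReLU /
sigmoid / channel softmax, strided 3D convolution and transposed
convolution, 2x average pooling, 2x trilinear upsampling, truncated
box-window summation (the guided-filter workhorse) and inverted
dropout, plus an Adam optimizer.

Arrays are laid out channels-last: ``(batch, depth, height, width,
channels)``. Gradients are accumulated by a topological backward sweep
over the tape recorded during the forward pass.
"""

from __future__ import annotations

from itertools import product as _iproduct
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import ndimage as _ndi

__all__ = [
    "Tensor",
    "wrap",
    "relu",
    "sigmoid",
    "exp",
    "log",
    "tsum",
    "tmean",
    "reshape",
    "concat",
    "softmax",
    "dropout",
    "conv3d",
    "conv_transpose3d",
    "avg_pool3d",
    "upsample_trilinear3d",
    "boxsum3d",
    "boxsum3d_np",
    "Adam",
]


class Tensor:
    """A numpy array plus the tape metadata needed for backprop."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: Sequence["Tensor"] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data)
        self.requires_grad = bool(
            requires_grad or any(p.requires_grad for p in parents)
        )
        self.grad: np.ndarray | None = None
        self._parents = tuple(parents)
        self._backward = backward

    # -- bookkeeping ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def zero_grad(self) -> None:
        self.grad = None

    def accumulate(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node through the recorded tape."""
        if grad is None:
            grad = np.ones_like(self.data)
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; deep nets overflow recursion limits
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.accumulate(grad)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar ------------------------------------------------
    def __add__(self, other):
        return _add(self, wrap(other))

    __radd__ = __add__

    def __mul__(self, other):
        return _mul(self, wrap(other))

    __rmul__ = __mul__

    def __sub__(self, other):
        return _add(self, _neg(wrap(other)))

    def __rsub__(self, other):
        return _add(wrap(other), _neg(self))

    def __neg__(self):
        return _neg(self)

    def __truediv__(self, other):
        return _div(self, wrap(other))

    def __rtruediv__(self, other):
        return _div(wrap(other), self)

    def __pow__(self, k):
        return _pow(self, float(k))

    def __matmul__(self, other):
        return matmul(self, wrap(other))

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def wrap(x) -> Tensor:
    """Lift a plain array/scalar into a constant Tensor."""
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------
# elementwise / linear algebra
# ---------------------------------------------------------------------

def _add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, parents=(a, b))

    def bw(g):
        a.accumulate(_unbroadcast(g, a.data.shape))
        b.accumulate(_unbroadcast(g, b.data.shape))

    out._backward = bw
    return out


def _neg(a: Tensor) -> Tensor:
    out = Tensor(-a.data, parents=(a,))
    out._backward = lambda g: a.accumulate(-g)
    return out


def _mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, parents=(a, b))

    def bw(g):
        a.accumulate(_unbroadcast(g * b.data, a.data.shape))
        b.accumulate(_unbroadcast(g * a.data, b.data.shape))

    out._backward = bw
    return out


def _div(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data / b.data, parents=(a, b))

    def bw(g):
        a.accumulate(_unbroadcast(g / b.data, a.data.shape))
        b.accumulate(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

    out._backward = bw
    return out


def _pow(a: Tensor, k: float) -> Tensor:
    out = Tensor(a.data**k, parents=(a,))
    out._backward = lambda g: a.accumulate(g * k * a.data ** (k - 1.0))
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """a (..., n, k) @ b (k, m); the right operand must be a matrix."""
    if b.data.ndim != 2:
        raise ValueError("matmul right operand must be 2-D")
    out = Tensor(a.data @ b.data, parents=(a, b))

    def bw(g):
        a.accumulate(g @ b.data.T)
        lead = list(range(a.data.ndim - 1))
        b.accumulate(np.tensordot(a.data, g, axes=(lead, lead)))

    out._backward = bw
    return out


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    out = Tensor(np.where(mask, a.data, 0.0), parents=(a,))
    out._backward = lambda g: a.accumulate(g * mask)
    return out


def sigmoid(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-a.data))
    out = Tensor(s, parents=(a,))
    out._backward = lambda g: a.accumulate(g * s * (1.0 - s))
    return out


def exp(a: Tensor) -> Tensor:
    e = np.exp(a.data)
    out = Tensor(e, parents=(a,))
    out._backward = lambda g: a.accumulate(g * e)
    return out


def log(a: Tensor) -> Tensor:
    out = Tensor(np.log(a.data), parents=(a,))
    out._backward = lambda g: a.accumulate(g / a.data)
    return out


def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out = Tensor(a.data.sum(axis=axis, keepdims=keepdims), parents=(a,))

    def bw(g):
        if axis is None:
            a.accumulate(np.broadcast_to(g, a.data.shape))
            return
        if not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            g = np.expand_dims(g, tuple(ax % a.data.ndim for ax in axes))
        a.accumulate(np.broadcast_to(g, a.data.shape))

    out._backward = bw
    return out


def tmean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return tsum(a, axis=axis, keepdims=keepdims) * (1.0 / float(n))


def reshape(a: Tensor, shape: tuple[int, ...]) -> Tensor:
    out = Tensor(a.data.reshape(shape), parents=(a,))
    out._backward = lambda g: a.accumulate(g.reshape(a.data.shape))
    return out


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    ts = [wrap(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in ts], axis=axis), parents=ts)
    sizes = [t.data.shape[axis] for t in ts]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(ts, np.split(g, splits, axis=axis)):
            t.accumulate(piece)

    out._backward = bw
    return out


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    x = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(x)
    p = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(p, parents=(a,))

    def bw(g):
        dot = (g * p).sum(axis=axis, keepdims=True)
        a.accumulate(p * (g - dot))

    out._backward = bw
    return out


def dropout(a: Tensor, rate: float, rng: np.random.Generator,
            training: bool = True) -> Tensor:
    """Inverted dropout: at eval time (or rate 0) a no-op."""
    if not training or rate <= 0.0:
        return a
    keep = 1.0 - rate
    mask = (rng.random(a.data.shape) < keep).astype(a.data.dtype) / keep
    out = Tensor(a.data * mask, parents=(a,))
    out._backward = lambda g: a.accumulate(g * mask)
    return out


# ---------------------------------------------------------------------
# 3D convolution primitives (channels-last)
# ---------------------------------------------------------------------

def _conv_out_len(i: int, k: int, s: int, p: int) -> int:
    return (i + 2 * p - k) // s + 1


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 1) -> Tensor:
    """3D convolution, x (N,D,H,W,Ci), w (kd,kh,kw,Ci,Co).

    Implemented as a sum over kernel offsets of strided-slice matmuls,
    which keeps both directions exact and reasonably fast in numpy.
    """
    N, D, H, W, Ci = x.data.shape
    kd, kh, kw, Ci2, Co = w.data.shape
    if Ci != Ci2:
        raise ValueError(f"channel mismatch: input {Ci}, kernel {Ci2}")
    s, p = stride, padding
    Do, Ho, Wo = (_conv_out_len(n, k, s, p) for n, k in ((D, kd), (H, kh), (W, kw)))
    xp = np.pad(x.data, ((0, 0), (p, p), (p, p), (p, p), (0, 0))) if p else x.data
    out_data = np.zeros((N, Do, Ho, Wo, Co), dtype=x.data.dtype)
    for dz, dy, dx in _iproduct(range(kd), range(kh), range(kw)):
        xs = xp[:, dz:dz + s * Do:s, dy:dy + s * Ho:s, dx:dx + s * Wo:s, :]
        out_data += np.tensordot(xs, w.data[dz, dy, dx], axes=([4], [0]))
    if b is not None:
        out_data += b.data
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, parents=parents)

    def bw(g):
        if b is not None:
            b.accumulate(g.sum(axis=(0, 1, 2, 3)))
        gxp = np.zeros_like(xp) if x.requires_grad else None
        for dz, dy, dx in _iproduct(range(kd), range(kh), range(kw)):
            xs = xp[:, dz:dz + s * Do:s, dy:dy + s * Ho:s, dx:dx + s * Wo:s, :]
            if w.requires_grad:
                gw = np.tensordot(xs, g, axes=([0, 1, 2, 3], [0, 1, 2, 3]))
                if w.grad is None:
                    w.grad = np.zeros_like(w.data)
                w.grad[dz, dy, dx] += gw
            if gxp is not None:
                gxp[:, dz:dz + s * Do:s, dy:dy + s * Ho:s, dx:dx + s * Wo:s, :] += (
                    np.tensordot(g, w.data[dz, dy, dx], axes=([4], [1]))
                )
        if gxp is not None:
            x.accumulate(gxp[:, p:p + D, p:p + H, p:p + W, :] if p else gxp)

    out._backward = bw
    return out


def conv_transpose3d(x: Tensor, w: Tensor, b: Tensor | None = None,
                     stride: int = 2, padding: int = 0,
                     output_padding: int = 0) -> Tensor:
    """Transposed 3D convolution, w (kd,kh,kw,Ci,Co).

    Output length per axis: s*(i-1) + k - 2p + output_padding.
    """
    N, D, H, W, Ci = x.data.shape
    kd, kh, kw, Ci2, Co = w.data.shape
    if Ci != Ci2:
        raise ValueError(f"channel mismatch: input {Ci}, kernel {Ci2}")
    s, p, op = stride, padding, output_padding
    full = np.zeros(
        (N, s * (D - 1) + kd, s * (H - 1) + kh, s * (W - 1) + kw, Co),
        dtype=x.data.dtype,
    )
    for dz, dy, dx in _iproduct(range(kd), range(kh), range(kw)):
        full[:, dz:dz + s * D:s, dy:dy + s * H:s, dx:dx + s * W:s, :] += (
            np.tensordot(x.data, w.data[dz, dy, dx], axes=([4], [0]))
        )
    lims = [full.shape[ax + 1] - max(p - op, 0) for ax in range(3)]
    out_data = full[:, p:lims[0], p:lims[1], p:lims[2], :]
    if b is not None:
        out_data = out_data + b.data
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, parents=parents)

    def bw(g):
        if b is not None:
            b.accumulate(g.sum(axis=(0, 1, 2, 3)))
        gfull = np.zeros_like(full)
        gfull[:, p:lims[0], p:lims[1], p:lims[2], :] = g
        for dz, dy, dx in _iproduct(range(kd), range(kh), range(kw)):
            gs = gfull[:, dz:dz + s * D:s, dy:dy + s * H:s, dx:dx + s * W:s, :]
            if w.requires_grad:
                gw = np.tensordot(x.data, gs, axes=([0, 1, 2, 3], [0, 1, 2, 3]))
                if w.grad is None:
                    w.grad = np.zeros_like(w.data)
                w.grad[dz, dy, dx] += gw
            if x.requires_grad:
                x.accumulate(np.tensordot(gs, w.data[dz, dy, dx], axes=([4], [1])))

    out._backward = bw
    return out


def avg_pool3d(x: Tensor, factor: int = 2) -> Tensor:
    """Non-overlapping average pooling over the three spatial axes."""
    N, D, H, W, C = x.data.shape
    f = factor
    if D % f or H % f or W % f:
        raise ValueError(f"spatial dims {(D, H, W)} not divisible by {f}")
    r = x.data.reshape(N, D // f, f, H // f, f, W // f, f, C)
    out = Tensor(r.mean(axis=(2, 4, 6)), parents=(x,))

    def bw(g):
        ge = g[:, :, None, :, None, :, None, :] / float(f**3)
        x.accumulate(np.broadcast_to(
            ge, (N, D // f, f, H // f, f, W // f, f, C)).reshape(x.data.shape))

    out._backward = bw
    return out


def _linear_up_axis(x: Tensor, axis: int) -> Tensor:
    """Double one axis by linear interpolation (half-pixel centers)."""
    n = x.data.shape[axis]
    src = np.arange(2 * n) / 2.0 - 0.25
    i0 = np.floor(src).astype(np.intp)
    t = (src - i0).astype(x.data.dtype)
    i1 = np.clip(i0 + 1, 0, n - 1)
    i0 = np.clip(i0, 0, n - 1)
    x0 = np.take(x.data, i0, axis=axis)
    x1 = np.take(x.data, i1, axis=axis)
    sh = [1] * x.data.ndim
    sh[axis] = 2 * n
    w1 = t.reshape(sh)
    w0 = (1.0 - t).reshape(sh)
    out = Tensor(w0 * x0 + w1 * x1, parents=(x,))

    def bw(g):
        g0 = np.moveaxis(g, axis, 0)
        gx = np.zeros(np.moveaxis(x.data, axis, 0).shape, dtype=x.data.dtype)
        wcol0 = (1.0 - t).reshape((2 * n,) + (1,) * (g0.ndim - 1))
        wcol1 = t.reshape((2 * n,) + (1,) * (g0.ndim - 1))
        np.add.at(gx, i0, g0 * wcol0)
        np.add.at(gx, i1, g0 * wcol1)
        x.accumulate(np.moveaxis(gx, 0, axis))

    out._backward = bw
    return out


def upsample_trilinear3d(x: Tensor, factor: int = 2) -> Tensor:
    """Trilinear 2x upsampling of the spatial axes (applied per axis)."""
    if factor == 1:
        return x
    if factor % 2:
        raise ValueError("only powers of two supported")
    out = x
    f = factor
    while f > 1:
        for ax in (1, 2, 3):
            out = _linear_up_axis(out, ax)
        f //= 2
    return out


def boxsum3d_np(x: np.ndarray, radius: int) -> np.ndarray:
    """Sum over the (2r+1)^3 window around each voxel, truncated at the
    array border (out-of-bounds contributes zero). Spatial axes are the
    middle three of a rank-5 array; rank-3 arrays are handled directly."""
    size = 2 * radius + 1
    if x.ndim == 3:
        sz: tuple[int, ...] = (size, size, size)
    elif x.ndim == 5:
        sz = (1, size, size, size, 1)
    else:
        raise ValueError("expected rank-3 or rank-5 array")
    out = _ndi.uniform_filter(x, size=sz, mode="constant", cval=0.0)
    return out * float(size**3)


def boxsum3d(x: Tensor, radius: int) -> Tensor:
    """Autodiff truncated box-window sum; the operator is self-adjoint."""
    out = Tensor(boxsum3d_np(x.data, radius), parents=(x,))
    out._backward = lambda g: x.accumulate(boxsum3d_np(g, radius))
    return out


# ---------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------

class Adam:
    """Standard Adam with bias correction over a list of Tensors."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * (g * g)
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def state_dict(self) -> dict:
        return {
            "t": self.t,
            "m": [m.copy() for m in self.m],
            "v": [v.copy() for v in self.v],
            "lr": self.lr,
        }

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        self.m = [np.array(m) for m in state["m"]]
        self.v = [np.array(v) for v in state["v"]]
        self.lr = float(state["lr"])
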