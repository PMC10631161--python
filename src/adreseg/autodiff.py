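"""Reverse-mode tensor autodiff core.

A deliberately small engine: a :class:`Tensor` wraps a NumPy array and a
closure that propagates the upstream gradient to its parents.  Only the
operations needed by the segmentation network are provided — elementwise
arithmetic with broadcasting, matrix products, reshapes, activations,
softmax, feature standardisation (the shared kernel of layer/group norm),
dropout, and three fused volumetric convolution primitives (depthwise,
pointwise and 2x2x2 transposed convolution).

Convolutions are expressed as a short sum of strided-slice multiply-adds,
which keeps both the forward and the backward pass in vectorised NumPy with
no im2col buffers; for the kernel sizes used here (3 and 2) this is fast
and exactly differentiable.
"""

from __future__ import annotations

from itertools import product
import numpy as np

__all__ = [
    "Tensor",
    "parameter",
    "concat",
    "matmul",
    "relu",
    "gelu",
    "sigmoid",
    "softmax",
    "standardize",
    "dropout",
    "depthwise_conv3d",
    "pointwise_conv3d",
    "conv_transpose3d_2x",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents: tuple = (), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- introspection -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autograd ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node (default seed: ones)."""
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out_data = self.data + other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accumulate(-g)

        return Tensor(-self.data, parents=(self,), backward=bw)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out_data = self.data * other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out_data = self.data / other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(-g * self.data / (other.data ** 2), other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=bw)

    def __matmul__(self, other):
        return matmul(self, other)

    # -- shape ---------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out_data = self.data.reshape(shape)

        def bw(g):
            self._accumulate(g.reshape(orig))

        return Tensor(out_data, parents=(self,), backward=bw)

    def permute(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out_data = np.transpose(self.data, axes)

        def bw(g):
            self._accumulate(np.transpose(g, inv))

        return Tensor(out_data, parents=(self,), backward=bw)

    def swap_last2(self):
        axes = list(range(self.ndim))
        axes[-1], axes[-2] = axes[-2], axes[-1]
        return self.permute(*axes)

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accumulate(np.broadcast_to(gg, self.data.shape).astype(self.data.dtype))

        return Tensor(out_data, parents=(self,), backward=bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod([self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def parameter(data: np.ndarray) -> Tensor:
    """Wrap an array as a trainable leaf tensor."""
    return Tensor(np.asarray(data, dtype=np.float32), requires_grad=True)


def concat(tensors: Sequence[Tensor], axis: int) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accumulate(p)

    return Tensor(out_data, parents=tuple(tensors), backward=bw)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = np.matmul(a.data, b.data)

    def bw(g):
        if a.requires_grad:
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            a._accumulate(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            b._accumulate(_unbroadcast(gb, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=bw)


# ---------------------------------------------------------------------
# activations
# ---------------------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out_data = np.where(mask, x.data, 0.0).astype(x.data.dtype)

    def bw(g):
        x._accumulate(g * mask)

    return Tensor(out_data, parents=(x,), backward=bw)


_SQRT_2_OVER_PI = np.float32(np.sqrt(2.0 / np.pi))


def gelu(x: Tensor) -> Tensor:
    """Gaussian error linear unit (tanh approximation)."""
    d = x.data
    inner = _SQRT_2_OVER_PI * (d + 0.044715 * d ** 3)
    t = np.tanh(inner)
    out_data = 0.5 * d * (1.0 + t)

    def bw(g):
        dinner = _SQRT_2_OVER_PI * (1.0 + 3 * 0.044715 * d ** 2)
        grad = 0.5 * (1.0 + t) + 0.5 * d * (1.0 - t ** 2) * dinner
        x._accumulate(g * grad.astype(d.dtype))

    return Tensor(out_data, parents=(x,), backward=bw)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))

    def bw(g):
        x._accumulate(g * s * (1.0 - s))

    return Tensor(s.astype(x.data.dtype), parents=(x,), backward=bw)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    e = np.exp(x.data - m)
    s = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        x._accumulate(s * (g - dot))

    return Tensor(s.astype(x.data.dtype), parents=(x,), backward=bw)


def standardize(x: Tensor, axes: tuple[int, ...], eps: float = 1e-5) -> Tensor:
    """(x - mean) / sqrt(var + eps) over ``axes`` — the core of layer/group norm."""
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    n = float(np.prod([x.data.shape[a] for a in axes]))

    def bw(g):
        gsum = g.mean(axis=axes, keepdims=True)
        gxhat = (g * xhat).mean(axis=axes, keepdims=True)
        x._accumulate((inv * (g - gsum - xhat * gxhat)).astype(x.data.dtype))

    return Tensor(xhat.astype(x.data.dtype), parents=(x,), backward=bw)


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    keep = (rng.random(x.data.shape) >= p).astype(x.data.dtype)
    scale = np.float32(1.0 / (1.0 - p))
    mask = keep * scale

    def bw(g):
        x._accumulate(g * mask)

    return Tensor(x.data * mask, parents=(x,), backward=bw)


# ---------------------------------------------------------------------
# volumetric convolution primitives
# ---------------------------------------------------------------------

def _out_len(n: int, k: int, p: int, s: int) -> int:
    return (n + 2 * p - k) // s + 1


try:  # jitted hot loops; the numpy tap-loop below remains the reference path
    import numba as _nb

    @_nb.njit(fastmath=True, cache=True)
    def _dw3_fwd(x, w, s, out):  # pragma: no cover - exercised via depthwise_conv3d
        B, C, OX, OY, OZ = out.shape
        X, Y, Z = x.shape[2], x.shape[3], x.shape[4]
        for b in range(B):
            for c in range(C):
                for i in range(OX):
                    for j in range(OY):
                        for l in range(OZ):
                            acc = np.float32(0.0)
                            for di in range(3):
                                ii = i * s + di - 1
                                if ii < 0 or ii >= X:
                                    continue
                                for dj in range(3):
                                    jj = j * s + dj - 1
                                    if jj < 0 or jj >= Y:
                                        continue
                                    for dl in range(3):
                                        ll = l * s + dl - 1
                                        if ll < 0 or ll >= Z:
                                            continue
                                        acc += x[b, c, ii, jj, ll] * w[c, di, dj, dl]
                            out[b, c, i, j, l] = acc

    @_nb.njit(fastmath=True, cache=True)
    def _dw3_bwd(x, w, g, s, gx, gw, need_gx, need_gw):  # pragma: no cover
        B, C, OX, OY, OZ = g.shape
        X, Y, Z = x.shape[2], x.shape[3], x.shape[4]
        for b in range(B):
            for c in range(C):
                for i in range(OX):
                    for j in range(OY):
                        for l in range(OZ):
                            gv = g[b, c, i, j, l]
                            for di in range(3):
                                ii = i * s + di - 1
                                if ii < 0 or ii >= X:
                                    continue
                                for dj in range(3):
                                    jj = j * s + dj - 1
                                    if jj < 0 or jj >= Y:
                                        continue
                                    for dl in range(3):
                                        ll = l * s + dl - 1
                                        if ll < 0 or ll >= Z:
                                            continue
                                        if need_gx:
                                            gx[b, c, ii, jj, ll] += w[c, di, dj, dl] * gv
                                        if need_gw:
                                            gw[c, di, dj, dl] += x[b, c, ii, jj, ll] * gv

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def depthwise_conv3d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1) -> Tensor:
    """Per-channel 3D convolution, kernel k, 'same' zero padding p=(k-1)//2.

    x: (B, C, X, Y, Z); w: (C, k, k, k); b: (C,) or None.
    """
    B, C, X, Y, Z = x.data.shape
    k = w.data.shape[1]
    p = (k - 1) // 2
    s = stride
    ox, oy, oz = _out_len(X, k, p, s), _out_len(Y, k, p, s), _out_len(Z, k, p, s)
    fast = _HAVE_NUMBA and k == 3
    if fast:
        out = np.empty((B, C, ox, oy, oz), dtype=np.float32)
        _dw3_fwd(x.data, w.data, s, out)
        xp = None
    else:
        xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        out = np.zeros((B, C, ox, oy, oz), dtype=x.data.dtype)
        for i, j, l in product(range(k), range(k), range(k)):
            sl = xp[:, :, i : i + s * ox : s, j : j + s * oy : s, l : l + s * oz : s]
            out += w.data[:, i, j, l][None, :, None, None, None] * sl
    if b is not None:
        out += b.data[None, :, None, None, None]

    def bw(g):
        g = np.ascontiguousarray(g, dtype=np.float32)
        if fast:
            gx = np.zeros_like(x.data) if x.requires_grad else np.empty((1, 1, 1, 1, 1), np.float32)
            gw = np.zeros_like(w.data) if w.requires_grad else np.empty((1, 3, 3, 3), np.float32)
            _dw3_bwd(x.data, w.data, g, s, gx, gw, x.requires_grad, w.requires_grad)
            if x.requires_grad:
                x._accumulate(gx)
            if w.requires_grad:
                w._accumulate(gw)
        else:
            if x.requires_grad:
                gxp = np.zeros_like(xp)
                for i, j, l in product(range(k), range(k), range(k)):
                    gxp[:, :, i : i + s * ox : s, j : j + s * oy : s, l : l + s * oz : s] += (
                        w.data[:, i, j, l][None, :, None, None, None] * g
                    )
                x._accumulate(gxp[:, :, p : p + X, p : p + Y, p : p + Z])
            if w.requires_grad:
                gw = np.empty_like(w.data)
                for i, j, l in product(range(k), range(k), range(k)):
                    sl = xp[:, :, i : i + s * ox : s, j : j + s * oy : s, l : l + s * oz : s]
                    gw[:, i, j, l] = np.einsum("bcxyz,bcxyz->c", sl, g, optimize=True)
                w._accumulate(gw)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3, 4)))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out, parents=parents, backward=bw)


def pointwise_conv3d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """1x1x1 channel-mixing convolution.  x: (B, C, X, Y, Z); w: (C_out, C_in)."""
    B, C, X, Y, Z = x.data.shape
    xr = x.data.reshape(B, C, -1)
    out = np.matmul(w.data, xr)  # (B, C_out, V)
    if b is not None:
        out += b.data[None, :, None]
    out = out.reshape(B, -1, X, Y, Z)

    def bw(g):
        gr = g.reshape(B, g.shape[1], -1)
        if x.requires_grad:
            gx = np.matmul(w.data.T, gr).reshape(x.data.shape)
            x._accumulate(gx)
        if w.requires_grad:
            gw = np.einsum("bov,bcv->oc", gr, xr, optimize=True)
            w._accumulate(gw)
        if b is not None and b.requires_grad:
            b._accumulate(gr.sum(axis=(0, 2)))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out, parents=parents, backward=bw)


def conv_transpose3d_2x(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Transposed convolution, kernel 2, stride 2 (exact spatial doubling).

    x: (B, C_in, X, Y, Z); w: (C_in, C_out, 2, 2, 2).  Each output voxel
    receives exactly one input voxel through one kernel tap, so the op is a
    bank of eight channel-mixing products scattered on the doubled grid.
    """
    B, Ci, X, Y, Z = x.data.shape
    Co = w.data.shape[1]
    xr = x.data.reshape(B, Ci, -1)
    out = np.empty((B, Co, 2 * X, 2 * Y, 2 * Z), dtype=x.data.dtype)
    for i, j, l in product(range(2), range(2), range(2)):
        blk = np.matmul(w.data[:, :, i, j, l].T, xr).reshape(B, Co, X, Y, Z)
        out[:, :, i::2, j::2, l::2] = blk
    if b is not None:
        out += b.data[None, :, None, None, None]

    def bw(g):
        gx = np.zeros_like(x.data) if x.requires_grad else None
        gw = np.empty_like(w.data) if w.requires_grad else None
        for i, j, l in product(range(2), range(2), range(2)):
            gblk = g[:, :, i::2, j::2, l::2].reshape(B, Co, -1)
            if gx is not None:
                gx += np.matmul(w.data[:, :, i, j, l], gblk).reshape(x.data.shape)
            if gw is not None:
                gw[:, :, i, j, l] = np.einsum("bcv,bov->co", xr, gblk, optimize=True)
        if gx is not None:
            x._accumulate(gx)
        if gw is not None:
            w._accumulate(gw)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3, 4)))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out, parents=parents, backward=bw)
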