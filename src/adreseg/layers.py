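"""Neural-network building blocks on top of the autodiff core.

Contains the depthwise-separable convolution unit used throughout the
encoder/decoder, group/layer normalisation, the multi-head attention of
the transformer bottleneck, and the pre-norm transformer layer.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Module:
    """Minimal container: children and named parameters are discovered by
    attribute walk, in deterministic (insertion) order."""

    def parameters(self):
        """Yield ``(name, Tensor)`` pairs for all trainable leaves."""

        def walk(prefix, val):
            if isinstance(val, Tensor):
                if val.requires_grad:
                    yield prefix, val
            elif isinstance(val, Module):
                for sub, p in val.parameters():
                    yield f"{prefix}.{sub}", p
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    yield from walk(f"{prefix}.{i}", item)

        for attr, val in vars(self).items():
            yield from walk(attr, val)

    def param_count(self) -> int:
        return sum(p.size for _, p in self.parameters())

    def zero_grad(self) -> None:
        for _, p in self.parameters():
            p.zero_grad()


def _he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


def _xavier(rng: np.random.Generator, shape) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        self.w = ad.parameter(_xavier(rng, (d_in, d_out)))
        self.b = ad.parameter(np.zeros(d_out, np.float32)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = ad.matmul(x, self.w)
        if self.b is not None:
            out = out + self.b
        return out


class GroupNorm(Module):
    """Group normalisation over (channel-group, spatial) for (B,C,X,Y,Z) input.

    Chosen over batch norm because training uses batch size 2, where batch
    statistics are unreliable.
    """

    def __init__(self, channels: int, groups: int = 8, eps: float = 1e-5):
        if channels % min(groups, channels) != 0:
            groups = 1
        self.groups = min(groups, channels)
        self.eps = eps
        self.gamma = ad.parameter(np.ones((1, channels, 1, 1, 1), np.float32))
        self.beta = ad.parameter(np.zeros((1, channels, 1, 1, 1), np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        B, C, X, Y, Z = x.shape
        g = self.groups
        xg = x.reshape(B, g, C // g, X, Y, Z)
        xn = ad.standardize(xg, axes=(2, 3, 4, 5), eps=self.eps)
        return xn.reshape(B, C, X, Y, Z) * self.gamma + self.beta


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.eps = eps
        self.gamma = ad.parameter(np.ones(dim, np.float32))
        self.beta = ad.parameter(np.zeros(dim, np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        return ad.standardize(x, axes=(x.ndim - 1,), eps=self.eps) * self.gamma + self.beta


class DSConvUnit(Module):
    """Depthwise separable convolution unit: per-channel k=3 'same' spatial
    convolution, then a 1x1x1 pointwise channel mix, group norm, ReLU."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, norm: bool = True):
        k = 3
        self.dw = ad.parameter(_he_normal(rng, (c_in, k, k, k), fan_in=k ** 3))
        self.pw = ad.parameter(_he_normal(rng, (c_out, c_in), fan_in=c_in))
        self.bias = ad.parameter(np.zeros(c_out, np.float32))
        self.norm = GroupNorm(c_out) if norm else None

    def __call__(self, x: Tensor) -> Tensor:
        h = ad.depthwise_conv3d(x, self.dw)
        h = ad.pointwise_conv3d(h, self.pw, self.bias)
        if self.norm is not None:
            h = self.norm(h)
        return ad.relu(h)

    def conv_param_count(self) -> int:
        """Parameters of the separable convolution pair (bias excluded)."""
        return self.dw.size + self.pw.size


class Downsample(Module):
    """Stride-2 depthwise convolution halving each spatial dimension."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.dw = ad.parameter(_he_normal(rng, (channels, 3, 3, 3), fan_in=27))

    def __call__(self, x: Tensor) -> Tensor:
        return ad.depthwise_conv3d(x, self.dw, stride=2)


class Upsample(Module):
    """2x2x2 transposed convolution doubling spatial dims, c_in -> c_out."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.w = ad.parameter(_he_normal(rng, (c_in, c_out, 2, 2, 2), fan_in=c_in * 8))
        self.b = ad.parameter(np.zeros(c_out, np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv_transpose3d_2x(x, self.w, self.b)


class MultiHeadAttention(Module):
    """Scaled dot-product attention with ``n_heads`` parallel heads.

    head_h = softmax(Q W_h^Q (K W_h^K)^T / sqrt(d_k)) V W_h^V, and the
    concatenated heads go through one shared output projection W^O.  The
    per-head maps are stored as blocks of (d_model, d_model) matrices; the
    projections carry no bias, matching the linear maps of the attention
    formula.  After each forward pass ``attention_`` holds the row-stochastic
    attention weights, shape (B, heads, T, T).
    """

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        if d_model % n_heads != 0:
            raise ValueError(f"model dim {d_model} not divisible by {n_heads} heads")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.wq = ad.parameter(_xavier(rng, (d_model, d_model)))
        self.wk = ad.parameter(_xavier(rng, (d_model, d_model)))
        self.wv = ad.parameter(_xavier(rng, (d_model, d_model)))
        self.wo = ad.parameter(_xavier(rng, (d_model, d_model)))
        self.attention_: np.ndarray | None = None

    def _split(self, x: Tensor) -> Tensor:
        B, T, D = x.shape
        return x.reshape(B, T, self.n_heads, self.d_head).permute(0, 2, 1, 3)

    def __call__(self, q: Tensor, k: Tensor, v: Tensor) -> Tensor:
        B, T, D = q.shape
        qh = self._split(ad.matmul(q, self.wq))  # (B, H, T, d)
        kh = self._split(ad.matmul(k, self.wk))
        vh = self._split(ad.matmul(v, self.wv))
        scores = ad.matmul(qh, kh.swap_last2()) * (1.0 / np.sqrt(self.d_head))
        attn = ad.softmax(scores, axis=-1)
        self.attention_ = attn.data.copy()
        ctx = ad.matmul(attn, vh)  # (B, H, T, d)
        ctx = ctx.permute(0, 2, 1, 3).reshape(B, T, D)
        return ad.matmul(ctx, self.wo)


class FeedForward(Module):
    """Two-layer per-token projection with a GELU nonlinearity."""

    def __init__(self, d_model: int, ratio: int, rng: np.random.Generator):
        self.fc1 = Linear(d_model, ratio * d_model, rng)
        self.fc2 = Linear(ratio * d_model, d_model, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(ad.gelu(self.fc1(x)))


class TransformerLayer(Module):
    """Pre-norm residual transformer layer: MHA sublayer then FFN sublayer."""

    def __init__(self, d_model: int, n_heads: int, ffn_ratio: int, rng: np.random.Generator, p_drop: float = 0.1):
        self.ln1 = LayerNorm(d_model)
        self.mha = MultiHeadAttention(d_model, n_heads, rng)
        self.ln2 = LayerNorm(d_model)
        self.ffn = FeedForward(d_model, ffn_ratio, rng)
        self.p_drop = p_drop

    def __call__(self, x: Tensor, rng: np.random.Generator, training: bool) -> Tensor:
        h = self.ln1(x)
        x = x + ad.dropout(self.mha(h, h, h), self.p_drop, rng, training)
        x = x + ad.dropout(self.ffn(self.ln2(x)), self.p_drop, rng, training)
        return x
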