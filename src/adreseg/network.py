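"""The volumetric segmentation model.

An encoder built from depthwise-separable convolution (DSConv) units
downsamples the input four times (each stage halves every spatial
dimension and doubles the channel width, ending at C' channels at 1/16
resolution).  The bottleneck feature map is reshaped channel-wise into a
token sequence — one token per channel, each token the flattened spatial
map of that channel, so the sequence is C' tokens of dimension
N = (W/16)*(H/16)*(D/16) — a learnable positional embedding is added, and
a stack of pre-norm transformer layers (8-head attention + feed-forward)
models global context.  The decoder maps tokens back to the bottleneck
grid and upsamples four times with transposed convolutions, concatenating
the saved encoder feature map at each resolution when skip connections
are enabled, and ends in a single-channel sigmoid head.

Ablation switches: ``use_skip`` removes the skip concatenations,
``use_transformer`` bypasses the token bottleneck entirely, and
``n_transformer_layers`` controls bottleneck depth (0 = identity stack).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .layers import (
    DSConvUnit,
    Downsample,
    Module,
    TransformerLayer,
    Upsample,
)

__all__ = ["NetConfig", "SegmentationNetwork", "dsconv_param_count"]


def dsconv_param_count(c_in: int, c_out: int, k: int) -> tuple[int, int]:
    """Weight counts (bias excluded) of a depthwise-separable convolution
    versus a standard convolution with the same widths and kernel.

    dsconv = k^3*c_in + c_in*c_out;  standard = k^3*c_in*c_out.
    """
    if c_in < 1 or c_out < 1 or k < 1:
        raise ValueError("c_in, c_out and k must be positive")
    dsconv = k ** 3 * c_in + c_in * c_out
    standard = k ** 3 * c_in * c_out
    return dsconv, standard


@dataclass(frozen=True)
class NetConfig:
    """Complete architectural description of the network."""

    input_size: tuple[int, int, int] = (256, 256, 32)
    in_channels: int = 1
    stem_channels: int = 16
    stage_channels: tuple[int, ...] = (32, 64, 128, 256)
    n_transformer_layers: int = 4
    n_heads: int = 8
    use_skip: bool = True
    use_transformer: bool = True
    ffn_ratio: int = 4
    dropout: float = 0.1
    #: expected foreground fraction; the sigmoid head's bias starts at its
    #: log-odds so the initial output matches the class prior instead of 0.5
    #: (standard initialization under extreme class imbalance)
    foreground_prior: float = 0.01

    def __post_init__(self):
        W, H, D = self.input_size
        for n in (W, H, D):
            if n % 16 != 0 or n < 16:
                raise ValueError(f"input_size {self.input_size} must be divisible by 16")
        if len(self.stage_channels) != 4:
            raise ValueError("stage_channels must list the four encoder stages")
        chain = (self.stem_channels,) + tuple(self.stage_channels)
        for a, b in zip(chain, chain[1:]):
            if b != 2 * a:
                raise ValueError(f"stage widths must double: {chain}")
        if self.n_transformer_layers < 0:
            raise ValueError("n_transformer_layers must be >= 0")
        if self.use_transformer and self.token_dim % self.n_heads != 0:
            raise ValueError(
                f"token dim {self.token_dim} not divisible by {self.n_heads} heads"
            )

    @property
    def bottleneck_channels(self) -> int:
        return self.stage_channels[-1]

    @property
    def bottleneck_size(self) -> tuple[int, int, int]:
        W, H, D = self.input_size
        return (W // 16, H // 16, D // 16)

    @property
    def token_dim(self) -> int:
        w, h, d = self.bottleneck_size
        return w * h * d

    @property
    def token_shape(self) -> tuple[int, int]:
        """(sequence length, embedding dim) = (C', N)."""
        return (self.bottleneck_channels, self.token_dim)

    def with_ablation(self, **kwargs) -> "NetConfig":
        return replace(self, **kwargs)


class SegmentationNetwork(Module):
    """Encoder-DSConv / transformer-bottleneck / decoder segmentation model."""

    def __init__(self, cfg: NetConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        chans = (cfg.stem_channels,) + tuple(cfg.stage_channels)

        # encoder: stem at full resolution, then 4 stages of
        # (two DSConv units, stride-2 depthwise downsample)
        self.stem = DSConvUnit(cfg.in_channels, chans[0], rng)
        self.enc_blocks: list[list[Module]] = []
        for i in range(4):
            self.enc_blocks.append(
                [
                    DSConvUnit(chans[i], chans[i + 1], rng),
                    DSConvUnit(chans[i + 1], chans[i + 1], rng),
                    Downsample(chans[i + 1], rng),
                ]
            )

        cp = cfg.bottleneck_channels
        n = cfg.token_dim
        if cfg.use_transformer:
            # convolutional projection ahead of the channel-token reshape
            self.token_proj = ad.parameter(
                (rng.standard_normal((cp, cp)) * np.sqrt(2.0 / cp)).astype(np.float32)
            )
            self.token_proj_bias = ad.parameter(np.zeros(cp, np.float32))
            self.pos_embedding = ad.parameter(
                (rng.standard_normal((cp, n)) * 0.02).astype(np.float32)
            )
            self.transformer_layers = [
                TransformerLayer(n, cfg.n_heads, cfg.ffn_ratio, rng, cfg.dropout)
                for _ in range(cfg.n_transformer_layers)
            ]
        else:
            self.transformer_layers = []

        # decoder: 4 upsampling stages halving channels, optional skip fuse
        self.dec_blocks: list[list[Module]] = []
        for i in range(4, 0, -1):
            c_in, c_out = chans[i], chans[i - 1]
            up = Upsample(c_in, c_out, rng)
            skip_ch = chans[i] if cfg.use_skip else 0
            fuse = DSConvUnit(c_out + skip_ch, c_out, rng)
            self.dec_blocks.append([up, fuse])

        self.head_w = ad.parameter(
            (rng.standard_normal((1, chans[0])) * np.sqrt(1.0 / chans[0])).astype(np.float32)
        )
        prior = float(np.clip(cfg.foreground_prior, 1e-6, 1 - 1e-6))
        self.head_b = ad.parameter(np.array([np.log(prior / (1 - prior))], np.float32))

        self.training = True
        self._dropout_rng = np.random.default_rng(seed + 1)

    # -- mode / rng ----------------------------------------------------
    def train(self) -> "SegmentationNetwork":
        self.training = True
        return self

    def eval(self) -> "SegmentationNetwork":
        self.training = False
        return self

    def reseed_dropout(self, seed: int) -> None:
        self._dropout_rng = np.random.default_rng(seed)

    # -- forward pieces ------------------------------------------------
    def encode(self, x: Tensor) -> tuple[Tensor, list[Tensor]]:
        """Four downsamplings; returns the bottleneck map and the per-stage
        pre-downsample feature maps retained for the skip connections."""
        W, H, D = self.cfg.input_size
        if x.shape[2:] != (W, H, D):
            raise ValueError(f"input spatial dims {x.shape[2:]} != configured {(W, H, D)}")
        h = self.stem(x)
        skips: list[Tensor] = []
        for conv1, conv2, down in self.enc_blocks:
            h = conv2(conv1(h))
            skips.append(h)
            h = down(h)
        return h, skips

    def tokenize(self, bottleneck: Tensor) -> Tensor:
        """Project, reshape channel-wise to a (C', N) token sequence and add
        the learnable positional embedding."""
        cp = self.cfg.bottleneck_channels
        if bottleneck.shape[1] != cp:
            raise ValueError(
                f"bottleneck has {bottleneck.shape[1]} channels, expected {cp}"
            )
        B = bottleneck.shape[0]
        h = ad.pointwise_conv3d(bottleneck, self.token_proj, self.token_proj_bias)
        tokens = h.reshape(B, cp, -1)  # token t = flattened spatial map of channel t
        return tokens + self.pos_embedding

    def transformer(self, tokens: Tensor, n_layers: int | None = None) -> Tensor:
        """Run ``n_layers`` pre-norm transformer layers (default: all)."""
        layers = self.transformer_layers if n_layers is None else self.transformer_layers[:n_layers]
        for layer in layers:
            tokens = layer(tokens, self._dropout_rng, self.training)
        return tokens

    def detokenize(self, tokens: Tensor) -> Tensor:
        """Feature mapping: reshape the token sequence back onto the
        bottleneck grid."""
        B = tokens.shape[0]
        w, h, d = self.cfg.bottleneck_size
        return tokens.reshape(B, self.cfg.bottleneck_channels, w, h, d)

    def decode(self, bottleneck: Tensor, skips: list[Tensor] | None) -> Tensor:
        """Four upsampling stages back to full resolution, sigmoid head."""
        if self.cfg.use_skip:
            if not skips:
                raise ValueError("skip connections enabled but no encoder maps given")
            skips = list(skips)
        h = bottleneck
        for i, (up, fuse) in enumerate(self.dec_blocks):
            h = up(h)
            if self.cfg.use_skip:
                h = ad.concat([h, skips[3 - i]], axis=1)
            h = fuse(h)
        logits = ad.pointwise_conv3d(h, self.head_w, self.head_b)
        return ad.sigmoid(logits)

    def forward(self, x: Tensor | np.ndarray) -> Tensor:
        """Full forward pass: (B, C, W, H, D) -> (B, 1, W, H, D) foreground
        probabilities in [0, 1]."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        bottleneck, skips = self.encode(x)
        if self.cfg.use_transformer:
            tokens = self.tokenize(bottleneck)
            tokens = self.transformer(tokens)
            bottleneck = self.detokenize(tokens)
        return self.decode(bottleneck, skips if self.cfg.use_skip else None)

    __call__ = forward

    # -- introspection -------------------------------------------------
    @property
    def attention_maps_(self) -> list[np.ndarray]:
        """Per-layer attention weights from the most recent forward pass."""
        return [layer.mha.attention_ for layer in self.transformer_layers]

    def encoder_conv_economy(self) -> list[tuple[int, int]]:
        """Per encoder DSConv unit: (separable weights, standard-conv weights)."""
        out = []
        units = [self.stem]
        for conv1, conv2, _ in self.enc_blocks:
            units.extend([conv1, conv2])
        for u in units:
            c_in = u.dw.shape[0]
            c_out = u.pw.shape[0]
            out.append((u.conv_param_count(), dsconv_param_count(c_in, c_out, 3)[1]))
        return out

    # -- persistence ---------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise ValueError(f"parameter name mismatch: {sorted(missing)[:5]}...")
        for name, arr in state.items():
            if own[name].data.shape != arr.shape:
                raise ValueError(f"shape mismatch for {name}")
            own[name].data[...] = arr

    def save(self, path) -> None:
        """Checkpoint: weights plus the embedded config, as compressed npz."""
        import json

        cfg = {k: getattr(self.cfg, k) for k in NetConfig.__dataclass_fields__}
        np.savez_compressed(path, __config__=json.dumps(cfg), **self.state_dict())

    @classmethod
    def load(cls, path) -> "SegmentationNetwork":
        import json

        with np.load(path, allow_pickle=False) as z:
            cfg_raw = json.loads(str(z["__config__"]))
            cfg_raw["input_size"] = tuple(cfg_raw["input_size"])
            cfg_raw["stage_channels"] = tuple(cfg_raw["stage_channels"])
            net = cls(NetConfig(**cfg_raw))
            net.load_state_dict({k: z[k] for k in z.files if k != "__config__"})
        return net


def multi_head_attention(q: Tensor, k: Tensor, v: Tensor, mha) -> Tensor:
    """Functional wrapper over :class:`~adreseg.layers.MultiHeadAttention`."""
    return mha(q, k, v)
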