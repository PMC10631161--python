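"""Architecture contracts: shapes, tokenization, attention, parameter economy."""

import numpy as np
import pytest

from adreseg import autodiff as ad
from adreseg.layers import MultiHeadAttention
from adreseg.network import NetConfig, SegmentationNetwork, dsconv_param_count

TINY = dict(stem_channels=8, stage_channels=(16, 32, 64, 128))


@pytest.fixture(scope="module")
def tiny_net():
    return SegmentationNetwork(NetConfig(input_size=(32, 32, 32), **TINY), seed=3)


# ---------------------------------------------------------------------
# parameter economy
# ---------------------------------------------------------------------

@pytest.mark.parametrize(
    "cin,cout,k,expected",
    [
        (16, 32, 3, (944, 13824)),
        (1, 1, 1, (2, 1)),  # degenerate: separable form is not smaller
        (64, 128, 3, (64 * 27 + 64 * 128, 27 * 64 * 128)),
    ],
)
def test_dsconv_param_count_closed_form(cin, cout, k, expected):
    assert dsconv_param_count(cin, cout, k) == expected


def test_dsconv_ratio_for_wide_layers():
    ds, std = dsconv_param_count(64, 128, 3)
    assert ds / std == pytest.approx(1 / 128 + 1 / 27, rel=1e-12)


def test_dsconv_param_count_rejects_nonpositive():
    with pytest.raises(ValueError):
        dsconv_param_count(0, 4, 3)


def test_every_encoder_unit_beats_standard_convolution(tiny_net):
    economy = tiny_net.encoder_conv_economy()
    assert len(economy) == 9  # stem + 2 units x 4 stages
    for separable, standard in economy:
        assert separable < standard


# ---------------------------------------------------------------------
# configuration invariants
# ---------------------------------------------------------------------

def test_default_config_token_shape_is_canonical():
    assert NetConfig().token_shape == (256, 512)
    assert NetConfig().bottleneck_size == (16, 16, 2)


def test_reduced_config_token_shape():
    assert NetConfig(input_size=(64, 64, 16)).token_shape == (256, 16)


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(input_size=(100, 64, 16)),  # not divisible by 16
        dict(stage_channels=(32, 64, 128)),  # wrong length
        dict(stem_channels=16, stage_channels=(32, 64, 128, 512)),  # broken doubling
        dict(input_size=(48, 48, 16)),  # token dim 9 not divisible by 8 heads
        dict(n_transformer_layers=-1),
    ],
)
def test_invalid_configs_are_rejected(kwargs):
    with pytest.raises(ValueError):
        NetConfig(**kwargs)


# ---------------------------------------------------------------------
# encoder / tokenizer
# ---------------------------------------------------------------------

def test_encoder_produces_bottleneck_and_four_skips(tiny_net):
    x = ad.Tensor(np.zeros((1, 1, 32, 32, 32), np.float32))
    bottleneck, skips = tiny_net.encode(x)
    assert bottleneck.shape == (1, 128, 2, 2, 2)
    assert [s.shape for s in skips] == [
        (1, 16, 32, 32, 32),
        (1, 32, 16, 16, 16),
        (1, 64, 8, 8, 8),
        (1, 128, 4, 4, 4),
    ]


def test_encoder_rejects_mismatched_input(tiny_net):
    with pytest.raises(ValueError, match="spatial dims"):
        tiny_net.encode(ad.Tensor(np.zeros((1, 1, 16, 16, 16), np.float32)))


def test_tokenize_is_projection_reshape_under_zero_embedding(tiny_net, rng):
    bottleneck = ad.Tensor(rng.standard_normal((1, 128, 2, 2, 2)).astype(np.float32))
    saved = tiny_net.pos_embedding.data.copy()
    try:
        tiny_net.pos_embedding.data[...] = 0.0
        tokens = tiny_net.tokenize(bottleneck)
        assert tokens.shape == (1, 128, 8)
        manual = ad.pointwise_conv3d(bottleneck, tiny_net.token_proj, tiny_net.token_proj_bias)
        np.testing.assert_allclose(tokens.data, manual.data.reshape(1, 128, 8), atol=1e-6)
    finally:
        tiny_net.pos_embedding.data[...] = saved


def test_tokenize_rejects_wrong_channel_count(tiny_net):
    with pytest.raises(ValueError, match="channels"):
        tiny_net.tokenize(ad.Tensor(np.zeros((1, 64, 2, 2, 2), np.float32)))


# ---------------------------------------------------------------------
# attention
# ---------------------------------------------------------------------

def brute_force_attention(x, mha):
    """Term-by-term evaluation of the scaled-dot-product attention formula."""
    B, T, D = x.shape
    H, d = mha.n_heads, mha.d_head
    out = np.zeros((B, T, D))
    for b in range(B):
        heads = []
        for h in range(H):
            wq = mha.wq.data.reshape(D, H, d)[:, h, :]
            wk = mha.wk.data.reshape(D, H, d)[:, h, :]
            wv = mha.wv.data.reshape(D, H, d)[:, h, :]
            q, k, v = x[b] @ wq, x[b] @ wk, x[b] @ wv
            scores = q @ k.T / np.sqrt(d)
            e = np.exp(scores - scores.max(axis=1, keepdims=True))
            attn = e / e.sum(axis=1, keepdims=True)
            heads.append(attn @ v)
        out[b] = np.concatenate(heads, axis=1) @ mha.wo.data
    return out


def test_attention_matches_term_by_term_formula(rng):
    mha = MultiHeadAttention(8, 2, np.random.default_rng(0))
    x = rng.standard_normal((1, 4, 8)).astype(np.float32)
    xt = ad.Tensor(x)
    out = mha(xt, xt, xt)
    np.testing.assert_allclose(out.data, brute_force_attention(x, mha), atol=1e-6)


def test_single_token_attention_ignores_scores(rng):
    mha = MultiHeadAttention(8, 2, np.random.default_rng(1))
    x = rng.standard_normal((1, 1, 8)).astype(np.float32)
    out = mha(ad.Tensor(x), ad.Tensor(x), ad.Tensor(x))
    # softmax over one key is 1 regardless of the query
    expected = (x[0] @ mha.wv.data) @ mha.wo.data
    np.testing.assert_allclose(out.data[0], expected, atol=1e-6)
    assert np.all(mha.attention_ == 1.0)


def test_identical_keys_give_uniform_attention_rows(rng):
    mha = MultiHeadAttention(8, 2, np.random.default_rng(2))
    q = ad.Tensor(rng.standard_normal((1, 6, 8)).astype(np.float32))
    k = ad.Tensor(np.tile(rng.standard_normal((1, 1, 8)).astype(np.float32), (1, 6, 1)))
    mha(q, k, k)
    np.testing.assert_allclose(mha.attention_, 1.0 / 6.0, atol=1e-6)


def test_attention_rows_sum_to_one_in_every_layer(tiny_net, rng):
    x = rng.standard_normal((1, 1, 32, 32, 32)).astype(np.float32)
    tiny_net.eval().forward(x)
    assert len(tiny_net.attention_maps_) == 4
    for attn in tiny_net.attention_maps_:
        np.testing.assert_allclose(attn.sum(axis=-1), 1.0, atol=1e-6)


# ---------------------------------------------------------------------
# transformer stack
# ---------------------------------------------------------------------

def test_zero_layer_stack_is_identity(rng):
    cfg = NetConfig(input_size=(32, 32, 32), n_transformer_layers=0, **TINY)
    net = SegmentationNetwork(cfg, seed=0)
    tokens = ad.Tensor(rng.standard_normal((1, 128, 8)).astype(np.float32))
    out = net.transformer(tokens)
    np.testing.assert_array_equal(out.data, tokens.data)


def test_stack_preserves_token_shape(tiny_net, rng):
    tokens = ad.Tensor(rng.standard_normal((2, 128, 8)).astype(np.float32))
    assert tiny_net.eval().transformer(tokens).shape == (2, 128, 8)


def test_transformer_parameter_count_matches_closed_form(tiny_net):
    n = tiny_net.cfg.token_dim
    r = tiny_net.cfg.ffn_ratio
    per_layer = (
        4 * n * n  # Q, K, V, O projections (no bias)
        + (n * r * n + r * n) + (r * n * n + n)  # FFN with biases
        + 2 * (2 * n)  # two layer norms
    )
    measured = sum(
        p.size for name, p in tiny_net.parameters() if name.startswith("transformer_layers")
    )
    assert measured == 4 * per_layer


def test_positional_embedding_receives_gradient(rng):
    cfg = NetConfig(input_size=(32, 32, 32), **TINY)
    net = SegmentationNetwork(cfg, seed=1)
    x = rng.standard_normal((1, 1, 32, 32, 32)).astype(np.float32)
    out = net.train().forward(x)
    out.sum().backward()
    assert net.pos_embedding.grad is not None
    assert np.abs(net.pos_embedding.grad).max() > 0


# ---------------------------------------------------------------------
# decoder / full pass
# ---------------------------------------------------------------------

def test_forward_preserves_grid_and_probability_range(tiny_net, rng):
    x = rng.standard_normal((1, 1, 32, 32, 32)).astype(np.float32)
    out = tiny_net.eval().forward(x)
    assert out.shape == (1, 1, 32, 32, 32)
    assert out.data.min() >= 0.0 and out.data.max() <= 1.0


def test_zeroed_head_outputs_half_everywhere(rng):
    net = SegmentationNetwork(NetConfig(input_size=(32, 32, 32), **TINY), seed=5)
    net.head_w.data[...] = 0.0
    net.head_b.data[...] = 0.0
    out = net.eval().forward(rng.standard_normal((1, 1, 32, 32, 32)).astype(np.float32))
    np.testing.assert_allclose(out.data, 0.5, atol=1e-7)


def test_skip_ablation_runs_with_same_output_shape(rng):
    cfg = NetConfig(input_size=(32, 32, 32), use_skip=False, **TINY)
    net = SegmentationNetwork(cfg, seed=2)
    out = net.eval().forward(rng.standard_normal((1, 1, 32, 32, 32)).astype(np.float32))
    assert out.shape == (1, 1, 32, 32, 32)


def test_transformer_ablation_has_no_transformer_parameters():
    cfg = NetConfig(input_size=(32, 32, 32), use_transformer=False, **TINY)
    net = SegmentationNetwork(cfg, seed=2)
    names = [name for name, _ in net.parameters()]
    assert not any("transformer" in n or "pos_embedding" in n for n in names)
    full = SegmentationNetwork(NetConfig(input_size=(32, 32, 32), **TINY), seed=2)
    assert net.param_count() < full.param_count()


def test_decode_requires_skips_when_enabled(tiny_net):
    bottleneck = ad.Tensor(np.zeros((1, 128, 2, 2, 2), np.float32))
    with pytest.raises(ValueError, match="skip"):
        tiny_net.decode(bottleneck, None)


def test_checkpoint_roundtrip_reproduces_forward(tmp_path, rng):
    cfg = NetConfig(input_size=(32, 32, 32), **TINY)
    net = SegmentationNetwork(cfg, seed=11)
    x = rng.standard_normal((1, 1, 32, 32, 32)).astype(np.float32)
    ref = net.eval().forward(x).data
    path = tmp_path / "ckpt.npz"
    net.save(path)
    back = SegmentationNetwork.load(path)
    np.testing.assert_array_equal(back.eval().forward(x).data, ref)
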