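"""Architecture contracts: shapes, window algebra, attention oracles, ablations."""

import numpy as np
import pytest

from socialvit import nn
from socialvit.model import (
    BASE,
    MICRO,
    SMALL,
    TINY,
    ConfigurationError,
    DepthwiseSeparableConv,
    Downsample,
    GlobalQueryAttention,
    GlobalQueryGenerator,
    LocalWindowAttention,
    MixedScaleFeedForward,
    ModelConfig,
    ShapeError,
    Stem,
    build_model,
    dsc_msfn,
    window_partition,
    window_reverse,
)
from socialvit.nn import Tensor


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def test_published_variants_differ_only_in_scaling_fields():
    assert TINY.depths == SMALL.depths == BASE.depths == (3, 4, 19, 5)
    assert TINY.window_size == SMALL.window_size == BASE.window_size == (7, 7, 14, 7)
    assert (TINY.dim, SMALL.dim, BASE.dim) == (64, 96, 128)
    assert (TINY.mlp_ratio, SMALL.mlp_ratio, BASE.mlp_ratio) == (3.0, 2.0, 2.0)
    assert (TINY.drop_path_rate, SMALL.drop_path_rate, BASE.drop_path_rate) == (0.2, 0.3, 0.5)
    assert TINY.layer_scale_init is None
    assert SMALL.layer_scale_init == BASE.layer_scale_init == 1e-5
    for cfg in (TINY, SMALL, BASE):
        assert [cfg.stage_side(s) for s in range(4)] == [56, 28, 14, 7]
        for s in range(4):
            assert cfg.stage_side(s) % cfg.window_size[s] == 0


@pytest.mark.parametrize(
    "kwargs, match",
    [
        (dict(resolution=100), "divisible by 32"),
        (dict(window_size=(5, 7, 14, 7)), "does not divide"),
        (dict(num_heads=(3, 4, 8, 16)), "not divisible"),
        (dict(depths=(1, 1, 1)), "exactly 4 entries"),
    ],
)
def test_invalid_configuration_names_failed_constraint(kwargs, match):
    with pytest.raises(ConfigurationError, match=match):
        ModelConfig(**kwargs)


def test_wider_embedding_has_more_parameters():
    small_dim = build_model(MICRO, seed=0).num_parameters()
    wider = build_model(MICRO.replace(dim=32), seed=0).num_parameters()
    assert wider > small_dim


# ---------------------------------------------------------------------------
# stem and window algebra
# ---------------------------------------------------------------------------

def test_stem_downsamples_by_four(rng):
    stem = Stem(3, 16)
    out = stem(Tensor(rng.random((1, 64, 64, 3))))
    assert out.shape == (1, 16, 16, 16)
    with pytest.raises(ShapeError):
        stem(Tensor(rng.random((1, 66, 66, 3))))


def test_window_counting(rng):
    ws = window_partition(Tensor(rng.random((2, 56, 56, 4))), 7)
    assert ws.num_windows == 64 and ws.tokens_per_window == 49
    assert ws.values.shape == (2 * 64, 49, 4)
    ws = window_partition(Tensor(rng.random((1, 14, 14, 4))), 14)
    assert ws.num_windows == 1 and ws.tokens_per_window == 196


def test_window_partition_reverse_roundtrip_exhaustive(rng):
    for h in (2, 4, 6, 8):
        for w in (2, 4, 6, 8):
            for win in (1, 2):
                if h % win or w % win:
                    continue
                x = rng.random((2, h, w, 3))
                back = window_reverse(window_partition(Tensor(x), win))
                np.testing.assert_array_equal(back.numpy(), x)
    with pytest.raises(ShapeError):
        window_partition(Tensor(rng.random((1, 6, 6, 2))), 4)


# ---------------------------------------------------------------------------
# local attention
# ---------------------------------------------------------------------------

def _dense_local_oracle(attn: LocalWindowAttention, x: np.ndarray) -> np.ndarray:
    """Independent per-window dense attention using the module's parameters."""
    wq = attn.qkv.weight.data
    bq = attn.qkv.bias.data if attn.qkv.bias is not None else 0.0
    h, d = attn.num_heads, attn.head_dim
    c = h * d
    bias = None
    if attn.rel_bias_table is not None:
        bias = attn.rel_bias_table.data[attn._rel_index].reshape(
            x.shape[1], x.shape[1], h
        ).transpose(2, 0, 1)
    outs = []
    for win in x:                                   # each window independently
        qkv = win @ wq + bq
        q, k, v = np.split(qkv, 3, axis=-1)
        heads = []
        for i in range(h):
            qs, ks, vs = (m[:, i * d:(i + 1) * d] for m in (q, k, v))
            scores = qs @ ks.T * attn.scale
            if bias is not None:
                scores = scores + bias[i]
            e = np.exp(scores - scores.max(axis=-1, keepdims=True))
            a = e / e.sum(axis=-1, keepdims=True)
            heads.append(a @ vs)
        merged = np.concatenate(heads, axis=-1)
        outs.append(merged @ attn.proj.weight.data + attn.proj.bias.data)
    return np.stack(outs)


def test_local_attention_matches_dense_oracle(rng):
    nn.manual_seed(1)
    attn = LocalWindowAttention(dim=8, num_heads=2, window=2)
    x = rng.standard_normal((2, 4, 8)).astype(np.float32)   # 2 windows of 4 tokens
    from socialvit.model.blocks import WindowSet

    ws = WindowSet(Tensor(x), batch=1, height=2, width=4, window=2)
    with nn.no_grad():
        got = attn(ws).values.numpy()
    np.testing.assert_allclose(got, _dense_local_oracle(attn, x), atol=1e-5)


def test_local_attention_rows_are_stochastic(rng):
    nn.manual_seed(2)
    attn = LocalWindowAttention(dim=8, num_heads=2, window=2)
    from socialvit.model.blocks import WindowSet

    ws = WindowSet(Tensor(rng.standard_normal((3, 4, 8))), 1, 2, 6, 2)
    weights = attn.attention_weights(ws)
    np.testing.assert_allclose(weights.sum(axis=-1), 1.0, atol=1e-5)


def test_single_token_window_attention_is_projection_chain(rng):
    nn.manual_seed(3)
    attn = LocalWindowAttention(dim=6, num_heads=1, window=1)
    from socialvit.model.blocks import WindowSet

    x = rng.standard_normal((2, 1, 6)).astype(np.float32)
    ws = WindowSet(Tensor(x), 2, 1, 1, 1)
    assert attn.attention_weights(ws) == pytest.approx(1.0)
    with nn.no_grad():
        got = attn(ws).values.numpy()
    # degenerate softmax: output is proj(value-projection(token))
    qkv = x @ attn.qkv.weight.data + attn.qkv.bias.data
    v = qkv[..., 12:]
    expected = v @ attn.proj.weight.data + attn.proj.bias.data
    np.testing.assert_allclose(got, expected, atol=1e-5)


def test_attention_head_divisibility_guard():
    with pytest.raises(ConfigurationError):
        LocalWindowAttention(dim=7, num_heads=2, window=2)


# ---------------------------------------------------------------------------
# global attention and query generation
# ---------------------------------------------------------------------------

def test_identical_windows_receive_identical_global_outputs(rng):
    nn.manual_seed(4)
    attn = GlobalQueryAttention(dim=8, num_heads=2)
    from socialvit.model.blocks import GlobalTokenSet, WindowSet

    one = rng.standard_normal((1, 4, 8)).astype(np.float32)
    x = np.concatenate([one, one], axis=0)          # two identical windows
    ws = WindowSet(Tensor(x), 1, 2, 4, 2)
    q = GlobalTokenSet(Tensor(rng.standard_normal((1, 4, 8))))
    with nn.no_grad():
        out = attn(ws, q).values.numpy()
    np.testing.assert_allclose(out[0], out[1], atol=1e-6)
    rows = attn.attention_weights(ws, q)
    np.testing.assert_allclose(rows.sum(axis=-1), 1.0, atol=1e-5)


def test_global_attention_identity_projection_oracle(rng):
    nn.manual_seed(5)
    dim = 4
    attn = GlobalQueryAttention(dim=dim, num_heads=1, qkv_bias=False)
    eye = np.eye(dim, dtype=np.float32)
    attn.q.weight.data = eye.copy()
    attn.kv.weight.data = np.concatenate([eye, eye], axis=1)  # k = v = tokens
    attn.proj.weight.data = eye.copy()
    attn.proj.bias.data = np.zeros(dim, dtype=np.float32)
    from socialvit.model.blocks import GlobalTokenSet, WindowSet

    tokens = rng.standard_normal((1, 4, dim)).astype(np.float32)
    queries = rng.standard_normal((1, 4, dim)).astype(np.float32)
    ws = WindowSet(Tensor(tokens), 1, 2, 2, 2)
    with nn.no_grad():
        got = attn(ws, GlobalTokenSet(Tensor(queries))).values.numpy()[0]
    scores = queries[0] @ tokens[0].T / np.sqrt(dim)
    e = np.exp(scores - scores.max(axis=-1, keepdims=True))
    expected = (e / e.sum(axis=-1, keepdims=True)) @ tokens[0]
    np.testing.assert_allclose(got, expected, atol=1e-5)


def test_global_token_mismatch_raises(rng):
    nn.manual_seed(6)
    attn = GlobalQueryAttention(dim=8, num_heads=2)
    from socialvit.model.blocks import GlobalTokenSet, WindowSet

    ws = WindowSet(Tensor(rng.standard_normal((2, 4, 8))), 1, 2, 4, 2)
    bad_q = GlobalTokenSet(Tensor(rng.standard_normal((1, 9, 8))))
    with pytest.raises(ShapeError):
        attn(ws, bad_q)


@pytest.mark.parametrize("side, window, levels, tokens", [(56, 7, 3, 49), (8, 8, 0, 64), (8, 2, 2, 4)])
def test_global_query_generator_downsampling(rng, side, window, levels, tokens):
    nn.manual_seed(7)
    gen = GlobalQueryGenerator(dim=4, stage_side=side, window=window)
    assert gen.levels == levels
    out = gen(Tensor(rng.random((1, side, side, 4)).astype(np.float32)))
    assert out.tokens == tokens


def test_global_query_generator_requires_power_of_two_ratio():
    with pytest.raises(ConfigurationError):
        GlobalQueryGenerator(dim=4, stage_side=12, window=4)


# ---------------------------------------------------------------------------
# depthwise-separable convolution and the mixed-scale feedforward
# ---------------------------------------------------------------------------

def _naive_depthwise_separable(block: DepthwiseSeparableConv, x: np.ndarray) -> np.ndarray:
    """Channel-by-channel 2-D convolution then explicit 1x1 mixing."""
    from scipy.signal import convolve2d

    kh = block.depthwise.weight.shape[0]
    pad = kh // 2
    mid = np.zeros_like(x)
    for b in range(x.shape[0]):
        for c in range(x.shape[-1]):
            kernel = block.depthwise.weight.data[:, :, c][::-1, ::-1]  # correlation
            mid[b, :, :, c] = convolve2d(
                np.pad(x[b, :, :, c], pad), kernel, mode="valid"
            )
    mid = mid + block.depthwise.bias.data
    w1 = block.pointwise.weight.data.reshape(x.shape[-1], x.shape[-1])
    return mid @ w1 + block.pointwise.bias.data


def test_depthwise_separable_matches_naive_oracle(rng):
    nn.manual_seed(8)
    block = DepthwiseSeparableConv(3, 3)
    x = rng.standard_normal((4, 5, 6, 3)).astype(np.float32)
    with nn.no_grad():
        got = block(Tensor(x)).numpy()
    np.testing.assert_allclose(got, _naive_depthwise_separable(block, x), atol=1e-5)


def test_depthwise_separable_parameter_count():
    nn.manual_seed(9)
    c = 6
    block = DepthwiseSeparableConv(c, 3)
    # 9C depthwise + C^2 pointwise weights (biases counted separately)
    n_weights = block.depthwise.weight.data.size + block.pointwise.weight.data.size
    assert n_weights == 9 * c + c * c
    assert n_weights < 9 * c * c  # strictly fewer than a full 3x3 conv for C > 1
    with pytest.raises(ConfigurationError):
        DepthwiseSeparableConv(c, 4)


def test_depthwise_on_single_pixel_is_center_tap(rng):
    nn.manual_seed(10)
    block = DepthwiseSeparableConv(3, 3)
    block.depthwise.bias.data[:] = 0
    x = rng.standard_normal((1, 1, 1, 3)).astype(np.float32)
    with nn.no_grad():
        mid = block.depthwise(Tensor(x)).numpy()
    np.testing.assert_allclose(mid[0, 0, 0], x[0, 0, 0] * block.depthwise.weight.data[1, 1], atol=1e-6)


def test_msfn_preserves_shape_and_residual_identity(rng):
    nn.manual_seed(11)
    msfn = MixedScaleFeedForward(6, 2.0)
    x = rng.standard_normal((2, 4, 4, 6)).astype(np.float32)
    with nn.no_grad():
        out = dsc_msfn(Tensor(x), msfn)
    assert out.shape == x.shape
    for p in msfn.parameters():
        p.data[:] = 0
    with nn.no_grad():
        out = dsc_msfn(Tensor(x), msfn)
    np.testing.assert_allclose(out.numpy(), x, atol=1e-6)
    with pytest.raises(ConfigurationError):
        MixedScaleFeedForward(5, 1.0)   # odd expansion cannot split


def test_msfn_branches_match_depthwise_oracle(rng):
    from scipy.signal import convolve2d

    nn.manual_seed(12)
    msfn = MixedScaleFeedForward(4, 2.0)    # hidden 8, branches of 4 channels
    x = rng.standard_normal((1, 5, 5, 4)).astype(np.float32)
    with nn.no_grad():
        expanded = nn.gelu(msfn.expand(Tensor(x))).numpy()
        got3 = msfn.branch3(Tensor(expanded[..., :4])).numpy()
    pad = 1
    for c in range(4):
        kernel = msfn.branch3.weight.data[:, :, c][::-1, ::-1]
        expected = convolve2d(np.pad(expanded[0, :, :, c], pad), kernel, mode="valid")
        np.testing.assert_allclose(got3[0, :, :, c],
                                   expected + msfn.branch3.bias.data[c], atol=1e-5)


# ---------------------------------------------------------------------------
# downsampling and the full forward contract
# ---------------------------------------------------------------------------

def test_downsample_halves_grid_and_doubles_channels(rng):
    nn.manual_seed(13)
    down = Downsample(8)
    out = down(Tensor(rng.random((1, 16, 16, 8)).astype(np.float32)))
    assert out.shape == (1, 8, 8, 16)
    with pytest.raises(ShapeError):
        down(Tensor(rng.random((1, 7, 7, 8))))


def test_stage_geometry_chain():
    for cfg in (TINY, SMALL, BASE):
        sides = [cfg.stage_side(s) for s in range(4)]
        dims = [cfg.stage_dim(s) for s in range(4)]
        assert sides == [56, 28, 14, 7]
        assert dims == [cfg.dim * m for m in (1, 2, 4, 8)]


def test_micro_forward_contract(rng):
    model = build_model(MICRO, seed=14)
    x = rng.random((2, 64, 64, 3)).astype(np.float32)
    logits = model.predict_logits(x)
    assert logits.shape == (2, 5) and np.isfinite(logits).all()
    proba = model.predict_proba(x)
    assert (proba >= 0).all() and (proba <= 1).all()
    np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-5)
    # eval-mode determinism
    np.testing.assert_array_equal(logits, model.predict_logits(x))
    with pytest.raises(ShapeError):
        model.predict_logits(rng.random((1, 65, 65, 3)))


def test_drop_path_rates_linearly_spaced():
    model = build_model(MICRO.replace(drop_path_rate=0.3), seed=15)
    rates = []
    for stage in model.stages:
        for unit in stage.units:
            rates.extend([unit.dp_local.p, unit.dp_ffn.p, unit.dp_global.p, unit.dp_mlp.p])
    assert rates[0] == 0.0
    assert rates[-1] == pytest.approx(0.3)
    assert all(b > a for a, b in zip(rates, rates[1:]))


def test_ablation_flags_strictly_reduce_parameters():
    full = build_model(MICRO, seed=16).num_parameters()
    for flag in ("use_local_msa", "use_global_msa", "use_dsc_msfn"):
        reduced = build_model(MICRO.replace(**{flag: False}), seed=16).num_parameters()
        assert reduced < full, flag
    baseline = build_model(
        MICRO.replace(use_local_msa=False, use_global_msa=False, use_dsc_msfn=False),
        seed=16,
    )
    assert baseline.num_parameters() < full
    # the baseline still classifies
    assert baseline.predict_logits(np.zeros((1, 64, 64, 3), np.float32)).shape == (1, 5)


def test_checkpoint_roundtrip(tmp_path, rng):
    from socialvit.model import load_checkpoint, save_checkpoint

    model = build_model(MICRO, seed=17)
    x = rng.random((1, 64, 64, 3)).astype(np.float32)
    before = model.predict_logits(x)
    save_checkpoint(model, tmp_path / "m.npz", {"note": "test"})
    loaded, extra = load_checkpoint(tmp_path / "m.npz")
    assert extra["note"] == "test"
    np.testing.assert_array_equal(loaded.predict_logits(x), before)
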