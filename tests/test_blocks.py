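"""Block algebra against independent straight-line oracles, parameter
accounting, and architecture contracts."""

import numpy as np
import pytest

from endo3d import nn
from endo3d.blocks import (
    ArchitectureConfig,
    BlockConfig,
    Conv2Plus1D,
    CSE3D,
    Downsample,
    Model,
    PScSE3D,
    ResidualBlock,
    RPABlock,
    SSE3D,
    build_model,
    conv2plus1d_param_count,
    full3d_param_count,
    mid_channels_rule,
)
from endo3d.nn import ConfigurationError


def rand(shape, seed=0):
    return np.random.default_rng(seed).standard_normal(shape)


# ---------------------------------------------------------------- oracles
def oracle_spatial_conv(x, w, b):
    """Naive looped 1xkxk convolution with same padding."""
    B, T, H, W_, C = x.shape
    k, _, _, O = w.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (0, 0)))
    out = np.zeros((B, T, H, W_, O))
    for i in range(k):
        for j in range(k):
            for c in range(C):
                for o in range(O):
                    out[..., o] += xp[:, :, i:i + H, j:j + W_, c] * w[i, j, c, o]
    return out + b


def oracle_temporal_conv(x, w, b):
    B, T, H, W_, C = x.shape
    t, _, O = w.shape
    p = t // 2
    xp = np.pad(x, ((0, 0), (p, p), (0, 0), (0, 0), (0, 0)))
    out = np.zeros((B, T, H, W_, O))
    for i in range(t):
        for c in range(C):
            for o in range(O):
                out[..., o] += xp[:, i:i + T, :, :, c] * w[i, c, o]
    return out + b


def oracle_layernorm(x, gamma, beta, eps):
    mu = x.mean(-1, keepdims=True)
    var = x.var(-1, keepdims=True)
    return gamma * (x - mu) / np.sqrt(var + eps) + beta


def oracle_cse(x, block):
    z = x.mean(axis=(1, 2, 3))
    h = np.maximum(z @ block.fc1.w.value + block.fc1.b.value, 0.0)
    gate = 1.0 / (1.0 + np.exp(-(h @ block.fc2.w.value + block.fc2.b.value)))
    return x * gate[:, None, None, None, :]


def oracle_sse(x, block):
    gate = 1.0 / (1.0 + np.exp(-(x @ block.squeeze.w.value + block.squeeze.b.value)))
    return x * gate


def oracle_conv2plus1d(x, block):
    h = oracle_spatial_conv(x, block.spatial.w.value, block.spatial.b.value)
    return oracle_temporal_conv(h, block.temporal.w.value, block.temporal.b.value)


def oracle_residual(x, block):
    h = oracle_conv2plus1d(x, block.conv1)
    h = oracle_layernorm(h, block.ln1.gamma.value, block.ln1.beta.value, block.ln1.eps)
    h = np.maximum(h, 0.0)
    h = oracle_conv2plus1d(h, block.conv2)
    h = oracle_layernorm(h, block.ln2.gamma.value, block.ln2.beta.value, block.ln2.eps)
    if block.proj is None:
        skip = x
    else:
        skip = x @ block.proj.w.value + block.proj.b.value
    return h + skip


# ------------------------------------------------------- oracle agreement
X_SMALL = rand((1, 4, 8, 8, 8), seed=42)


def test_cse3d_matches_oracle():
    block = CSE3D(8, 2, np.random.default_rng(1))
    np.testing.assert_allclose(block(X_SMALL), oracle_cse(X_SMALL, block), atol=1e-10)


def test_sse3d_matches_oracle():
    block = SSE3D(8, np.random.default_rng(2))
    np.testing.assert_allclose(block(X_SMALL), oracle_sse(X_SMALL, block), atol=1e-10)


@pytest.mark.parametrize("threshold,shorted", [(4, False), (32, True)])
def test_pscse3d_matches_elementwise_oracle(threshold, shorted):
    block = PScSE3D(8, BlockConfig(8, sw_bypass_threshold=threshold),
                    np.random.default_rng(3))
    assert block.shorted is shorted
    c = oracle_cse(X_SMALL, block.cse)
    s = oracle_sse(X_SMALL, block.sse)
    expected = (c + s) if shorted else np.maximum(c, s) + c + s
    np.testing.assert_allclose(block(X_SMALL), expected, atol=1e-10)


def test_conv2plus1d_matches_looped_oracle():
    x = rand((1, 3, 5, 5, 2), seed=7)
    block = Conv2Plus1D(2, BlockConfig(4, mid_channels=3), np.random.default_rng(4))
    np.testing.assert_allclose(block(x), oracle_conv2plus1d(x, block), atol=1e-10)


def test_residual_block_matches_straight_line_oracle():
    x = rand((1, 3, 5, 5, 2), seed=8)
    block = ResidualBlock(2, BlockConfig(4, mid_channels=3), np.random.default_rng(5))
    np.testing.assert_allclose(block(x), oracle_residual(x, block), atol=1e-10)


def test_rpa_block_is_composition_of_tested_parts():
    x = rand((1, 2, 6, 6, 3), seed=9)
    block = RPABlock(3, BlockConfig(4, mid_channels=3, sw_bypass_threshold=2),
                     np.random.default_rng(6))
    h = oracle_residual(x, block.residual)
    c = oracle_cse(h, block.attention.cse)
    s = oracle_sse(h, block.attention.sse)
    np.testing.assert_allclose(block(x), np.maximum(c, s) + c + s, atol=1e-10)
    assert block(x).shape[-1] == 4


# --------------------------------------------------------------- identities
def test_conv2plus1d_identity_kernels():
    """k=t=1 with identity kernels reproduces the input exactly."""
    block = Conv2Plus1D(3, BlockConfig(3, spatial_kernel=1, temporal_kernel=1,
                                       mid_channels=3), np.random.default_rng(0))
    block.spatial.w.value[...] = np.eye(3)[None, None]
    block.spatial.b.value[...] = 0
    block.temporal.w.value[...] = np.eye(3)[None]
    block.temporal.b.value[...] = 0
    x = rand((2, 3, 4, 4, 3), seed=10)
    np.testing.assert_allclose(block(x), x, atol=1e-12)


def test_conv2plus1d_preserves_extents():
    x = rand((1, 8, 16, 16, 4), seed=11)
    block = Conv2Plus1D(4, BlockConfig(8, mid_channels=6), np.random.default_rng(7))
    assert block(x).shape == (1, 8, 16, 16, 8)


def test_residual_zero_branch_is_identity():
    """Zero conv weights: the branch emits zero and the skip passes x."""
    block = ResidualBlock(4, BlockConfig(4, mid_channels=4), np.random.default_rng(8))
    for conv in (block.conv1, block.conv2):
        conv.spatial.w.value[...] = 0
        conv.temporal.w.value[...] = 0
        conv.spatial.b.value[...] = 0
        conv.temporal.b.value[...] = 0
    x = rand((1, 2, 4, 4, 4), seed=12)
    np.testing.assert_allclose(block(x), x, atol=1e-12)


def test_residual_projects_skip_on_channel_change():
    block = ResidualBlock(4, BlockConfig(8), np.random.default_rng(9))
    assert block.proj is not None
    assert block(rand((1, 2, 4, 4, 4), seed=13)).shape[-1] == 8


def test_sse_zero_weights_halves_input():
    block = SSE3D(5, np.random.default_rng(10))
    block.squeeze.w.value[...] = 0
    block.squeeze.b.value[...] = 0
    x = rand((1, 2, 3, 3, 5), seed=14)
    np.testing.assert_allclose(block(x), x / 2, atol=1e-12)


def test_cse_zero_input_gives_zero_output():
    block = CSE3D(6, 2, np.random.default_rng(11))
    assert np.all(block(np.zeros((1, 2, 3, 3, 6))) == 0.0)


def test_gates_strictly_inside_unit_interval():
    x = rand((2, 3, 4, 4, 8), seed=15) * 5
    cse = CSE3D(8, 2, np.random.default_rng(12))
    sse = SSE3D(8, np.random.default_rng(13))
    cse(x)
    sse(x)
    for gate in (cse._gate, sse._gate):
        assert np.all(gate > 0.0) and np.all(gate < 1.0)


def test_pscse_full_form_dominates_shorted_on_nonnegative_branches():
    # same seed, same structure -> identical sub-block weights in both forms
    full = PScSE3D(8, BlockConfig(8, sw_bypass_threshold=2), np.random.default_rng(14))
    shorted = PScSE3D(8, BlockConfig(8, sw_bypass_threshold=32), np.random.default_rng(14))
    x = np.abs(rand((1, 2, 4, 4, 8), seed=16))
    assert np.all(full(x) >= shorted(x) - 1e-12)


def test_pscse_equal_branches_gives_three_c():
    block = PScSE3D(4, BlockConfig(4, sw_bypass_threshold=2), np.random.default_rng(15))
    c = np.full((1, 1, 2, 2, 4), 0.3)
    block.cse.forward = lambda x: c
    block.sse.forward = lambda x: c
    np.testing.assert_allclose(block(np.ones_like(c)), 3 * c)


# ------------------------------------------------------ parameter accounting
def test_mid_channel_rule_and_param_count_example():
    m = 6
    assert conv2plus1d_param_count(4, 8, 3, 3, m) == 3**2 * 4 * 6 + 3 * 6 * 8 == 360
    assert full3d_param_count(4, 8, 3, 3) == 864
    block = Conv2Plus1D(4, BlockConfig(8, mid_channels=6), np.random.default_rng(16))
    assert block.n_params(include_bias=False) == 360


def test_factorized_below_full3d_at_every_default_stage():
    arch = ArchitectureConfig()
    c_in = arch.in_channels
    for i in range(5):
        cfg = arch.block_config(i)
        for conv_c_in in (c_in, cfg.out_channels):  # both convs of the stage
            m = mid_channels_rule(conv_c_in, cfg.out_channels,
                                  cfg.spatial_kernel, cfg.temporal_kernel)
            fact = conv2plus1d_param_count(conv_c_in, cfg.out_channels,
                                           cfg.spatial_kernel, cfg.temporal_kernel, m)
            full = full3d_param_count(conv_c_in, cfg.out_channels,
                                      cfg.spatial_kernel, cfg.temporal_kernel)
            assert fact < full
        c_in = cfg.out_channels


def test_conv2plus1d_weight_count_matches_closed_form():
    for c_in, c_out, k, t in [(3, 16, 3, 3), (16, 32, 5, 3), (8, 8, 3, 5)]:
        block = Conv2Plus1D(c_in, BlockConfig(c_out, spatial_kernel=k, temporal_kernel=t),
                            np.random.default_rng(17))
        expected = conv2plus1d_param_count(c_in, c_out, k, t, block.mid_channels)
        assert block.n_params(include_bias=False) == expected


# ------------------------------------------------------------ architecture
def test_downsample_halves_extents():
    d = Downsample()
    assert d(rand((1, 8, 24, 24, 16), seed=17)).shape == (1, 4, 12, 12, 16)


def test_downsample_keeps_unit_temporal_axis():
    d = Downsample()
    assert d(rand((1, 1, 8, 8, 4), seed=18)).shape == (1, 1, 4, 4, 4)


def test_downsample_constant_input_stays_constant():
    out = Downsample()(np.full((1, 4, 8, 8, 2), 0.7))
    np.testing.assert_allclose(out, 0.7)


def test_model_emits_two_logits_and_is_deterministic():
    arch = ArchitectureConfig(stage_widths=(4, 4, 8, 8, 8))
    model = build_model(arch, seed=3)
    x = rand((2, 3, 16, 16, 3), seed=19)
    logits = model.forward(x)
    assert logits.shape == (2, 2)
    np.testing.assert_array_equal(logits, model.forward(x))


def test_model_architecture_audit():
    model = build_model(ArchitectureConfig(stage_widths=(4, 4, 8, 8, 8)), seed=4)
    assert len(model.rpa_blocks) == 5
    downs = [s for s in model.body.layers if isinstance(s, Downsample)]
    assert len(downs) == 4
    assert model.head.w.value.shape == (8, 2)


def test_identical_seed_gives_identical_weights():
    a = build_model(ArchitectureConfig(stage_widths=(4, 4, 8, 8, 8)), seed=9)
    b = build_model(ArchitectureConfig(stage_widths=(4, 4, 8, 8, 8)), seed=9)
    for (na, pa), (nb, pb) in zip(a.named_params(), b.named_params()):
        assert na == nb
        np.testing.assert_array_equal(pa.value, pb.value)


def test_too_small_input_rejected():
    model = build_model(ArchitectureConfig(stage_widths=(4, 4, 8, 8, 8)), seed=0)
    with pytest.raises(ConfigurationError):
        model.forward(rand((1, 2, 8, 8, 3), seed=20))


def test_arch_requires_five_stage_widths():
    with pytest.raises(ConfigurationError):
        ArchitectureConfig(stage_widths=(4, 4, 8))


def test_cse_rejects_too_few_channels():
    with pytest.raises(ConfigurationError):
        CSE3D(2, 4, np.random.default_rng(0))


def test_model_save_load_roundtrip(tmp_path):
    model = build_model(ArchitectureConfig(stage_widths=(4, 4, 8, 8, 8)), seed=5)
    x = rand((1, 2, 16, 16, 3), seed=21)
    path = str(tmp_path / "ckpt.npz")
    model.save(path)
    restored = Model.load(path)
    np.testing.assert_allclose(restored.forward(x), model.forward(x), atol=1e-12)
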