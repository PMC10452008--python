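"""Ghost block, switchable normalization, MHSA and bottleneck contracts."""

import numpy as np
import pytest

from ghostseg.autodiff import Tensor, conv2d
from ghostseg.core_blocks import (
    GhostBlock,
    MultiHeadSelfAttention2d,
    ResidualBottleneck,
    SwitchableNorm,
    ghost_param_count,
    plain_conv_param_count,
)


def seeded(seed=0):
    return np.random.default_rng(seed)


# -- ghost block ---------------------------------------------------------


def test_ghost_channel_arithmetic():
    blk = GhostBlock(4, 8, ratio=2, rng=seeded())
    assert blk.intrinsic == 4 and blk.cheap == 4
    out = blk(Tensor(seeded(1).normal(size=(2, 4, 6, 6))))
    assert out.shape == (2, 8, 6, 6)


def test_ghost_identity_cheap_kernel_copies_intrinsic_maps():
    blk = GhostBlock(3, 8, ratio=2, rng=seeded())
    w = np.zeros_like(blk.cheap_weight.data)
    w[:, 0, 1, 1] = 1.0  # centre tap
    blk.cheap_weight.data = w
    x = Tensor(seeded(2).normal(size=(1, 3, 5, 5)))
    out = blk(x).data
    assert np.allclose(out[:, 4:], out[:, :4], atol=1e-12)


@pytest.mark.parametrize("cin,cout,ratio", [(4, 8, 2), (16, 16, 2), (32, 64, 4), (7, 10, 3)])
def test_ghost_economy_closed_form(cin, cout, ratio):
    blk = GhostBlock(cin, cout, ratio=ratio, rng=seeded())
    assert blk.param_count() == ghost_param_count(cin, cout, ratio)
    assert blk.param_count() < plain_conv_param_count(cin, cout, 3)


def test_ghost_channel_mismatch_names_both_counts():
    blk = GhostBlock(4, 8, rng=seeded())
    with pytest.raises(ValueError, match="4.*6|6.*4"):
        blk(Tensor(np.zeros((1, 6, 4, 4))))


def test_ghost_stride_downsamples_via_primary_conv():
    blk = GhostBlock(4, 8, primary_kernel=3, stride=2, rng=seeded())
    assert blk(Tensor(np.zeros((1, 4, 8, 8)))).shape == (1, 8, 4, 4)
    with pytest.raises(ValueError, match="stride"):
        blk(Tensor(np.zeros((1, 4, 7, 8))))


# -- switchable normalization ---------------------------------------------


def _manual_stats(x):
    """Independent BN/IN/LN statistics computed with plain reductions."""
    mu_in = x.mean(axis=(2, 3), keepdims=True)
    var_in = x.var(axis=(2, 3), keepdims=True)
    mu_ln = x.mean(axis=(1, 2, 3), keepdims=True)
    var_ln = x.var(axis=(1, 2, 3), keepdims=True)
    mu_bn = x.mean(axis=(0, 2, 3), keepdims=True)
    var_bn = x.var(axis=(0, 2, 3), keepdims=True)
    return (mu_bn, mu_in, mu_ln), (var_bn, var_in, var_ln)


@pytest.mark.parametrize("batch", [1, 2, 4])
@pytest.mark.parametrize("which", [0, 1, 2], ids=["BN", "IN", "LN"])
def test_sn_saturated_logits_match_pure_normalizers(batch, which):
    rng = seeded(5)
    x = rng.normal(size=(batch, 3, 4, 5))
    sn = SwitchableNorm(3)
    sn.mean_logits.data[which] = 50.0
    sn.var_logits.data[which] = 50.0
    out = sn(Tensor(x)).data
    mus, vars_ = _manual_stats(x)
    expected = (x - mus[which]) / np.sqrt(vars_[which] + sn.eps)
    assert np.isfinite(out).all()
    assert np.allclose(out, expected, atol=1e-5)


def test_sn_constant_input_returns_shift():
    sn = SwitchableNorm(2)
    sn.beta.data = np.array([1.5, -0.5]).reshape(1, 2, 1, 1)
    out = sn(Tensor(np.full((2, 2, 3, 3), 7.0))).data
    assert np.allclose(out, sn.beta.data, atol=1e-6)


def test_sn_equal_logits_average_the_three_statistics():
    rng = seeded(9)
    x = rng.normal(size=(2, 2, 2, 2))
    sn = SwitchableNorm(2)
    out = sn(Tensor(x)).data
    mus, vars_ = _manual_stats(x)
    mu = sum(mus) / 3.0
    var = sum(vars_) / 3.0
    expected = (x - mu) / np.sqrt(var + sn.eps)
    assert np.allclose(out, expected, atol=1e-12)


def test_sn_rejects_empty_batch_and_tracks_running_stats():
    sn = SwitchableNorm(2)
    with pytest.raises(ValueError, match="batch"):
        sn(Tensor(np.zeros((0, 2, 3, 3))))
    x = seeded(3).normal(size=(4, 2, 3, 3))
    before = sn.running_mean.copy()
    sn(Tensor(x))
    assert not np.array_equal(before, sn.running_mean)
    sn.eval()
    frozen = sn.running_mean.copy()
    sn(Tensor(x))
    assert np.array_equal(frozen, sn.running_mean)


# -- MHSA -----------------------------------------------------------------


def test_mhsa_rows_sum_to_one_and_shapes():
    rng = seeded(21)
    mhsa = MultiHeadSelfAttention2d(8, heads=4, spatial=(3, 4), rng=rng)
    x = Tensor(rng.normal(size=(2, 8, 3, 4)))
    res = mhsa(x, return_attention=True)
    assert res.output.shape == (2, 8, 3, 4)
    assert res.weights.shape == (2, 4, 12, 12)
    assert np.allclose(res.weights.sum(axis=-1), 1.0, atol=1e-6)


def test_mhsa_single_token_is_value_output_projection():
    rng = seeded(22)
    mhsa = MultiHeadSelfAttention2d(8, heads=2, spatial=(1, 1), rng=rng)
    x = Tensor(rng.normal(size=(3, 8, 1, 1)))
    res = mhsa(x, return_attention=True)
    assert np.allclose(res.weights, 1.0, atol=1e-12)
    expected = conv2d(conv2d(x, mhsa.wv), mhsa.wo).data
    assert np.allclose(res.output.data, expected, atol=1e-10)


def test_mhsa_head_divisibility_and_spatial_rejection():
    with pytest.raises(ValueError, match="3.*8|8.*3"):
        MultiHeadSelfAttention2d(8, heads=3, spatial=(2, 2))
    mhsa = MultiHeadSelfAttention2d(8, heads=2, spatial=(4, 4), rng=seeded())
    with pytest.raises(ValueError, match="relative tables"):
        mhsa(Tensor(np.zeros((1, 8, 2, 2))))


def test_mhsa_forced_one_hot_attention_reduces_to_projections():
    """Saturated self-position logits make MHSA act as value+output 1x1 convs."""
    rng = seeded(23)
    H = W = 3
    mhsa = MultiHeadSelfAttention2d(8, heads=2, spatial=(H, W), rng=rng)
    mhsa.rel_rows.data = np.full_like(mhsa.rel_rows.data, -60.0)
    mhsa.rel_cols.data = np.full_like(mhsa.rel_cols.data, -60.0)
    mhsa.rel_rows.data[:, H - 1] = 60.0  # zero row offset
    mhsa.rel_cols.data[:, W - 1] = 60.0  # zero col offset
    x = Tensor(rng.normal(size=(1, 8, H, W)))
    out = mhsa(x).data
    expected = conv2d(conv2d(x, mhsa.wv), mhsa.wo).data
    assert np.allclose(out, expected, atol=1e-8)


# -- residual bottlenecks -------------------------------------------------


def test_rgs_bottleneck_stride_two_halves_resolution():
    blk = ResidualBottleneck(8, 16, stride=2, rng=seeded(4))
    out = blk(Tensor(seeded(5).normal(size=(1, 8, 64, 64))))
    assert out.shape == (1, 16, 32, 32)
    with pytest.raises(ValueError, match="even"):
        blk(Tensor(np.zeros((1, 8, 63, 64))))


def test_rgs_zero_main_path_is_relu_identity():
    blk = ResidualBottleneck(8, 8, stride=1, rng=seeded(6))
    assert blk.shortcut_weight is None
    for gb in (blk.reduce, blk.middle, blk.expand):
        gb.primary_weight.data[...] = 0.0
        gb.cheap_weight.data[...] = 0.0
    x = seeded(7).normal(size=(2, 8, 6, 6))
    out = blk(Tensor(x)).data
    assert np.allclose(out, np.maximum(x, 0.0), atol=1e-12)


def test_bot_bottleneck_preserves_resolution_and_identity_limit():
    rng = seeded(8)
    blk = ResidualBottleneck(
        8, 16, stride=1, middle="mhsa", heads=2, spatial=(6, 6), rng=rng
    )
    x = Tensor(rng.normal(size=(1, 8, 6, 6)))
    assert blk(x).shape == (1, 16, 6, 6)
    # zero main path: output = ReLU(shortcut(x))
    blk2 = ResidualBottleneck(8, 8, stride=1, middle="mhsa", heads=2, spatial=(6, 6), rng=seeded(9))
    for gb in (blk2.reduce, blk2.expand):
        gb.primary_weight.data[...] = 0.0
        gb.cheap_weight.data[...] = 0.0
    x2 = seeded(10).normal(size=(1, 8, 6, 6))
    out = blk2(Tensor(x2)).data
    assert np.allclose(out, np.maximum(x2, 0.0), atol=1e-12)


def test_bot_rejects_stride_two():
    with pytest.raises(ValueError, match="stride 1"):
        ResidualBottleneck(8, 16, stride=2, middle="mhsa", heads=2, spatial=(4, 4))


@pytest.mark.parametrize("middle,kwargs", [
    ("ghost", {}),
    ("mhsa", dict(heads=2, spatial=(5, 5))),
])
def test_bottleneck_gradient_reaches_every_weight(middle, kwargs):
    rng = seeded(11)
    blk = ResidualBottleneck(6, 16, stride=1, middle=middle, rng=rng, **kwargs)
    x = Tensor(rng.normal(size=(2, 6, 5, 5)), requires_grad=True)
    out = blk(x)
    (out * out).sum().backward()
    for p in blk.parameters():
        assert p.grad is not None and np.any(p.grad != 0.0)


@pytest.mark.parametrize("cin,cout,stride,hw", [(4, 8, 1, 10), (8, 8, 2, 12), (3, 16, 2, 8)])
def test_bottleneck_shape_contract(cin, cout, stride, hw):
    blk = ResidualBottleneck(cin, cout, stride=stride, rng=seeded(12))
    out = blk(Tensor(seeded(13).normal(size=(2, cin, hw, hw))))
    assert out.shape == (2, cout, hw // stride, hw // stride)
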