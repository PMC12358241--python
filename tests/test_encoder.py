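"""Encoder enhancement tests: residual self-attention against a loop-based
dense-attention oracle, CMKD against an independent numpy recomposition,
hand-computed attention gates, and pipeline contracts."""

import numpy as np
import pytest
from scipy.signal import correlate2d
from scipy.special import expit

from mranet import autodiff as ad
from mranet.autodiff import Tensor
from mranet.backbone import BackboneFeatures, ConfigurationError, DimensionError
from mranet.encoder import (CBR, CMKD, ChannelAttention, CMKDParams,
                            EncoderEnhancer, ResidualSelfAttention, RSABParams,
                            SpatialAttention)
from mranet.layers import set_seed


# ---------------------------------------------------------------------------
# independent numpy reference operations (loop/scipy based)
# ---------------------------------------------------------------------------

def np_conv(x, w, b=None, dilation=1):
    """Stride-1 "same" convolution via scipy, one (out, in) pair at a time."""
    cout = w.shape[0]
    out = np.zeros((cout,) + x.shape[1:])
    for o in range(cout):
        for c in range(x.shape[0]):
            kernel = w[o, c]
            if dilation > 1:
                k = kernel.shape[0]
                dk = np.zeros(((k - 1) * dilation + 1,) * 2)
                dk[::dilation, ::dilation] = kernel
                kernel = dk
            out[o] += correlate2d(x[c], kernel, mode="same")
        if b is not None:
            out[o] += b[o]
    return out


def np_bn_eval(x, bn):
    g = bn.weight.data[:, None, None]
    b = bn.bias.data[:, None, None]
    rm = bn.running_mean[:, None, None]
    rv = bn.running_var[:, None, None]
    return (x - rm) / np.sqrt(rv + bn.eps) * g + b


def np_cbr_eval(x, cbr, dilation=1):
    conv, bn, _ = cbr._list
    y = np_conv(x, conv.weight.data, conv.bias.data, dilation=dilation)
    return np.maximum(np_bn_eval(y, bn), 0.0)


# ---------------------------------------------------------------------------
# RSAB
# ---------------------------------------------------------------------------

def test_rsab_zero_output_projection_is_identity(rng):
    set_seed(1)
    rsab = ResidualSelfAttention(RSABParams(channels=4, qk_reduction=2))
    rsab.out.weight.data[:] = 0.0
    rsab.out.bias.data[:] = 0.0
    f4 = rng.normal(size=(1, 4, 3, 3))
    out = rsab(Tensor(f4)).data
    np.testing.assert_array_equal(out, f4)


def test_rsab_singleton_spatial_softmax_is_one(rng):
    set_seed(2)
    rsab = ResidualSelfAttention(RSABParams(channels=4, qk_reduction=2))
    f4 = rng.normal(size=(1, 4, 1, 1))
    attn = rsab.attention_matrix(Tensor(f4)).data
    np.testing.assert_allclose(attn, 1.0, atol=1e-12)
    # attention weight 1 on the single position -> out = f4 + Conv(v)
    v = np_conv(f4[0], rsab.value.weight.data, rsab.value.bias.data)
    expect = f4[0] + np_conv(v, rsab.out.weight.data, rsab.out.bias.data)
    np.testing.assert_allclose(rsab(Tensor(f4)).data[0], expect, rtol=1e-10)


def test_rsab_matches_loop_based_attention_oracle(rng):
    """Explicit q.k matrix, row softmax, weighted value sum, done with loops."""
    set_seed(3)
    rsab = ResidualSelfAttention(RSABParams(channels=4, qk_reduction=2))
    f4 = rng.normal(size=(1, 4, 2, 2))
    out = rsab(Tensor(f4)).data[0]

    x = f4[0]
    q = np_conv(x, rsab.query.weight.data, rsab.query.bias.data).reshape(2, -1)
    k = np_conv(x, rsab.key.weight.data, rsab.key.bias.data).reshape(2, -1)
    v = np_conv(x, rsab.value.weight.data, rsab.value.bias.data).reshape(4, -1)
    L = 4
    attended = np.zeros((4, L))
    for i in range(L):
        logits = np.array([np.dot(q[:, i], k[:, j]) for j in range(L)])
        weights = np.exp(logits - logits.max())
        weights /= weights.sum()
        assert abs(weights.sum() - 1.0) < 1e-12
        for j in range(L):
            attended[:, i] += weights[j] * v[:, j]
    proj = np_conv(attended.reshape(4, 2, 2), rsab.out.weight.data,
                   rsab.out.bias.data)
    np.testing.assert_allclose(out, x + proj, rtol=1e-5, atol=1e-8)


def test_rsab_attention_rows_sum_to_one(rng):
    set_seed(4)
    rsab = ResidualSelfAttention(RSABParams(channels=8, qk_reduction=4))
    f4 = rng.normal(size=(2, 8, 4, 4))
    attn = rsab.attention_matrix(Tensor(f4)).data
    np.testing.assert_allclose(attn.sum(axis=-1), 1.0, atol=1e-6)


def test_rsab_channel_mismatch_raises():
    set_seed(0)
    rsab = ResidualSelfAttention(RSABParams(channels=8, qk_reduction=4))
    with pytest.raises(DimensionError):
        rsab(Tensor(np.zeros((1, 4, 2, 2))))


def test_rsab_params_divisibility():
    with pytest.raises(ConfigurationError, match="divisible"):
        RSABParams(channels=6, qk_reduction=4)


# ---------------------------------------------------------------------------
# channel / spatial attention
# ---------------------------------------------------------------------------

def test_channel_attention_gates_open_interval(rng):
    set_seed(5)
    ca = ChannelAttention(8, reduction=2)
    gates = ca.gates(Tensor(rng.normal(size=(2, 8, 3, 3)))).data
    assert np.all(gates > 0.0) and np.all(gates < 1.0)


def test_channel_attention_symmetric_on_zero_input():
    set_seed(6)
    ca = ChannelAttention(4, reduction=2)
    ca.fc1.bias.data[:] = 0.0
    ca.fc2.bias.data[:] = 0.0
    gates = ca.gates(Tensor(np.zeros((1, 4, 2, 2)))).data.reshape(-1)
    np.testing.assert_allclose(gates, gates[0], atol=1e-12)


def test_channel_attention_matches_hand_computation():
    set_seed(7)
    ca = ChannelAttention(4, reduction=2)
    x = np.arange(16, dtype=float).reshape(1, 4, 2, 2) / 10.0
    gates = ca.gates(Tensor(x)).data.reshape(4)
    w1 = ca.fc1.weight.data[:, :, 0, 0]
    b1 = ca.fc1.bias.data
    w2 = ca.fc2.weight.data[:, :, 0, 0]
    b2 = ca.fc2.bias.data
    avg = x[0].mean(axis=(1, 2))
    mx = x[0].max(axis=(1, 2))
    logit = (w2 @ np.maximum(w1 @ avg + b1, 0) + b2) \
        + (w2 @ np.maximum(w1 @ mx + b1, 0) + b2)
    np.testing.assert_allclose(gates, expit(logit), rtol=1e-12)


def test_channel_attention_reduction_must_divide():
    with pytest.raises(ConfigurationError, match="divisible"):
        ChannelAttention(6, reduction=4)


def test_spatial_attention_constant_input_gives_constant_gate():
    set_seed(8)
    sa = SpatialAttention(kernel_size=3)
    gates = sa.gates(Tensor(np.full((1, 5, 4, 4), 1.7))).data
    # interior positions see identical neighbourhoods
    interior = gates[0, 0, 1:-1, 1:-1]
    np.testing.assert_allclose(interior, interior[0, 0], atol=1e-12)
    assert np.all(gates > 0) and np.all(gates < 1)


def test_spatial_attention_matches_hand_computation():
    set_seed(9)
    sa = SpatialAttention(kernel_size=3)
    x = np.random.default_rng(10).normal(size=(1, 3, 3, 3))
    gates = sa.gates(Tensor(x)).data[0, 0]
    stacked = np.stack([x[0].mean(axis=0), x[0].max(axis=0)])
    pre = np_conv(stacked, sa.conv.weight.data, sa.conv.bias.data)[0]
    np.testing.assert_allclose(gates, expit(pre), rtol=1e-10)


def test_spatial_attention_even_kernel_rejected():
    with pytest.raises(ConfigurationError, match="odd"):
        SpatialAttention(kernel_size=4)


# ---------------------------------------------------------------------------
# CMKD
# ---------------------------------------------------------------------------

def test_cmkd_preserves_shape_on_grid(rng):
    set_seed(10)
    cmkd = CMKD(CMKDParams(in_channels=8, attention_reduction=2))
    cmkd.eval()
    for h, w in [(4, 4), (5, 7), (12, 8)]:
        out = cmkd(Tensor(rng.normal(size=(1, 8, h, w)))).data
        assert out.shape == (1, 8, h, w)


def test_cmkd_branch_concatenation_width():
    set_seed(11)
    params = CMKDParams(in_channels=8, branch_width=4, attention_reduction=2)
    cmkd = CMKD(params)
    fcon = ad.concat([b(Tensor(np.zeros((1, 8, 4, 4))))
                      for b in cmkd.kernel_branches], axis=1)
    assert fcon.shape[1] == 4 * params.branch_width
    assert cmkd.fuse.weight.shape == (8, 4 * params.branch_width, 1, 1)


def test_dilated_kernel_effective_extent():
    # a 3x3 kernel at dilation 11 spans k + (k-1)(r-1) = 23 pixels
    k, r = 3, 11
    assert k + (k - 1) * (r - 1) == 23
    set_seed(12)
    cmkd = CMKD(CMKDParams(in_channels=4, attention_reduction=2))
    conv = cmkd.dilated_branches[3]._list[0]
    assert conv.dilation == 11 and conv.padding == 11


def test_cmkd_zeroed_main_branch_reduces_to_shortcut(rng):
    set_seed(13)
    cmkd = CMKD(CMKDParams(in_channels=4, attention_reduction=2))
    cmkd.eval()
    cmkd.fuse.weight.data[:] = 0.0
    cmkd.fuse.bias.data[:] = 0.0
    x = rng.normal(size=(1, 4, 5, 5))
    got = cmkd.pre_attention(Tensor(x)).data[0]
    conv, bn = cmkd.shortcut._list
    expect = np.maximum(np_bn_eval(
        np_conv(x[0], conv.weight.data, conv.bias.data), bn), 0.0)
    np.testing.assert_allclose(got, expect, rtol=1e-10, atol=1e-12)


def test_cmkd_matches_sequential_numpy_recomposition(rng):
    """Full block against an unfused scipy/numpy recomposition (eval mode)."""
    set_seed(14)
    params = CMKDParams(in_channels=4, branch_width=3, attention_reduction=2,
                        spatial_kernel=3)
    cmkd = CMKD(params)
    cmkd.eval()
    x = rng.normal(size=(4, 6, 6))
    got = cmkd(Tensor(x[None])).data[0]

    branches = [np_cbr_eval(x, b) for b in cmkd.kernel_branches]
    fcon = np.concatenate(branches, axis=0)
    dil = [np_cbr_eval(fcon, b, dilation=r)
           for b, r in zip(cmkd.dilated_branches, params.dilation_rates)]
    fmain = np_conv(np.concatenate(dil, axis=0), cmkd.fuse.weight.data,
                    cmkd.fuse.bias.data)
    sconv, sbn = cmkd.shortcut._list
    shortcut = np_bn_eval(np_conv(x, sconv.weight.data, sconv.bias.data), sbn)
    fmain_p = np.maximum(fmain + shortcut, 0.0)

    ca = cmkd.channel_attention
    w1, b1 = ca.fc1.weight.data[:, :, 0, 0], ca.fc1.bias.data
    w2, b2 = ca.fc2.weight.data[:, :, 0, 0], ca.fc2.bias.data
    logit = (w2 @ np.maximum(w1 @ fmain_p.mean(axis=(1, 2)) + b1, 0) + b2) \
        + (w2 @ np.maximum(w1 @ fmain_p.max(axis=(1, 2)) + b1, 0) + b2)
    after_ca = fmain_p * expit(logit)[:, None, None]

    sa = cmkd.spatial_attention
    stacked = np.stack([after_ca.mean(axis=0), after_ca.max(axis=0)])
    gate = expit(np_conv(stacked, sa.conv.weight.data, sa.conv.bias.data)[0])
    expect = fmain_p + after_ca * gate[None]
    np.testing.assert_allclose(got, expect, rtol=1e-5, atol=1e-9)


def test_cmkd_even_kernel_override_rejected():
    with pytest.raises(ConfigurationError, match="odd"):
        CMKDParams(in_channels=8, kernel_sizes=(1, 2, 7, 11),
                   attention_reduction=2)


def test_cmkd_channel_mismatch_raises():
    set_seed(15)
    cmkd = CMKD(CMKDParams(in_channels=8, attention_reduction=2))
    with pytest.raises(DimensionError):
        cmkd(Tensor(np.zeros((1, 4, 4, 4))))


# ---------------------------------------------------------------------------
# CBR + pipeline
# ---------------------------------------------------------------------------

def test_cbr_output_nonnegative_and_projected(rng):
    set_seed(16)
    cbr = CBR(8, 16)
    out = cbr(Tensor(rng.normal(size=(2, 8, 5, 5)))).data
    assert out.shape == (2, 16, 5, 5)
    assert np.all(out >= 0.0)


def test_cbr_zero_weights_zero_output():
    set_seed(17)
    cbr = CBR(4, 4)
    cbr.eval()
    conv, bn, _ = cbr._list
    conv.weight.data[:] = 0.0
    conv.bias.data[:] = 0.0
    out = cbr(Tensor(np.random.default_rng(0).normal(size=(1, 4, 3, 3)))).data
    np.testing.assert_allclose(out, 0.0, atol=1e-12)


def _fake_pyramid(rng, chans=(8, 16, 32, 64), size=16):
    feats = []
    for c, s in zip(chans, (4, 8, 16, 32)):
        feats.append(Tensor(rng.normal(size=(1, c, size * 4 // s, size * 4 // s))))
    return BackboneFeatures(*feats)


def test_enhance_pyramid_projects_all_levels_to_decoder_width(rng):
    set_seed(18)
    enh = EncoderEnhancer((8, 16, 32, 64), decoder_width=24,
                          cmkd_params=[CMKDParams(c, attention_reduction=2)
                                       for c in (8, 16, 32)],
                          rsab_params=RSABParams(64, qk_reduction=4))
    feats = _fake_pyramid(rng)
    out = enh(feats)
    for fp, f in zip(out.fprime, feats.levels()):
        assert fp.shape == f.shape  # refinement preserves geometry
    for fd in out.fdp:
        assert fd.shape[1] == 24


def test_enhance_pyramid_ablation_substitutes_identity(rng):
    set_seed(19)
    enh = EncoderEnhancer((8, 16, 32, 64), decoder_width=16,
                          use_cmkd=False, use_rsab=False)
    feats = _fake_pyramid(rng)
    out = enh(feats)
    for fp, f in zip(out.fprime, feats.levels()):
        np.testing.assert_array_equal(fp.data, f.data)
    for fd in out.fdp:
        assert fd.shape[1] == 16
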