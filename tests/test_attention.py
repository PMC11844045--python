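"""Attention operators against straight-line scalar-arithmetic oracles."""

import numpy as np
import pytest

from vesselseg.attention import AttentionGate, ChannelAttention, SpatialAttention
from vesselseg.autodiff import Tensor


def _sig(z):
    return 1.0 / (1.0 + np.exp(-z))


def _zero_weights(module):
    for p in module.parameters():
        p.data[...] = 0.0


def _rng():
    return np.random.default_rng(7)


# -- scalar hand-arithmetic oracles on 1x1-spatial inputs ---------------------


def gate_scalar_oracle(x, g, wx, bx, wg, bg, wpsi, bpsi):
    pre = max(wx * x + bx + wg * g + bg, 0.0)
    return x * _sig(wpsi * pre + bpsi)


def test_attention_gate_matches_scalar_oracle():
    gate = AttentionGate(1, 1, _rng(), inter_channels=1)
    for p in gate.parameters():
        p.data[...] = 1.0
    gate.w_x.bias.data[...] = 0
    gate.w_g.bias.data[...] = 0
    gate.psi.bias.data[...] = 0
    x = Tensor(np.full((1, 1, 1, 1), 2.0, np.float32))
    out = gate(x, Tensor(np.full((1, 1, 1, 1), 2.0, np.float32)))
    # ReLU(2+2)=4, alpha=sigmoid(4), output 2*sigmoid(4) ~= 1.9640
    assert out.data[0, 0, 0, 0] == pytest.approx(2.0 * _sig(4.0), rel=1e-6)
    assert out.data[0, 0, 0, 0] == pytest.approx(1.9640, abs=1e-4)


def test_attention_gate_matches_oracle_for_random_scalar_weights():
    rng = _rng()
    for _ in range(20):
        gate = AttentionGate(1, 1, _rng(), inter_channels=1)
        vals = rng.normal(size=8)
        (gate.w_x.weight.data[...], gate.w_x.bias.data[...],
         gate.w_g.weight.data[...], gate.w_g.bias.data[...],
         gate.psi.weight.data[...], gate.psi.bias.data[...]) = vals[:6]
        x, g = vals[6], vals[7]
        out = gate(Tensor(np.full((1, 1, 1, 1), x, np.float32)),
                   Tensor(np.full((1, 1, 1, 1), g, np.float32)))
        expected = gate_scalar_oracle(
            np.float32(x), np.float32(g), *(np.float32(v) for v in vals[:6]))
        assert out.data[0, 0, 0, 0] == pytest.approx(expected, rel=1e-5, abs=1e-6)


def test_spatial_attention_matches_scalar_oracle():
    sam = SpatialAttention(_rng(), kernel_size=7)
    _zero_weights(sam)
    sam.conv.weight.data[:, :, 3, 3] = 1.0  # centre taps only
    x = Tensor(np.array([1.0, 3.0], np.float32).reshape(1, 2, 1, 1))
    out = sam(x)
    # mean 2, max 3 -> pre-activation 5 -> channel 2 output 3*sigmoid(5)
    assert out.data[0, 1, 0, 0] == pytest.approx(3.0 * _sig(5.0), rel=1e-6)
    assert out.data[0, 1, 0, 0] == pytest.approx(2.9799, abs=1e-4)
    assert out.data[0, 0, 0, 0] == pytest.approx(1.0 * _sig(5.0), rel=1e-6)


def test_channel_attention_matches_scalar_oracle():
    cam = ChannelAttention(2, _rng(), reduction=2)
    cam.fc1.weight.data[...] = 1.0
    cam.fc1.bias.data[...] = 0.0
    cam.fc2.weight.data[...] = 1.0
    cam.fc2.bias.data[...] = 0.0
    x = Tensor(np.ones((1, 2, 1, 1), np.float32))
    out = cam(x)
    # each branch gives (2,2); summed (4,4); alpha = sigmoid(4) ~= 0.9820
    np.testing.assert_allclose(out.data, _sig(4.0), rtol=1e-6)
    assert out.data[0, 0, 0, 0] == pytest.approx(0.9820, abs=1e-4)


# -- zero-weight configurations: sigmoid(0) = 1/2 -----------------------------


def test_zero_weight_configurations_scale_by_exactly_half(rng):
    x_data = rng.normal(size=(2, 4, 8, 8)).astype(np.float32)
    x = Tensor(x_data)

    gate = AttentionGate(4, 4, _rng())
    _zero_weights(gate.psi)
    np.testing.assert_allclose(gate(x, x).data, 0.5 * x_data, rtol=1e-6)

    sam = SpatialAttention(_rng())
    _zero_weights(sam)
    np.testing.assert_allclose(sam(x).data, 0.5 * x_data, rtol=1e-6)

    cam = ChannelAttention(4, _rng(), reduction=2)
    _zero_weights(cam.fc2)
    np.testing.assert_allclose(cam(x).data, 0.5 * x_data, rtol=1e-6)


# -- contracts and properties -------------------------------------------------


@pytest.mark.parametrize("B,C,HW", [(1, 1, 8), (2, 3, 8), (1, 8, 16), (2, 5, 32)])
def test_all_operators_preserve_shape_and_bound_coefficients(rng, B, C, HW):
    x = Tensor(rng.normal(size=(B, C, HW, HW)).astype(np.float32))
    g_half = Tensor(rng.normal(size=(B, C, HW // 2, HW // 2)).astype(np.float32))
    gate = AttentionGate(C, C, _rng())
    sam = SpatialAttention(_rng())
    cam = ChannelAttention(C, _rng())
    for out in (gate(x, g_half), sam(x), cam(x)):
        assert out.shape == x.shape
    for coeff in (gate.coefficients(x, g_half), sam.coefficients(x),
                  cam.coefficients(x)):
        assert np.all(coeff.data > 0.0) and np.all(coeff.data < 1.0)


def test_gate_accepts_equal_resolution_gating(rng):
    x = Tensor(rng.normal(size=(1, 2, 8, 8)).astype(np.float32))
    gate = AttentionGate(2, 2, _rng())
    assert gate(x, x).shape == (1, 2, 8, 8)


def test_gate_shape_contract_with_half_resolution_gate(rng):
    x = Tensor(rng.normal(size=(1, 2, 4, 4)).astype(np.float32))
    g = Tensor(rng.normal(size=(1, 2, 2, 2)).astype(np.float32))
    assert AttentionGate(2, 2, _rng())(x, g).shape == (1, 2, 4, 4)


def test_gate_errors(rng):
    gate = AttentionGate(2, 2, _rng())
    x = Tensor(rng.normal(size=(2, 2, 8, 8)).astype(np.float32))
    with pytest.raises(ValueError, match="batch mismatch"):
        gate(x, Tensor(np.zeros((1, 2, 4, 4), np.float32)))
    with pytest.raises(ValueError, match="incompatible gate resolution"):
        gate(x, Tensor(np.zeros((2, 2, 3, 3), np.float32)))


def test_spatial_attention_rejects_even_kernel():
    with pytest.raises(ValueError, match="odd"):
        SpatialAttention(_rng(), kernel_size=6)


def test_channel_attention_rejects_bad_reduction():
    with pytest.raises(ValueError):
        ChannelAttention(4, _rng(), reduction=0)


def test_constant_input_gives_spatially_constant_sam_output(rng):
    # mean map == max map == c everywhere; away from the zero-padded
    # border the 7x7 convolution then sees identical neighbourhoods
    x = Tensor(np.full((1, 3, 16, 16), 0.7, np.float32))
    out = SpatialAttention(_rng())(x)
    assert np.ptp(out.data[:, :, 3:-3, 3:-3]) < 1e-6


def test_spatially_constant_input_doubles_cam_branch(rng):
    """Mean-pool == max-pool for constant maps, so pre-sigmoid = 2x one branch."""
    cam = ChannelAttention(3, _rng(), reduction=1)
    x = Tensor(np.broadcast_to(
        rng.random((1, 3, 1, 1)).astype(np.float32), (1, 3, 8, 8)).copy())
    from vesselseg import autodiff as ad
    one_branch = cam._branch(ad.spatial_mean(x))
    coeff = cam.coefficients(x)
    np.testing.assert_allclose(coeff.data, _sig(2.0 * one_branch.data),
                               rtol=1e-5)


def test_gating_is_linear_in_input_for_frozen_coefficients(rng):
    x_data = rng.normal(size=(1, 4, 8, 8)).astype(np.float32)
    for op in (SpatialAttention(_rng()), ChannelAttention(4, _rng())):
        alpha = op.coefficients(Tensor(x_data)).data
        out1 = x_data * alpha
        out3 = (3.0 * x_data) * alpha
        np.testing.assert_allclose(out3, 3.0 * out1, rtol=1e-5)
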