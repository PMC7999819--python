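"""Unit and oracle tests for the three attention blocks and their fusion."""

import numpy as np
import pytest

import ascunet.autodiff as ad
from ascunet import (AttentionGate, ChannelAttention, SpatialAttention,
                     channel_squeeze, fuse_dual_attention)
from ascunet.autodiff import Tensor

import oracles


def _t64(rng, shape):
    return Tensor(rng.normal(size=shape).astype(np.float64))


class TestAttentionGate:
    def test_zero_parameters_give_half_alpha(self, rng):
        gate = AttentionGate(3, 5, rng, f_int=4, dtype=np.float64)
        for p in gate.parameters():
            p.data[...] = 0.0
        x, g = _t64(rng, (2, 3, 4, 4)), _t64(rng, (2, 5, 4, 4))
        gated, alpha = gate(x, g)
        assert np.allclose(alpha.data, 0.5)
        assert np.allclose(gated.data, 0.5 * x.data)

    def test_saturated_bias_passes_input_through(self, rng):
        gate = AttentionGate(3, 3, rng, f_int=2, dtype=np.float64)
        gate.psi.weight.data[...] = 0.0
        gate.psi.bias.data[...] = 100.0
        x, g = _t64(rng, (1, 3, 4, 4)), _t64(rng, (1, 3, 4, 4))
        gated, alpha = gate(x, g)
        assert np.allclose(alpha.data, 1.0)
        assert np.allclose(gated.data, x.data)

    def test_matches_scalar_loop_oracle(self, rng):
        gate = AttentionGate(3, 2, rng, f_int=4, dtype=np.float64)
        x, g = _t64(rng, (2, 3, 4, 4)), _t64(rng, (2, 2, 4, 4))
        gated, alpha = gate(x, g)
        o_gated, o_alpha = oracles.attention_gate_loop(
            x.data, g.data, gate.Wx.weight.data, gate.Wg.weight.data,
            gate.Wg.bias.data, gate.psi.weight.data, gate.psi.bias.data)
        np.testing.assert_allclose(alpha.data, o_alpha, rtol=1e-5, atol=1e-8)
        np.testing.assert_allclose(gated.data, o_gated, rtol=1e-5, atol=1e-8)

    def test_coarser_gate_is_resampled(self, rng):
        gate = AttentionGate(4, 6, rng, dtype=np.float64)
        x, g = _t64(rng, (1, 4, 8, 8)), _t64(rng, (1, 6, 4, 4))
        gated, alpha = gate(x, g)
        assert gated.shape == x.shape
        assert alpha.shape == (1, 1, 8, 8)

    @pytest.mark.parametrize("f_l,f_g,f_int", [(1, 1, 1), (2, 4, 3), (8, 8, 4), (5, 2, 2)])
    def test_output_shape_matches_skip(self, rng, f_l, f_g, f_int):
        gate = AttentionGate(f_l, f_g, rng, f_int=f_int)
        x = Tensor(rng.normal(size=(2, f_l, 6, 6)).astype(np.float32))
        g = Tensor(rng.normal(size=(2, f_g, 6, 6)).astype(np.float32))
        gated, alpha = gate(x, g)
        assert gated.shape == x.shape
        assert np.all((alpha.data >= 0) & (alpha.data <= 1))

    def test_batch_mismatch_raises(self, rng):
        gate = AttentionGate(2, 2, rng)
        with pytest.raises(ValueError, match="batch"):
            gate(_t64(rng, (2, 2, 4, 4)), _t64(rng, (3, 2, 4, 4)))

    def test_non_finite_input_raises(self, rng):
        gate = AttentionGate(2, 2, rng)
        x = np.ones((1, 2, 4, 4))
        x[0, 0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            gate(Tensor(x), Tensor(np.ones((1, 2, 4, 4))))


class TestSpatialAttention:
    def test_zero_weights_give_half_mask(self, rng):
        sam = SpatialAttention(4, rng, dtype=np.float64)
        for p in sam.parameters():
            p.data[...] = 0.0
        sam.eval()
        out = sam(_t64(rng, (2, 4, 5, 5)))
        assert np.allclose(out.data, 0.5)

    def test_channels_are_replicas(self, rng):
        sam = SpatialAttention(6, rng, dtype=np.float64).eval()
        out = sam(_t64(rng, (1, 6, 4, 4))).data
        for c in range(1, 6):
            np.testing.assert_array_equal(out[:, c], out[:, 0])

    def test_matches_scalar_loop_oracle(self, rng):
        sam = SpatialAttention(8, rng, dtype=np.float64).eval()
        x = _t64(rng, (2, 8, 4, 4))
        out = sam(x)
        expected = oracles.spatial_attention_loop(
            x.data, sam.conv1.weight.data, sam.conv1.bias.data,
            sam.bn.gamma.data, sam.bn.beta.data, sam.bn.running_mean,
            sam.bn.running_var, sam.conv2.weight.data, sam.conv2.bias.data)
        np.testing.assert_allclose(out.data, expected, rtol=1e-5, atol=1e-8)
        assert np.all((out.data >= 0) & (out.data <= 1))

    def test_odd_channels_rejected_at_construction(self, rng):
        with pytest.raises(ValueError, match="even"):
            SpatialAttention(5, rng)


class TestChannelAttention:
    def test_squeeze_of_constant_map(self):
        x = Tensor(np.full((2, 3, 4, 4), 3.0))
        np.testing.assert_allclose(channel_squeeze(x).data, 3.0)

    def test_squeeze_forced_arithmetic(self):
        x = Tensor(np.array([[1.0, 2.0], [3.0, 4.0]]).reshape(1, 1, 2, 2))
        assert channel_squeeze(x).data[0, 0] == pytest.approx(2.5)

    def test_squeeze_matches_double_sum_oracle(self, rng):
        y = _t64(rng, (2, 5, 7, 3))
        np.testing.assert_allclose(channel_squeeze(y).data,
                                   oracles.channel_squeeze_loop(y.data),
                                   rtol=1e-6, atol=1e-12)

    def test_zero_weights_scale_by_half(self, rng):
        cam = ChannelAttention(4, rng, r=2, dtype=np.float64)
        for p in cam.parameters():
            p.data[...] = 0.0
        x = _t64(rng, (2, 4, 3, 3))
        out = cam(x)
        np.testing.assert_allclose(out.data, 0.5 * x.data)

    def test_excitation_strictly_inside_unit_interval(self, rng):
        cam = ChannelAttention(8, rng, r=2, dtype=np.float64)
        cs = cam.excite(_t64(rng, (4, 8)))
        assert np.all((cs.data > 0) & (cs.data < 1))

    def test_excite_matches_matrix_vector_loop_oracle(self, rng):
        cam = ChannelAttention(8, rng, r=2, dtype=np.float64)
        z = _t64(rng, (3, 8))
        expected = oracles.channel_excite_loop(
            z.data, cam.fc1.weight.data, cam.fc1.bias.data,
            cam.fc2.weight.data, cam.fc2.bias.data)
        np.testing.assert_allclose(cam.excite(z).data, expected, rtol=1e-6, atol=1e-12)

    def test_indivisible_reduction_rejected(self, rng):
        with pytest.raises(ValueError, match="divisible"):
            ChannelAttention(6, rng, r=4)

    def test_ratio_clamped_for_narrow_networks(self, rng):
        cam = ChannelAttention(8, rng, r=16)
        assert cam.r == 8


class TestFusion:
    def test_zero_mask_is_identity(self, rng):
        fc = _t64(rng, (1, 3, 4, 4))
        fs = Tensor(np.zeros((1, 3, 4, 4)))
        np.testing.assert_array_equal(fuse_dual_attention(fc, fs).data, fc.data)

    def test_forced_arithmetic(self):
        fc = Tensor(np.full((1, 1, 1, 1), 2.0))
        fs = Tensor(np.full((1, 1, 1, 1), 1.0))
        assert fuse_dual_attention(fc, fs).data[0, 0, 0, 0] == pytest.approx(4.0)

    def test_matches_element_loop_exactly(self, rng):
        fc = _t64(rng, (2, 3, 4, 4))
        fs = Tensor(rng.random((2, 3, 4, 4)))
        np.testing.assert_array_equal(fuse_dual_attention(fc, fs).data,
                                      oracles.fuse_loop(fc.data, fs.data))

    def test_never_attenuates(self, rng):
        fc = _t64(rng, (2, 4, 5, 5))
        fs = Tensor(rng.random((2, 4, 5, 5)))
        out = fuse_dual_attention(fc, fs).data
        assert np.all(np.abs(out) >= np.abs(fc.data) - 1e-12)

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            fuse_dual_attention(_t64(rng, (1, 2, 3, 3)), _t64(rng, (1, 3, 3, 3)))


def test_all_blocks_differentiable_end_to_end(rng):
    """Finite, nonzero gradients reach every parameter of every block."""
    gate = AttentionGate(4, 4, rng, dtype=np.float64)
    sam = SpatialAttention(4, rng, dtype=np.float64)
    cam = ChannelAttention(4, rng, r=2, dtype=np.float64)
    x = Tensor(rng.normal(size=(2, 4, 6, 6)), requires_grad=True)
    g = Tensor(rng.normal(size=(2, 4, 6, 6)))
    gated, _ = gate(x, g)
    out = fuse_dual_attention(cam(gated), sam(gated))
    (out * out).mean().backward()
    for module in (gate, sam, cam):
        for name, p in module.named_parameters():
            assert p.grad is not None, name
            assert np.all(np.isfinite(p.grad)), name
            assert np.any(p.grad != 0), name
    assert x.grad is not None and np.any(x.grad != 0)
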