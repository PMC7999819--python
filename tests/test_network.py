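"""Network assembly: shapes, ablation variants, and composition oracles."""

import numpy as np
import pytest

import ascunet.autodiff as ad
from ascunet import (AttentionConfig, NetworkConfig, VARIANTS, ablation_suite,
                     build_ascunet, variant_config)
from ascunet.autodiff import Tensor
from ascunet.network import ConvBlock, TripleAttentionDecoderBlock

import oracles

SMALL = NetworkConfig(base_channels=4, depth=2)


class TestConvBlock:
    def test_shape_and_nonnegativity(self, rng):
        block = ConvBlock(3, 8, rng)
        out = block(Tensor(rng.normal(size=(1, 3, 16, 16)).astype(np.float32)))
        assert out.shape == (1, 8, 16, 16)
        assert np.all(out.data >= 0)

    def test_zero_weights_give_zero_output(self, rng):
        block = ConvBlock(2, 4, rng)
        for p in block.parameters():
            p.data[...] = 0.0
        out = block(Tensor(rng.normal(size=(1, 2, 8, 8)).astype(np.float32)))
        np.testing.assert_array_equal(out.data, 0.0)


class TestDecoderBlock:
    def test_shape_contract(self, rng):
        block = TripleAttentionDecoderBlock(4, AttentionConfig(), rng)
        skip = Tensor(rng.normal(size=(1, 4, 32, 32)).astype(np.float32))
        below = Tensor(rng.normal(size=(1, 8, 16, 16)).astype(np.float32))
        assert block(skip, below).shape == (1, 4, 32, 32)

    def test_no_attention_equals_plain_concat_conv(self, rng):
        """The degenerate configuration is exactly up-concat-conv."""
        block = TripleAttentionDecoderBlock(4, AttentionConfig(False, False, False),
                                            rng, dtype=np.float64).eval()
        skip = Tensor(rng.normal(size=(2, 4, 8, 8)))
        below = Tensor(rng.normal(size=(2, 8, 4, 4)))
        out = block(skip, below)
        up = ad.conv_transpose2d_2x2(below, block.up.weight, block.up.bias)
        ref = ad.relu(block.bn1(ad.conv2d(ad.concat([skip, up], axis=1),
                                          block.conv1.weight, block.conv1.bias, pad=1)))
        np.testing.assert_array_equal(out.data, ref.data)

    def test_full_attention_matches_composition_oracle(self, rng):
        """Steps (a)-(f) composed from the scalar-loop block oracles."""
        block = TripleAttentionDecoderBlock(4, AttentionConfig(True, True, True),
                                            rng, r=2, dtype=np.float64).eval()
        skip = rng.normal(size=(1, 4, 6, 6))
        below = rng.normal(size=(1, 8, 3, 3))
        out = block(Tensor(skip), Tensor(below))

        up = oracles.conv_transpose2x2_loop(below, block.up.weight.data, block.up.bias.data)
        gated, _ = oracles.attention_gate_loop(
            skip, up, block.gate.Wx.weight.data, block.gate.Wg.weight.data,
            block.gate.Wg.bias.data, block.gate.psi.weight.data, block.gate.psi.bias.data)
        cat = np.concatenate([gated, up], axis=1)
        t = oracles.conv3x3_loop(cat, block.conv1.weight.data, block.conv1.bias.data)
        t = oracles.bn_eval_loop(t, block.bn1.gamma.data, block.bn1.beta.data,
                                 block.bn1.running_mean, block.bn1.running_var)
        t = np.maximum(t, 0.0)
        z = oracles.channel_squeeze_loop(t)
        cs = oracles.channel_excite_loop(z, block.cam.fc1.weight.data, block.cam.fc1.bias.data,
                                         block.cam.fc2.weight.data, block.cam.fc2.bias.data)
        fc = t * cs[:, :, None, None]
        fs = oracles.spatial_attention_loop(
            t, block.sam.conv1.weight.data, block.sam.conv1.bias.data,
            block.sam.bn.gamma.data, block.sam.bn.beta.data, block.sam.bn.running_mean,
            block.sam.bn.running_var, block.sam.conv2.weight.data, block.sam.conv2.bias.data)
        expected = oracles.fuse_loop(fc, fs)
        np.testing.assert_allclose(out.data, expected, rtol=1e-5, atol=1e-10)

    def test_channel_mismatch_raises(self, rng):
        block = TripleAttentionDecoderBlock(4, AttentionConfig(), rng)
        with pytest.raises(ValueError):
            block(Tensor(np.zeros((1, 4, 8, 8), np.float32)),
                  Tensor(np.zeros((1, 6, 4, 4), np.float32)))


class TestASCUNet:
    def test_forward_shape_and_range(self, rng):
        net = build_ascunet(SMALL, seed=0)
        out = net(Tensor(rng.normal(size=(2, 3, 32, 32)).astype(np.float32)))
        assert out.shape == (2, 1, 32, 32)
        assert np.all((out.data > 0) & (out.data < 1))

    def test_indivisible_resolution_raises(self, rng):
        net = build_ascunet(SMALL, seed=0)
        with pytest.raises(ValueError, match="divisible"):
            net(Tensor(np.zeros((1, 3, 30, 30), np.float32)))

    def test_encoder_widths_double_and_decoder_mirrors(self):
        net = build_ascunet(NetworkConfig(base_channels=8, depth=3), seed=0)
        enc_widths = [e.conv2.out_channels for e in net.encoders]
        assert enc_widths == [8, 16, 32]
        assert net.bottleneck.conv2.out_channels == 64
        dec_widths = [d.channels for d in net.decoders]
        assert dec_widths == [32, 16, 8]

    def test_all_eight_variants_forward(self, rng):
        x = Tensor(rng.normal(size=(1, 3, 16, 16)).astype(np.float32))
        for name, net in ablation_suite(SMALL, seed=0):
            out = net(x)
            assert out.shape == (1, 1, 16, 16), name

    def test_gradient_reaches_every_parameter_of_every_variant(self, rng):
        x = Tensor(rng.normal(size=(2, 3, 8, 8)).astype(np.float32))
        y = (rng.random((2, 1, 8, 8)) > 0.5).astype(np.float32)
        for name, net in ablation_suite(NetworkConfig(base_channels=4, depth=1), seed=1):
            out = net(x)
            loss = ((out - Tensor(y)) ** 2.0).mean()
            loss.backward()
            for pname, p in net.named_parameters():
                assert p.grad is not None, f"{name}: no grad on {pname}"
                assert np.all(np.isfinite(p.grad)), f"{name}: {pname}"
                assert np.any(p.grad != 0), f"{name}: dead parameter {pname}"


class TestAblationSuite:
    def test_eight_distinct_configurations(self):
        suite = ablation_suite(SMALL, seed=0)
        assert [name for name, _ in suite] == list(VARIANTS)
        configs = {(n.config.attention.ag, n.config.attention.spatial,
                    n.config.attention.channel) for _, n in suite}
        assert len(configs) == 8

    def test_parameter_count_strictly_increases_per_flag(self):
        counts = {name: net.num_parameters() for name, net in ablation_suite(SMALL, seed=0)}
        # switching any single flag on (all else fixed) adds parameters
        for off, on in [("No-attention", "single-AG"), ("No-attention", "single-spatial"),
                        ("No-attention", "single-channel"), ("single-spatial", "AG+spatial"),
                        ("single-channel", "AG+channel"), ("single-AG", "AG+spatial"),
                        ("single-AG", "AG+channel"), ("AG+spatial", "Ours"),
                        ("AG+channel", "Ours"), ("Spatial+channel", "Ours"),
                        ("single-spatial", "Spatial+channel"),
                        ("single-channel", "Spatial+channel")]:
            assert counts[on] > counts[off], (off, on)

    def test_variant_names_round_trip_through_parser(self):
        from ascunet.cli import build_parser
        parser = build_parser()
        for name in VARIANTS:
            args = parser.parse_args(["train", "--data", "x", "--out", "y",
                                      "--variant", name])
            assert variant_config(args.variant) == VARIANTS[name]

    def test_no_attention_forward_is_bitwise_plain_unet(self, rng):
        """A plain U-Net forward pass written from primitives reproduces the
        No-attention variant bit-for-bit under a shared seed."""
        net = build_ascunet(NetworkConfig(base_channels=4, depth=2,
                                          attention=AttentionConfig(False, False, False)),
                            seed=5).eval()
        x = Tensor(rng.normal(size=(1, 3, 16, 16)).astype(np.float32))

        def conv_block(block, t):
            t = ad.relu(block.bn1(ad.conv2d(t, block.conv1.weight, block.conv1.bias, pad=1)))
            return ad.relu(block.bn2(ad.conv2d(t, block.conv2.weight, block.conv2.bias, pad=1)))

        t = x
        skips = []
        for enc in net.encoders:
            t = conv_block(enc, t)
            skips.append(t)
            t = ad.maxpool2x2(t)
        t = conv_block(net.bottleneck, t)
        for dec, skip in zip(net.decoders, reversed(skips)):
            up = ad.conv_transpose2d_2x2(t, dec.up.weight, dec.up.bias)
            t = ad.concat([skip, up], axis=1)
            t = ad.relu(dec.bn1(ad.conv2d(t, dec.conv1.weight, dec.conv1.bias, pad=1)))
        ref = ad.sigmoid(ad.conv2d(t, net.head.weight, net.head.bias, pad=0))
        np.testing.assert_array_equal(net(x).data, ref.data)
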