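"""Backbone assembly: layer contracts, the dimensional ledger of the
reference configuration, Conformer residual structure, parameter count and
checkpoint round-trips."""

import numpy as np
import pytest
from scipy.special import erf

from tanet.backbone import (ClassifierHead, ConformerBlock,
                            ConformerConvModule, ConformerFFN, ConvBlock,
                            ModelConfig, SequenceProjection, TANet,
                            count_trainable_parameters, load_checkpoint,
                            save_checkpoint)
from tanet.nn import Linear, Tensor
from tanet.nn.functional import adaptive_avg_pool2d

rng = np.random.default_rng(0)
CFG = ModelConfig.seed_config()


def gelu_exact(x):
    return x * 0.5 * (1 + erf(x / np.sqrt(2)))


class TestConvBlock:
    def test_channel_ledger_5_to_64(self):
        block = ConvBlock(CFG, np.random.default_rng(0)).eval()
        out = block(Tensor(rng.standard_normal((2, 5, 62, 10))))
        assert out.shape == (2, 64, 62, 10)

    def test_padding_keeps_degenerate_spatial_input_defined(self):
        block = ConvBlock(CFG, np.random.default_rng(0)).eval()
        assert block(Tensor(rng.standard_normal((1, 5, 1, 1)))
                     ).shape == (1, 64, 1, 1)

    def test_wrong_channel_count_rejected(self):
        block = ConvBlock(CFG, np.random.default_rng(0)).eval()
        with pytest.raises(ValueError, match="channels"):
            block(Tensor(np.zeros((1, 4, 8, 8))))

    def test_convolution_sum_matches_manual_arithmetic(self):
        from tanet.nn import Conv2d
        conv = Conv2d(1, 1, 3, np.random.default_rng(0), padding=0)
        x = rng.standard_normal((1, 1, 3, 3))
        expected = (x[0, 0] * conv.weight.data[0, 0]).sum() \
            + conv.bias.data[0]
        got = conv(Tensor(x)).numpy()[0, 0, 0, 0]
        assert got == pytest.approx(expected, abs=1e-6)


class TestAdaptivePool:
    def test_downsample_62_to_31_averages_2x1_bins(self):
        x = rng.standard_normal((1, 2, 62, 10))
        out = adaptive_avg_pool2d(Tensor(x), (31, 10)).numpy()
        expected = x.reshape(1, 2, 31, 2, 10).mean(axis=3)
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_constant_input_preserved(self):
        out = adaptive_avg_pool2d(Tensor(np.full((1, 1, 32, 3), 2.5)),
                                  (31, 10)).numpy()
        np.testing.assert_allclose(out, 2.5, atol=1e-12)

    def test_upsampling_path_reaches_target_shape(self):
        out = adaptive_avg_pool2d(Tensor(rng.standard_normal((2, 64, 32, 3))),
                                  (31, 10))
        assert out.shape == (2, 64, 31, 10)


class TestSequenceProjection:
    def test_fan_in_is_1984_and_output_is_b_10_256(self):
        proj = SequenceProjection(CFG, np.random.default_rng(0))
        assert proj.fan_in == 1984
        out = proj(Tensor(rng.standard_normal((2, 64, 31, 10))))
        assert out.shape == (2, 10, 256)

    def test_layernorm_rows_standardised_pre_affine(self):
        proj = SequenceProjection(CFG, np.random.default_rng(0))
        out = proj(Tensor(rng.standard_normal((1, 64, 31, 10)))).numpy()
        np.testing.assert_allclose(out.mean(axis=-1), 0.0, atol=1e-5)
        np.testing.assert_allclose(out.var(axis=-1), 1.0, atol=1e-3)

    def test_wrong_shape_rejected(self):
        proj = SequenceProjection(CFG, np.random.default_rng(0))
        with pytest.raises(ValueError, match="expected"):
            proj(Tensor(np.zeros((1, 64, 30, 10))))


class TestConformerModules:
    def test_ffn_preserves_shape_and_zero_weights_zero_output(self):
        ffn = ConformerFFN(256, 4, 0.1, np.random.default_rng(0)).eval()
        x = Tensor(rng.standard_normal((2, 10, 256)))
        assert ffn(x).shape == (2, 10, 256)
        for p in ffn.linear1.parameters() + ffn.linear2.parameters():
            p.data[:] = 0.0
        np.testing.assert_array_equal(ffn(x).numpy(), 0.0)

    def test_ffn_scalar_oracle_with_hand_weights(self):
        ffn = ConformerFFN(2, 2, 0.0, np.random.default_rng(0)).eval()
        w1 = np.array([[1.0, -1.0, 0.5, 0.0], [0.0, 2.0, -0.5, 1.0]],
                      dtype=np.float32)
        b1 = np.array([0.1, -0.1, 0.0, 0.2], dtype=np.float32)
        w2 = np.array([[1.0, 0.0], [0.5, -1.0], [0.0, 1.0], [2.0, 0.5]],
                      dtype=np.float32)
        b2 = np.array([-0.2, 0.3], dtype=np.float32)
        ffn.linear1.weight.data, ffn.linear1.bias.data = w1, b1
        ffn.linear2.weight.data, ffn.linear2.bias.data = w2, b2
        x = np.array([[[0.7, -1.3]]])
        mu, sd = x.mean(), x.std()
        normed = (x - mu) / np.sqrt(sd ** 2 + 1e-5)
        expected = gelu_exact(normed @ w1 + b1) @ w2 + b2
        np.testing.assert_allclose(ffn(Tensor(x)).numpy(), expected,
                                   atol=1e-6)

    def test_depthwise_identity_kernel_is_identity(self):
        conv = ConformerConvModule(4, 5, 0.0, np.random.default_rng(0)).eval()
        conv.depthwise.weight.data[:] = 0.0
        conv.depthwise.weight.data[:, 2] = 1.0  # centre tap
        x = rng.standard_normal((1, 6, 4))
        normed = conv.norm(Tensor(x)).numpy()
        z = conv.depthwise(conv.norm(Tensor(x)).swapaxes(1, 2)).numpy()
        np.testing.assert_allclose(z, normed.swapaxes(1, 2), atol=1e-6)

    def test_pointwise_identity_matrix_is_identity(self):
        lin = Linear(3, 3, np.random.default_rng(0))
        lin.weight.data = np.eye(3, dtype=np.float32)
        lin.bias.data[:] = 0.0
        z = rng.standard_normal((2, 5, 3))
        np.testing.assert_allclose(lin(Tensor(z)).numpy(), z, atol=1e-7)

    def test_depthwise_manual_convolution_oracle(self):
        from tanet.nn.functional import depthwise_conv1d
        w = np.array([[1.0, 2.0, 3.0, 2.0, 1.0]])
        x = rng.standard_normal((1, 1, 5))
        out = depthwise_conv1d(Tensor(x), Tensor(w), None, 2).numpy()
        expected = np.convolve(x[0, 0], w[0][::-1], mode="same")
        np.testing.assert_allclose(out[0, 0], expected, atol=1e-10)

    def test_zeroed_submodules_reduce_block_to_layernorm(self):
        block = ConformerBlock(CFG, np.random.default_rng(0)).eval()
        for mod in (block.ffn1.linear1, block.ffn1.linear2,
                    block.ffn2.linear1, block.ffn2.linear2,
                    block.attn.out_proj, block.conv.pointwise):
            for p in mod.parameters():
                p.data[:] = 0.0
        x = rng.standard_normal((2, 10, 256))
        out = block(Tensor(x)).numpy()
        expected = block.final_norm(Tensor(x)).numpy()
        np.testing.assert_allclose(out, expected, atol=1e-6)

    def test_block_preserves_shape_and_attention_rows_normalised(self):
        block = ConformerBlock(CFG, np.random.default_rng(0)).eval()
        out = block(Tensor(rng.standard_normal((2, 10, 256))))
        assert out.shape == (2, 10, 256)
        attn = block.attn.last_attention
        assert attn.shape == (2, 8, 10, 10)
        np.testing.assert_allclose(attn.sum(axis=-1), 1.0, atol=1e-5)


class TestClassifier:
    def test_probabilities_normalised(self):
        head = ClassifierHead(CFG, np.random.default_rng(0)).eval()
        probs = head.probabilities(Tensor(rng.standard_normal((5, 256))))
        np.testing.assert_allclose(probs.numpy().sum(axis=1), 1.0, atol=1e-6)

    def test_zero_final_layer_gives_uniform_probabilities(self):
        head = ClassifierHead(CFG, np.random.default_rng(0)).eval()
        head.fc3.weight.data[:] = 0.0
        head.fc3.bias.data[:] = 0.0
        probs = head.probabilities(Tensor(rng.standard_normal((4, 256))))
        np.testing.assert_allclose(probs.numpy(), 1.0 / 3.0, atol=1e-7)

    def test_binary_head_for_deap_config(self):
        head = ClassifierHead(ModelConfig.deap_config(),
                              np.random.default_rng(0)).eval()
        assert head.probabilities(
            Tensor(rng.standard_normal((2, 256)))).shape == (2, 2)


class TestFullModel:
    def test_dimensional_ledger_row_for_row(self, seed_features_small):
        de, psd, _ = seed_features_small
        model = TANet(CFG, seed=0).eval()
        B = 2
        d, p = Tensor(de.values[:B]), Tensor(psd.values[:B])
        fused = model.mca(d, p)
        assert fused.shape == (B, 5, 62, 10)
        refined = model.cbam(fused)
        assert refined.shape == (B, 5, 62, 10)
        conv = model.conv(refined)
        assert conv.shape == (B, 64, 62, 10)
        pooled = adaptive_avg_pool2d(conv, CFG.pool_target)
        assert pooled.shape == (B, 64, 31, 10)
        seq = model.projection(pooled)
        assert seq.shape == (B, 10, 256)
        for block in model.blocks.layers:
            seq = block(seq)
            assert seq.shape == (B, 10, 256)
        probs = model.classifier.probabilities(seq.mean(axis=1))
        assert probs.shape == (B, 3)
        np.testing.assert_allclose(probs.numpy().sum(axis=1), 1.0, atol=1e-6)

    def test_forward_probabilities_and_eval_determinism(self,
                                                        seed_features_small):
        de, psd, _ = seed_features_small
        model = TANet(CFG, seed=1).eval()
        a = model.forward(de.values[:2], psd.values[:2]).numpy()
        b = model.forward(de.values[:2], psd.values[:2]).numpy()
        np.testing.assert_array_equal(a, b)
        np.testing.assert_allclose(a.sum(axis=1), 1.0, atol=1e-6)

    def test_global_average_pool_of_constant_sequence(self):
        x = Tensor(np.tile(np.arange(4.0), (1, 5, 1)))
        np.testing.assert_allclose(x.mean(axis=1).numpy(),
                                   np.arange(4.0)[None], atol=1e-12)

    def test_layout_mismatch_rejected(self):
        model = TANet(CFG, seed=0).eval()
        bad = np.zeros((1, 5, 32, 10))
        with pytest.raises(ValueError, match="layout"):
            model.forward(bad, bad)


class TestParameterCount:
    def test_reference_configuration_counts_3_34_million(self):
        model = TANet(CFG, seed=0)
        n = count_trainable_parameters(model)
        assert abs(n / 1e6 - 3.34) <= 0.005

    def test_single_linear_layer_count(self):
        lin = Linear(256, 128, np.random.default_rng(0))
        assert sum(p.data.size for p in lin.parameters()) == 32_896

    def test_freezing_classifier_drops_exactly_its_parameters(self):
        model = TANet(CFG, seed=0)
        full = count_trainable_parameters(model)
        head = sum(p.data.size for p in model.classifier.parameters())
        for p in model.classifier.parameters():
            p.requires_grad = False
        assert count_trainable_parameters(model) == full - head


class TestCheckpoint:
    def test_roundtrip_is_bit_exact_in_eval_mode(self, tmp_path, tiny_config,
                                                 tiny_dataset):
        de, psd, _ = tiny_dataset
        model = TANet(tiny_config, seed=4).eval()
        before = model.forward(de[:3], psd[:3]).numpy()
        save_checkpoint(model, tmp_path / "ckpt")
        restored = load_checkpoint(tmp_path / "ckpt").eval()
        after = restored.forward(de[:3], psd[:3]).numpy()
        np.testing.assert_array_equal(before, after)
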