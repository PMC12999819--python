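"""Hybrid CNN-Transformer block: splitting rules, sub-block contracts, and
hand-computed oracles for the attention and gated units."""
import numpy as np
import pytest

from whorlnet import nn
from whorlnet.core_blocks import (CGLUBlock, CNNBranch, HCTBlock, HCTConfig,
                                  HCTConfigError, MHABlock, hct_split)
from whorlnet.nn import Tensor, concat


def fmap(rng, c, h=6, w=6, b=1):
    return Tensor(rng.normal(size=(b, c, h, w)).astype(np.float32))


class TestSplit:
    def test_quarter_three_quarter_ratio(self, rng):
        cfg = HCTConfig(in_channels=256)
        cnn, tr = hct_split(fmap(rng, 256), cfg)
        assert cnn.shape[1] == 64 and tr.shape[1] == 192

    def test_zero_fraction_degenerates_to_cnn(self, rng):
        cfg = HCTConfig(in_channels=32, transformer_fraction=0.0)
        cnn, tr = hct_split(fmap(rng, 32), cfg)
        assert cnn.shape[1] == 32 and tr.shape[1] == 0

    @pytest.mark.parametrize("c,expected_t", [(8, 0), (16, 8), (32, 24)])
    def test_head_divisibility_rounding(self, c, expected_t):
        # enumerated oracle: t = round(0.75*c) snapped down to a multiple of 8
        cfg = HCTConfig(in_channels=c, transformer_fraction=0.75, num_heads=8)
        assert cfg.transformer_channels == expected_t
        assert cfg.transformer_channels + cfg.cnn_channels == c

    def test_concat_restores_input(self, rng):
        cfg = HCTConfig(in_channels=48)
        x = fmap(rng, 48)
        cnn, tr = hct_split(x, cfg)
        np.testing.assert_array_equal(concat([cnn, tr], 1).data, x.data)

    def test_channel_mismatch_raises(self, rng):
        with pytest.raises(HCTConfigError, match="expects 64, input has 32"):
            hct_split(fmap(rng, 32), HCTConfig(in_channels=64))


class TestCNNBranch:
    def test_shape_preserved(self, rng):
        cfg = HCTConfig(in_channels=256)  # cnn width 64
        m = CNNBranch(cfg)
        x = fmap(rng, 64, 5, 7)
        assert m(x).shape == x.shape

    def test_zero_weights_pure_residual(self, rng):
        m = CNNBranch(HCTConfig(in_channels=128))  # cnn width 32
        for p in m.parameters():
            p.data[:] = 0
        m.eval()
        x = fmap(rng, 32)
        np.testing.assert_allclose(m(x).data, x.data, atol=1e-6)

    def test_parameter_hand_count(self):
        # reduce 64->32, restore 32->64, both 3x3 conv+BN
        cfg = HCTConfig(in_channels=256, cnn_reduction=0.5)
        m = CNNBranch(cfg)
        expected = (64 * 32 * 9 + 2 * 32) + (32 * 64 * 9 + 2 * 64)
        assert m.num_params() == expected


class TestMHA:
    def test_shape_and_head_arithmetic(self, rng):
        cfg = HCTConfig(in_channels=256)  # t=192, 8 heads -> head dim 24
        m = MHABlock(cfg)
        assert m.head_dim == 24
        x = fmap(rng, 192, 4, 5)
        assert m(x).shape == x.shape

    def test_snapping_always_yields_divisible_width(self):
        # the rounding rule guarantees head divisibility for any config
        for c in range(8, 257, 8):
            for heads in (2, 4, 8):
                for f in (0.25, 0.5, 0.75, 1.0):
                    cfg = HCTConfig(in_channels=c, transformer_fraction=f,
                                    num_heads=heads)
                    assert cfg.transformer_channels % heads == 0
                    assert cfg.transformer_channels + cfg.cnn_channels == c

    def test_two_token_attention_matches_hand_softmax(self):
        # single head, width 2: attention weights equal the softmax of the
        # 2x2 score matrix computed independently below
        cfg = HCTConfig(in_channels=2, transformer_fraction=1.0, num_heads=1)
        m = MHABlock(cfg)
        q = np.array([[1.0, 0.0], [0.0, 2.0]], dtype=np.float32)
        k = np.array([[0.5, -1.0], [1.5, 0.3]], dtype=np.float32)
        v = np.array([[2.0, 1.0], [-1.0, 3.0]], dtype=np.float32)
        qkv = np.concatenate([q, k, v], axis=1)[None]  # (1, 2, 6)
        out = m.attention(Tensor(qkv)).data[0]
        scores = q @ k.T / np.sqrt(2.0)
        e = np.exp(scores - scores.max(1, keepdims=True))
        attn = e / e.sum(1, keepdims=True)
        np.testing.assert_allclose(out, attn @ v, rtol=1e-5)

    def test_single_token_attention_is_identity_on_value(self, rng):
        cfg = HCTConfig(in_channels=8, transformer_fraction=1.0, num_heads=2)
        m = MHABlock(cfg)
        qkv = rng.normal(size=(1, 1, 24)).astype(np.float32)
        out = m.attention(Tensor(qkv)).data
        np.testing.assert_allclose(out[0, 0], qkv[0, 0, 16:], rtol=1e-5)

    def test_constant_value_tokens_pass_through(self, rng):
        # row-normalization: if every token has the same value vector, the
        # attention output equals it whatever the scores are
        cfg = HCTConfig(in_channels=8, transformer_fraction=1.0, num_heads=2)
        m = MHABlock(cfg)
        qk = rng.normal(size=(1, 5, 16)).astype(np.float32)
        v = np.tile(rng.normal(size=(1, 1, 8)).astype(np.float32), (1, 5, 1))
        out = m.attention(Tensor(np.concatenate([qk, v], -1))).data
        np.testing.assert_allclose(out, v, rtol=1e-4, atol=1e-5)


class TestCGLU:
    def test_shape(self, rng):
        m = CGLUBlock(HCTConfig(in_channels=256))
        x = fmap(rng, 192, 4, 4)
        assert m(x).shape == x.shape

    def test_saturated_gate_leaves_residual_only(self, rng):
        m = CGLUBlock(HCTConfig(in_channels=32))  # t=24
        m.dw.bias.data[:] = -40.0  # GELU(-40) == 0
        m.dw.weight.data[:] = 0
        m.fc2.bias.data[:] = 0
        x = fmap(rng, 24)
        np.testing.assert_allclose(m(x).data, x.data, atol=1e-6)

    def test_single_pixel_depthwise_is_center_tap(self, rng):
        # 1x1 spatial input: the padded 3x3 depth-wise conv reduces to a
        # per-channel scalar multiply by the center tap plus bias
        m = CGLUBlock(HCTConfig(in_channels=16, cglu_expansion=1.0))  # t=8, h=8
        x = rng.normal(size=(1, 8, 1, 1)).astype(np.float32)
        out = m.dw(Tensor(x)).data
        center = m.dw.weight.data[:, 0, 1, 1]
        expected = x[0, :, 0, 0] * center + m.dw.bias.data
        np.testing.assert_allclose(out[0, :, 0, 0], expected, rtol=1e-5)


class TestHCTBlock:
    @pytest.mark.parametrize("c,h,w", [(128, 5, 5), (64, 3, 7)])
    def test_forward_preserves_shape(self, rng, c, h, w):
        m = HCTBlock(HCTConfig(in_channels=c))
        x = fmap(rng, c, h, w)
        assert m(x).shape == x.shape

    def test_full_transformer_fraction(self, rng):
        m = HCTBlock(HCTConfig(in_channels=64, transformer_fraction=1.0))
        assert not hasattr(m, "cnn")
        x = fmap(rng, 64, 4, 4)
        assert m(x).shape == x.shape

    def test_batch_permutation_equivariance(self, rng):
        m = HCTBlock(HCTConfig(in_channels=32))
        m.eval()
        x = rng.normal(size=(3, 32, 4, 4)).astype(np.float32)
        out = m(Tensor(x)).data
        out_rev = m(Tensor(x[::-1].copy())).data
        np.testing.assert_allclose(out_rev, out[::-1], rtol=1e-5, atol=1e-6)

    def test_zeroed_blocks_reduce_to_fuse_of_identity(self, rng):
        cfg = HCTConfig(in_channels=32)
        m = HCTBlock(cfg)
        for name in ("cnn", "mha", "cglu"):
            for p in getattr(m, name).parameters():
                p.data[:] = 0
        m.eval()
        x = fmap(rng, 32)
        np.testing.assert_allclose(m(x).data, m.fuse(x).data, atol=1e-5)

    def test_param_count_matches_sum_of_sub_blocks(self):
        m = HCTBlock(HCTConfig(in_channels=256))
        total = (m.cnn.num_params() + m.mha.num_params()
                 + m.cglu.num_params() + m.fuse.num_params())
        assert m.num_params() == total
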