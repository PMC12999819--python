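"""Neck blocks: weighted fusion closed forms, channel shuffle permutation,
heterogeneous-kernel blocks, and the assembled pyramid graph."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from whorlnet import nn
from whorlnet.mbms_fpn import (DCMSCK, EMSCB, EUCB, MBMSFPN, NHKSM,
                               FusionError, NeckConfig, NeckConfigError,
                               WeightedFusion, channel_shuffle,
                               shuffle_permutation, weighted_fusion)
from whorlnet.nn import Tensor


def fmap(rng, c, h=4, w=4):
    return Tensor(rng.normal(size=(1, c, h, w)).astype(np.float32))


class TestWeightedFusion:
    def test_equal_weights_closed_form(self, rng):
        a, b = fmap(rng, 3), fmap(rng, 3)
        out = weighted_fusion([a, b], [1.0, 1.0], eps=1e-4)
        coef = 1.0 / (2.0 + 1e-4)
        np.testing.assert_allclose(out.data, coef * (a.data + b.data), rtol=1e-5)

    def test_negative_weight_clamped_to_zero(self, rng):
        a, b = fmap(rng, 2), fmap(rng, 2)
        out = weighted_fusion([a, b], [5.0, -3.0], eps=1e-4)
        np.testing.assert_allclose(out.data, a.data * (5.0 / (5.0 + 1e-4)),
                                   rtol=1e-5)

    def test_all_zero_weights_give_zero_map(self, rng):
        out = weighted_fusion([fmap(rng, 2), fmap(rng, 2)], [0.0, 0.0], 1e-4)
        np.testing.assert_array_equal(out.data, np.zeros_like(out.data))

    def test_shape_mismatch_reports_shapes(self, rng):
        node = WeightedFusion(2)
        with pytest.raises(FusionError, match="shapes differ"):
            node([fmap(rng, 2, 4, 4), fmap(rng, 2, 8, 8)])

    @given(st.lists(st.floats(-5, 50), min_size=2, max_size=5))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_coefficients_nonnegative_sum_below_one(self, weights):
        node = WeightedFusion(len(weights), eps=1e-4)
        node.weights.data[:] = weights
        coef = node.coefficients().data
        assert (coef >= 0).all()
        assert 0.0 <= coef.sum() < 1.0

    def test_coefficient_sum_approaches_one(self):
        node = WeightedFusion(2, eps=1e-4)
        node.weights.data[:] = [1e6, 1e6]
        assert node.coefficients().data.sum() > 0.999999


class TestChannelShuffle:
    @pytest.mark.parametrize("c,g", [(c, g) for c in range(2, 13)
                                     for g in range(1, 13) if c % g == 0])
    def test_matches_brute_force_permutation(self, c, g):
        # oracle: enumerate the reshape->transpose index mapping directly
        x = Tensor(np.arange(c, dtype=np.float32).reshape(1, c, 1, 1))
        out = channel_shuffle(x, g).data[:, :, 0, 0].ravel()
        brute = [gi * (c // g) + i for i in range(c // g) for gi in range(g)]
        np.testing.assert_array_equal(out, np.array(brute, dtype=np.float32))
        assert shuffle_permutation(c, g) == brute

    def test_six_channels_three_groups(self):
        x = Tensor(np.arange(6, dtype=np.float32).reshape(1, 6, 1, 1))
        out = channel_shuffle(x, 3).data.ravel()
        np.testing.assert_array_equal(out, [0, 2, 4, 1, 3, 5])

    def test_identity_for_one_group(self, rng):
        x = fmap(rng, 8)
        np.testing.assert_array_equal(channel_shuffle(x, 1).data, x.data)

    def test_inverse_restores_input(self, rng):
        x = fmap(rng, 12)
        y = channel_shuffle(x, 3)
        perm = shuffle_permutation(12, 3)
        inv = np.argsort(perm)
        np.testing.assert_array_equal(y.data[:, inv], x.data)

    def test_is_permutation_of_channel_contents(self, rng):
        x = fmap(rng, 8)
        y = channel_shuffle(x, 4)
        a = np.sort(x.data.reshape(8, -1), axis=0)
        b = np.sort(y.data.reshape(8, -1), axis=0)
        np.testing.assert_array_equal(a, b)

    def test_indivisible_raises(self, rng):
        with pytest.raises(NeckConfigError, match="not divisible"):
            channel_shuffle(fmap(rng, 7), 3)


class TestEUCB:
    def test_doubles_resolution_and_matches_channels(self, rng):
        m = EUCB(16, 16)
        out = m(fmap(rng, 16, 5, 7))
        assert out.shape == (1, 16, 10, 14)

    def test_channel_matching_contract(self, rng):
        m = EUCB(16, 8)
        assert m(fmap(rng, 16, 4, 4)).shape == (1, 8, 8, 8)

    def test_constant_input_constant_after_upsampling(self, rng):
        x = Tensor(np.full((1, 4, 3, 3), 2.5, dtype=np.float32))
        m = EUCB(4, 4)
        up = m.up(x)
        assert np.all(up.data == 2.5)


class TestDCMSCK:
    def test_parallel_branches_preserve_shape(self, rng):
        m = DCMSCK(16, [1, 3, 5])
        x = fmap(rng, 16, 6, 6)
        assert m(x).shape == x.shape
        assert len(m.branches) == 3

    def test_even_kernel_rejected(self):
        with pytest.raises(NeckConfigError, match="odd"):
            DCMSCK(8, [2])

    def test_single_kernel_equals_plain_branch_oracle(self, rng):
        # DCMSCK with one kernel == x + BN-ReLU(dwconv(x)), shuffle trivial
        m = DCMSCK(8, [3])
        m.eval()
        x = fmap(rng, 8)
        expected = x.data + m.branches[0](x).data
        np.testing.assert_allclose(m(x).data, expected, rtol=1e-5)

    def test_identity_initialized_1x1_branch(self, rng):
        m = DCMSCK(6, [1])
        br = m.branches[0]
        br.conv.weight.data[:] = 1.0  # 1x1 depth-wise identity kernel
        br.bn.weight.data[:] = 1.0
        br.bn.bias.data[:] = 0.0
        br.bn.register_buffer("running_mean", np.zeros(6, dtype=np.float32))
        br.bn.register_buffer("running_var", np.ones(6, dtype=np.float32) - 1e-3)
        m.eval()
        x = fmap(rng, 6)
        np.testing.assert_allclose(br(x).data, np.maximum(x.data, 0), atol=1e-4)

    def test_parameter_hand_count(self):
        c, kernels = 512, [3, 5, 7]
        m = DCMSCK(c, kernels)
        expected = sum(k * k * c + 2 * c for k in kernels)
        assert m.num_params() == expected


class TestEMSCB:
    def test_internal_width_is_expansion_times_input(self):
        m = EMSCB(256, [1, 3, 5], expansion=2.0)
        assert m.expand.conv.weight.data.shape[0] == 512

    def test_zeroed_projection_residual_identity(self, rng):
        m = EMSCB(8, [3], expansion=2.0)
        m.project.conv.weight.data[:] = 0
        m.project.bn.bias.data[:] = 0
        m.eval()
        x = fmap(rng, 8)
        np.testing.assert_allclose(m(x).data, x.data, atol=1e-6)

    def test_level_changes_kernels_not_shapes(self, rng):
        cfg = NeckConfig(neck_channels=32)
        x = fmap(rng, 32)
        from whorlnet.mbms_fpn import emscb_forward
        for level in ("P3", "P4", "P5"):
            assert emscb_forward(x, cfg, level).shape == x.shape


class TestNHKSM:
    def test_shape_contract(self, rng):
        cfg = NeckConfig(neck_channels=32)
        m = NHKSM(cfg, "P3")
        x = fmap(rng, 32, 8, 8)
        assert m(x).shape == x.shape

    def test_csp_split_width_follows_config(self):
        cfg = NeckConfig(neck_channels=256)
        assert NHKSM(cfg, "P3").split == 64      # 0.25 fraction
        assert NHKSM(cfg, "P5").split == 128     # 0.5 fraction

    def test_kernel_groups_follow_level_config(self):
        cfg = NeckConfig(neck_channels=32)
        for level, ks in (("P3", [1, 3, 5]), ("P4", [3, 5, 7]), ("P5", [5, 7, 9])):
            m = NHKSM(cfg, level)
            got = [br.conv.weight.data.shape[-1] for br in m.emscb.dcmsck.branches]
            assert got == ks


class TestNeckGraph:
    def _feats(self, rng, base=16, ch=(8, 12, 16)):
        return {"P3": fmap(rng, ch[0], 4 * base // 16, 4 * base // 16),
                "P4": fmap(rng, ch[1], 2 * base // 16, 2 * base // 16),
                "P5": fmap(rng, ch[2], base // 16, base // 16)}

    def test_outputs_all_at_neck_width_and_input_resolutions(self, rng):
        cfg = NeckConfig(neck_channels=32)
        feats = {"P3": fmap(rng, 24, 16, 16), "P4": fmap(rng, 12, 8, 8),
                 "P5": fmap(rng, 48, 4, 4)}
        m = MBMSFPN({k: v.shape[1] for k, v in feats.items()}, cfg)
        out = m(feats)
        assert out["P3"].shape == (1, 32, 16, 16)
        assert out["P4"].shape == (1, 32, 8, 8)
        assert out["P5"].shape == (1, 32, 4, 4)

    def test_scale_equivariance_of_graph(self, rng):
        cfg = NeckConfig(neck_channels=32)
        m = MBMSFPN({"P3": 8, "P4": 8, "P5": 8}, cfg)
        small = {"P3": fmap(rng, 8, 8, 8), "P4": fmap(rng, 8, 4, 4),
                 "P5": fmap(rng, 8, 2, 2)}
        big = {"P3": fmap(rng, 8, 16, 16), "P4": fmap(rng, 8, 8, 8),
               "P5": fmap(rng, 8, 4, 4)}
        for level, o in m(small).items():
            assert m(big)[level].shape[2] == 2 * o.shape[2]

    def test_non_pyramidal_inputs_raise(self, rng):
        cfg = NeckConfig(neck_channels=16)
        m = MBMSFPN({"P3": 8, "P4": 8, "P5": 8}, cfg)
        bad = {"P3": fmap(rng, 8, 8, 8), "P4": fmap(rng, 8, 8, 8),
               "P5": fmap(rng, 8, 2, 2)}
        with pytest.raises(NeckConfigError, match="pyramid"):
            m(bad)

    def test_config_validation(self):
        with pytest.raises(NeckConfigError, match="odd"):
            NeckConfig(kernel_groups={"P3": [2, 3, 5], "P4": [3, 5, 7],
                                      "P5": [5, 7, 9]})
        with pytest.raises(NeckConfigError, match="increasing"):
            NeckConfig(kernel_groups={"P3": [5, 3, 1], "P4": [3, 5, 7],
                                      "P5": [5, 7, 9]})
        with pytest.raises(NeckConfigError, match="epsilon"):
            NeckConfig(fusion_epsilon=0.0)

    def test_yaml_round_trip_of_kernel_groups(self, tmp_path):
        import yaml
        from dataclasses import asdict
        cfg = NeckConfig()
        path = tmp_path / "neck.yaml"
        path.write_text(yaml.safe_dump(asdict(cfg)))
        loaded = NeckConfig(**yaml.safe_load(path.read_text()))
        assert loaded == cfg
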