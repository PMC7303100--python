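"""Tests for the five architectures, conv4d and parameter accounting."""

import numpy as np
import pytest

from octmotion.nets import (MODEL_NAMES, BaselineTrunk, DenseBlock,
                            ModelConfig, Prediction, build_model, conv4d,
                            count_parameters, forward)
from octmotion.nn import Linear, Tensor, Conv
from octmotion.trajectories import MotionSequence

from .oracles import conv4d_nested_sum

SMALL = ModelConfig(initial_channels=(2, 3, 4), stem_strides=(1, 1, 1))


def _seq(rng, n=12):
    vols = rng.random((5, n, n, n)).astype(np.float32)
    shifts = np.zeros((5, 3))
    return vols, shifts


class TestConv4d:
    def test_all_ones_window_sums_to_16(self):
        x = np.ones((3, 4, 4, 4, 1))
        w = np.ones((2, 2, 2, 2, 1, 1))
        y = conv4d(x, w, bias=np.zeros(1), padding="valid")
        assert y.shape == (2, 3, 3, 3, 1)
        np.testing.assert_array_equal(y, 16.0)

    def test_kt1_equals_per_frame_3d(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((3, 6, 6, 6, 2))
        w = rng.standard_normal((1, 3, 3, 3, 2, 4))
        y4 = conv4d(x, w, padding="same")
        from octmotion.nn.functional import correlate_nd, same_pads
        for t in range(3):
            y3 = correlate_nd(x[t][None], w[0], same_pads((3, 3, 3)))[0]
            np.testing.assert_allclose(y4[t], y3, rtol=1e-6, atol=1e-6)

    def test_matches_nested_sum_oracle_many_instances(self):
        """>= 50 random small instances against the six-nested-loop oracle."""
        rng = np.random.default_rng(1)
        for _ in range(50):
            kt = int(rng.integers(1, 3))
            ks = tuple(int(rng.integers(1, 3)) for _ in range(3))
            cin, cout = int(rng.integers(1, 3)), int(rng.integers(1, 3))
            T = int(rng.integers(kt, kt + 2))
            S = tuple(int(rng.integers(k, k + 3)) for k in ks)
            x = rng.standard_normal((T, *S, cin))
            w = rng.standard_normal((kt, *ks, cin, cout))
            b = rng.standard_normal(cout)
            got = conv4d(x, w, bias=b, padding="valid")
            want = conv4d_nested_sum(x, w, bias=b)
            np.testing.assert_allclose(got, want, rtol=1e-5, atol=1e-8)

    def test_incompatible_shapes_raise(self):
        with pytest.raises(ValueError):
            conv4d(np.zeros((2, 4, 4, 4, 2)), np.zeros((2, 3, 3, 3, 1, 4)))


class TestDenseBlock:
    def test_channel_growth(self):
        rng = np.random.default_rng(2)
        block = DenseBlock(20, 3, ModelConfig(), rng)
        x = Tensor(rng.standard_normal((1, 4, 4, 4, 20)).astype(np.float32))
        assert block(x).shape[-1] == 40

    def test_three_blocks_add_60_channels(self):
        rng = np.random.default_rng(3)
        cfg = ModelConfig()
        c = 7
        x = Tensor(rng.standard_normal((1, 8, 8, 8, c)).astype(np.float32))
        trunk = BaselineTrunk(c, 3, cfg, rng)
        feats = trunk(x)
        assert trunk.out_channels == c + 60
        assert feats.shape == (1, c + 60)

    def test_invalid_dim_literal(self):
        with pytest.raises(ValueError):
            DenseBlock(4, 5, ModelConfig(), np.random.default_rng(0))

    def test_zero_weights_give_zero_new_channels(self):
        rng = np.random.default_rng(4)
        block = DenseBlock(3, 3, ModelConfig(), rng)
        for cv in block.convs:
            cv.weight.data[:] = 0.0
            cv.bias.data[:] = 0.0
        x = Tensor(np.random.default_rng(0).random((1, 4, 4, 4, 3)).astype(np.float32))
        y = block(x).data
        np.testing.assert_array_equal(y[..., 3:], 0.0)
        np.testing.assert_allclose(y[..., :3], x.data)


class TestTrunk:
    def test_non_divisible_spatial_raises(self):
        rng = np.random.default_rng(5)
        trunk = BaselineTrunk(2, 3, ModelConfig(), rng)
        x = Tensor(np.zeros((1, 6, 6, 6, 2), dtype=np.float32))
        with pytest.raises(ValueError):
            trunk(x)

    def test_constant_input_finite_deterministic(self):
        rng = np.random.default_rng(6)
        trunk = BaselineTrunk(2, 4, ModelConfig(), rng)
        x = Tensor(np.full((1, 5, 8, 8, 8, 2), 0.5, dtype=np.float32))
        a, b = trunk(x).data, trunk(x).data
        assert np.all(np.isfinite(a))
        np.testing.assert_array_equal(a, b)

    def test_temporal_axis_pools_toward_one(self):
        """Five frames pool 5 -> 3 -> 2 across the two pooling stages."""
        rng = np.random.default_rng(7)
        cfg = ModelConfig()
        block = DenseBlock(1, 4, cfg, rng)
        from octmotion.nn.core import avg_pool
        x = Tensor(np.zeros((1, 5, 8, 8, 8, 1), dtype=np.float32))
        y = avg_pool(block(x), (1, 2, 3, 4), (2, 2, 2, 2))
        assert y.shape[1] == 3
        y2 = avg_pool(y, (1, 2, 3, 4), (2, 2, 2, 2))
        assert y2.shape[1] == 2


class TestBuildModel:
    def test_unknown_name(self):
        with pytest.raises(ValueError):
            build_model("resnet", SMALL)

    @pytest.mark.parametrize("name", MODEL_NAMES)
    def test_forward_finite_on_zero_input(self, name):
        model = build_model(name, SMALL, seed=0)
        x = np.zeros((2, 5, 12, 12, 12), dtype=np.float32)
        y = model.forward_batch(x)["y_tn"].data
        assert y.shape == (2, 3)
        assert np.all(np.isfinite(y))

    def test_two_path_and_summed_variant_share_parameter_count(self):
        a = build_model("two_path_3d", SMALL, seed=0)
        b = build_model("s_two_path_3d", SMALL, seed=0)
        assert count_parameters(a) == count_parameters(b)

    def test_five_vs_two_path_count_difference_formula(self):
        """Widths differ only through the trunk/head input channels."""
        cfg = SMALL
        two = build_model("two_path_3d", cfg, seed=0)
        five = build_model("five_path_3d", cfg, seed=0)
        c3 = cfg.initial_channels[-1]
        delta_c = 5 * c3 - 2 * c3
        k3 = cfg.spatial_kernel ** 3
        n_convs = cfg.n_blocks * cfg.layers_per_block
        want = n_convs * cfg.growth_rate * k3 * delta_c + 3 * delta_c
        assert count_parameters(five) - count_parameters(two) == want

    def test_aux_outputs_add_two_heads(self):
        cfg_aux = ModelConfig(initial_channels=(2, 3, 4), aux_outputs=True)
        plain = build_model("five_path_4d", SMALL, seed=0)
        aux = build_model("five_path_4d", cfg_aux, seed=0)
        feat = plain.trunk.out_channels
        assert count_parameters(aux) - count_parameters(plain) == 2 * (3 * feat + 3)

    def test_weight_sharing_is_same_storage(self):
        """Mutating a path's stem weight changes every path's output."""
        model = build_model("five_path_3d", SMALL, seed=1)
        rng = np.random.default_rng(0)
        x = rng.random((1, 5, 12, 12, 12)).astype(np.float32)
        base = model.forward_batch(x)["y_tn"].data.copy()
        model.stem.convs[0].weight.data *= 1.5
        changed = model.forward_batch(x)["y_tn"].data
        assert not np.allclose(base, changed)
        # the stem object is literally the only one: all paths share it
        params_a = {id(p) for p in model.stem.parameters()}
        assert params_a  # non-empty; single stem reused for all five paths

    def test_forward_wrapper_and_prediction(self):
        rng = np.random.default_rng(2)
        vols, shifts = _seq(rng)
        seq = MotionSequence(volumes=vols, shifts=shifts, roi_id=0)
        model = build_model("dense4d", SMALL, seed=0)
        pred = forward(model, seq)
        assert isinstance(pred, Prediction)
        assert pred.y_tn.shape == (3,) and pred.y_tn1 is None
        cfg_aux = ModelConfig(initial_channels=(2, 3, 4), aux_outputs=True)
        pred2 = forward(build_model("dense4d", cfg_aux, seed=0), seq)
        assert pred2.y_tn1.shape == (3,) and pred2.y_tn2.shape == (3,)

    def test_instance_norm_build_runs(self):
        cfg = ModelConfig(initial_channels=(2, 3, 4), use_norm=True)
        model = build_model("five_path_4d", cfg, seed=0)
        x = np.random.default_rng(1).random((2, 5, 12, 12, 12)).astype(np.float32)
        y = model.forward_batch(x)["y_tn"].data
        assert np.all(np.isfinite(y))
        plain = build_model("five_path_4d", SMALL, seed=0)
        assert count_parameters(model) > count_parameters(plain)

    def test_wrong_layout_raises(self):
        model = build_model("five_path_4d", SMALL, seed=0)
        with pytest.raises(ValueError):
            model.forward_batch(np.zeros((1, 12, 12, 12, 5), dtype=np.float32))
        with pytest.raises(ValueError):
            model.forward_batch(np.zeros((1, 3, 12, 12, 12), dtype=np.float32))


class TestCountParameters:
    def test_linear_70_to_3(self):
        lin = Linear(70, 3, np.random.default_rng(0))
        from octmotion.nn import parameter_count
        assert parameter_count(lin) == 213

    def test_conv_3cubed_1_to_8(self):
        conv = Conv(1, 8, (3, 3, 3), np.random.default_rng(0))
        from octmotion.nn import parameter_count
        assert parameter_count(conv) == 224

    def test_no_trainables_is_zero(self):
        from octmotion.nn import Module, parameter_count

        class Empty(Module):
            pass

        assert parameter_count(Empty()) == 0
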