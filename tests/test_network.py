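"""Architecture wiring: shapes, determinism, gradients, parameter counts."""

import numpy as np
import pytest

from cbaseg import _tensor as T
from cbaseg._tensor import Tensor
from cbaseg.network import (
    CBANetwork,
    DNBlock,
    NetworkConfig,
    PBPModule,
    UPBlock,
    aux_features,
    build_cba_network,
    count_parameters,
    dn_block,
    load_checkpoint,
    pbp_module,
    save_checkpoint,
    up_block,
)
from cbaseg.nn import Conv2d, Module

RNG = lambda s: np.random.default_rng(s)


class TestNetworkConfig:
    def test_input_size_must_match_depth(self):
        with pytest.raises(ValueError):
            NetworkConfig(input_size=100)

    def test_bins_must_increase(self):
        with pytest.raises(ValueError):
            NetworkConfig(pbp_bins=(1, 4, 2))

    def test_default_channel_schedule_doubles_then_caps(self):
        cfg = NetworkConfig(base_channels=32)
        assert cfg.encoder_channels() == [32, 64, 128, 256, 256]
        assert cfg.decoder_channels() == [128, 64, 32, 32]

    def test_yaml_roundtrip(self):
        cfg = NetworkConfig(input_size=64, base_channels=8)
        assert NetworkConfig.from_yaml(cfg.to_yaml()) == cfg


class TestDNBlock:
    @pytest.mark.parametrize("side_in,side_out", [(192, 96), (24, 12)])
    def test_halves_spatial_side(self, side_in, side_out):
        blk = DNBlock(2, 4, RNG(0))
        out = dn_block(np.zeros((1, 2, side_in, side_in), dtype=np.float32), blk)
        assert out.shape == (1, 4, side_out, side_out)

    def test_zero_weights_give_zero_output(self):
        blk = DNBlock(2, 4, RNG(0))
        for p in blk.parameters():
            p.data = np.zeros_like(p.data)
        out = dn_block(np.random.default_rng(0).random((1, 2, 8, 8)).astype(np.float32), blk)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_odd_spatial_dims_rejected(self):
        blk = DNBlock(2, 4, RNG(0))
        with pytest.raises(ValueError):
            dn_block(np.zeros((1, 2, 9, 9), dtype=np.float32), blk)


class TestPBPModule:
    def test_doubles_channels_with_four_bins(self):
        mod = PBPModule(8, RNG(0), bins=(1, 2, 4, 8))
        out = pbp_module(np.zeros((1, 8, 16, 16), dtype=np.float32), mod)
        assert out.shape == (1, 16, 16, 16)

    def test_constant_input_gives_constant_branch_planes(self):
        mod = PBPModule(4, RNG(1), bins=(1, 2, 4))
        x = np.full((1, 4, 8, 8), 0.6, dtype=np.float32)
        out = pbp_module(x, mod)
        # every output plane is constant: the input passthrough trivially,
        # each branch because pooling/convolving a constant is constant
        for c in range(out.shape[1]):
            assert np.ptp(out[0, c]) < 1e-5

    def test_branch_matches_loop_oracle_on_single_bin(self):
        """One 4-channel branch with bin 2 against an explicit-loop pipeline."""
        from oracles import blur_filter_loops, blur_max_pool_loops

        mod = PBPModule(4, RNG(2), bins=(2,))
        x = np.random.default_rng(3).random((1, 4, 8, 8)).astype(np.float64)
        out = pbp_module(x.astype(np.float32), mod)

        # oracle: pool 8->4->2 by repeated blur max pooling, dilated 3x3
        # zero-padded conv, relu, blur filter, nearest upsample, concat
        pooled = blur_max_pool_loops(blur_max_pool_loops(x, 3, 2), 3, 2)
        w = mod.branch_convs[0].weight.data.astype(np.float64)
        b = mod.branch_convs[0].bias.data.astype(np.float64)
        d = 2
        conv = np.zeros((1, 1, 2, 2))
        for y in range(2):
            for xx in range(2):
                acc = b[0]
                for c in range(4):
                    for i in range(3):
                        for j in range(3):
                            yy = y + (i - 1) * d
                            xj = xx + (j - 1) * d
                            if 0 <= yy < 2 and 0 <= xj < 2:
                                acc += w[0, c, i, j] * pooled[0, c, yy, xj]
                conv[0, 0, y, xx] = max(0.0, acc)
        branch = blur_filter_loops(conv, 3)
        upsampled = branch[0, 0][[0, 0, 0, 0, 1, 1, 1, 1]][:, [0, 0, 0, 0, 1, 1, 1, 1]]
        np.testing.assert_allclose(out[0, :4], x[0], atol=1e-5)
        np.testing.assert_allclose(out[0, 4], upsampled, atol=1e-5)

    def test_non_divisible_side_handled_by_padding(self):
        mod = PBPModule(4, RNG(4), bins=(1, 2, 4, 8))
        out = pbp_module(np.random.default_rng(0).random((1, 4, 12, 12)).astype(np.float32), mod)
        assert out.shape == (1, 8, 12, 12)

    def test_indivisible_channels_rejected(self):
        with pytest.raises(ValueError):
            PBPModule(6, RNG(0))


class TestUPBlock:
    def test_doubles_spatial_side(self):
        blk = UPBlock(8, 4, RNG(0), bins=(1, 2, 4))
        out = up_block(np.zeros((1, 8, 12, 12), dtype=np.float32), None, blk)
        assert out.shape == (1, 4, 24, 24)

    def test_zero_weights_give_zero_doubled_output(self):
        blk = UPBlock(4, 2, RNG(1), bins=(1, 2))
        for p in blk.parameters():
            p.data = np.zeros_like(p.data)
        out = up_block(np.random.default_rng(0).random((1, 4, 6, 6)).astype(np.float32),
                       None, blk)
        assert out.shape == (1, 2, 12, 12)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_up_of_dn_restores_spatial_dims(self):
        dn = DNBlock(4, 8, RNG(2))
        up = UPBlock(8, 4, RNG(3), bins=(1, 2))
        x = np.random.default_rng(1).random((1, 4, 16, 16)).astype(np.float32)
        out = up_block(dn_block(x, dn), None, up)
        assert out.shape[-2:] == x.shape[-2:]

    def test_mismatched_skip_rejected(self):
        blk = UPBlock(8, 4, RNG(0), bins=(1, 2))
        with pytest.raises(ValueError):
            up_block(np.zeros((1, 4, 8, 8), dtype=np.float32),
                     np.zeros((1, 4, 6, 6), dtype=np.float32), blk)


class TestAuxFeatures:
    @pytest.mark.parametrize("input_size,sides", [(192, (96, 48, 24)), (64, (32, 16, 8))])
    def test_sides_follow_strides(self, input_size, sides):
        cfg = NetworkConfig(input_size=input_size, base_channels=4)
        model = build_cba_network(cfg, init_seed=0)
        c1 = np.zeros((1, 4, input_size, input_size), dtype=np.float32)
        outs = aux_features(c1, model)
        assert tuple(o.shape[-1] for o in outs) == sides

    def test_zero_input_gives_zero_maps(self):
        cfg = NetworkConfig(input_size=64, base_channels=4)
        model = build_cba_network(cfg, init_seed=0)
        # zero the aux conv biases so zero input propagates to zero output
        for blk in model.aux:
            blk.conv.bias.data[:] = 0
        outs = aux_features(np.zeros((1, 4, 64, 64), dtype=np.float32), model)
        for o in outs:
            np.testing.assert_allclose(o, 0.0, atol=1e-12)


class TestFullNetwork:
    def test_encoder_sides_and_output_shape_at_192(self):
        from cbaseg.experiments import encoder_side_sequence

        res = encoder_side_sequence(input_size=192, base_channels=4)
        assert res["encoder_sides"] == [192, 96, 48, 24, 12]
        assert res["aux_sides"] == [96, 48, 24]
        assert res["output_side"] == 192

    def test_forward_shape_and_range_at_64(self):
        cfg = NetworkConfig(input_size=64, base_channels=8)
        model = build_cba_network(cfg, init_seed=0)
        out = model.predict(np.random.default_rng(0).random((1, 1, 64, 64)))
        assert out.shape == (1, 1, 64, 64)
        assert ((out > 0) & (out < 1)).all()

    def test_inference_is_deterministic(self):
        cfg = NetworkConfig(input_size=32, base_channels=4)
        model = build_cba_network(cfg, init_seed=1)
        x = np.random.default_rng(2).random((2, 1, 32, 32)).astype(np.float32)
        a = model.predict(x)
        b = model.predict(x)
        assert (a == b).all()

    def test_every_parameter_reaches_a_nonzero_gradient(self):
        """No dead branch: each parameter gets gradient from some input."""
        cfg = NetworkConfig(input_size=32, base_channels=4)
        model = build_cba_network(cfg, init_seed=0)
        params = model.parameters()
        hit = [False] * len(params)
        rng = np.random.default_rng(0)
        for _ in range(3):
            model.zero_grad()
            x = Tensor(rng.random((2, 1, 32, 32)).astype(np.float32))
            out = model.forward(x)
            T.tsum(out * Tensor(rng.random(out.shape).astype(np.float32))).backward()
            for i, p in enumerate(params):
                if p.grad is not None and np.abs(p.grad).max() > 0:
                    hit[i] = True
        assert all(hit), f"{hit.count(False)} parameters never received gradient"

    def test_bad_input_shapes_rejected(self):
        model = build_cba_network(NetworkConfig(input_size=32, base_channels=4))
        with pytest.raises(ValueError):
            model.forward(np.zeros((1, 2, 32, 32), dtype=np.float32))
        with pytest.raises(ValueError):
            model.forward(np.zeros((1, 1, 30, 30), dtype=np.float32))


class TestCountParameters:
    def test_empty_module_has_zero(self):
        class Empty(Module):
            pass

        assert count_parameters(Empty()) == 0

    def test_single_conv_counts_weights_and_bias(self):
        conv = Conv2d(1, 8, 3, RNG(0))
        assert count_parameters(conv) == 3 * 3 * 1 * 8 + 8

    def test_default_config_lands_near_the_reference_budget(self):
        """The full-size model should hold roughly five to six million weights."""
        n = count_parameters(build_cba_network(NetworkConfig()))
        assert 3e6 < n < 9e6


class TestCheckpoint:
    def test_roundtrip_preserves_predictions(self, tmp_path):
        cfg = NetworkConfig(input_size=32, base_channels=4)
        model = build_cba_network(cfg, init_seed=5)
        path = tmp_path / "model.npz"
        save_checkpoint(model, path)
        clone = load_checkpoint(path)
        assert clone.config == cfg
        x = np.random.default_rng(0).random((1, 1, 32, 32)).astype(np.float32)
        np.testing.assert_array_equal(model.predict(x), clone.predict(x))
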