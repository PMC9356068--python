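"""Network assembly: shapes, variants, pyramid, determinism, gradient flow."""

import numpy as np
import pytest

from canalnet import (CanalNet, ConfigError, NetworkConfig,
                      build_multiscale_pyramid, total_loss)
from canalnet.model import build_convlstm_decoder_block, build_encoder_block
from canalnet.nn import BiConvLSTM, Tensor


MINI = dict(levels=3, encoder_channels=(2, 3, 4), input_shape=(8, 16, 16))


def mini_config(variant="canal_net", **overrides):
    return NetworkConfig.for_variant(variant, **{**MINI, **overrides})


class TestConfig:
    def test_channel_list_must_match_levels(self):
        with pytest.raises(ConfigError):
            NetworkConfig(levels=3, encoder_channels=(8, 16))

    def test_indivisible_shape_rejected_before_graph_construction(self):
        with pytest.raises(ConfigError):
            NetworkConfig(levels=4, encoder_channels=(1, 1, 1, 1),
                          input_shape=(8, 20, 32))

    def test_four_variants_expressible(self):
        flags = {v: NetworkConfig.for_variant(v, **MINI)
                 for v in ("canal_net", "convlstm_only", "mpl_only", "plain")}
        assert flags["canal_net"].convlstm_decoder
        assert flags["canal_net"].side_outputs
        assert flags["convlstm_only"].convlstm_decoder
        assert not flags["convlstm_only"].side_outputs
        assert not flags["mpl_only"].convlstm_decoder
        assert not flags["plain"].convlstm_decoder
        assert not flags["plain"].multiscale_inputs


class TestBlocks:
    def test_encoder_block_halves_all_axes(self, rng):
        cfg = mini_config()
        block = build_encoder_block(1, 5, cfg, rng=0)
        out = block(Tensor(rng.normal(size=(8, 1, 32, 32))))
        assert out.shape == (4, 5, 16, 16)

    def test_encoder_activations_nonnegative(self, rng):
        block = build_encoder_block(1, 4, mini_config(), rng=0)
        out = block(Tensor(rng.normal(size=(4, 1, 8, 8))))
        assert (out.data >= 0).all()

    def test_encoder_block_rejects_odd_axis(self, rng):
        block = build_encoder_block(1, 4, mini_config(), rng=0)
        with pytest.raises(ValueError):
            block(Tensor(rng.normal(size=(3, 1, 8, 8))))

    def test_decoder_block_doubles_axes(self, rng):
        cfg = mini_config()
        block = build_convlstm_decoder_block(6, 4, 4, cfg, rng=0)
        deep = Tensor(rng.normal(size=(4, 6, 16, 16)))
        skip = Tensor(rng.normal(size=(8, 4, 32, 32)))
        out = block(deep, skip)
        assert out.shape == (8, 4, 32, 32)
        assert np.isfinite(out.data).all()

    def test_decoder_block_shape_mismatch_rejected(self, rng):
        block = build_convlstm_decoder_block(6, 4, 4, mini_config(), rng=0)
        deep = Tensor(rng.normal(size=(4, 6, 16, 16)))
        bad_skip = Tensor(rng.normal(size=(8, 4, 16, 16)))
        with pytest.raises(ValueError):
            block(deep, bad_skip)


class TestPyramid:
    def test_constant_volume_stays_constant(self):
        pyr = build_multiscale_pyramid(np.full((8, 8, 8), 3.5), levels=3)
        assert len(pyr) == 3
        for level in pyr:
            np.testing.assert_allclose(level, 3.5)

    def test_single_impulse_becomes_one_eighth(self):
        v = np.zeros((4, 4, 4))
        v[0, 0, 0] = 1.0
        pyr = build_multiscale_pyramid(v, levels=2)
        assert pyr[1].shape == (2, 2, 2)
        assert pyr[1][0, 0, 0] == pytest.approx(1 / 8)
        assert pyr[1].sum() == pytest.approx(1 / 8)

    def test_intensity_integral_conserved(self, rng):
        v = rng.random((8, 8, 8))
        pyr = build_multiscale_pyramid(v, levels=3)
        integrals = [lvl.sum() * 8 ** k for k, lvl in enumerate(pyr)]
        np.testing.assert_allclose(integrals, integrals[0])

    def test_odd_shape_rejected(self):
        with pytest.raises(ValueError):
            build_multiscale_pyramid(np.zeros((6, 6, 6)), levels=3)


class TestAssembledNetwork:
    @pytest.mark.parametrize("variant", ["canal_net", "plain"])
    def test_output_shape_and_range(self, variant, rng):
        net = CanalNet(mini_config(variant))
        out = net(rng.normal(size=(8, 16, 16)))
        assert out.shape == (8, 16, 16)
        assert (out.data >= 0).all() and (out.data <= 1).all()

    def test_plain_variant_has_no_recurrent_blocks(self):
        plain = CanalNet(mini_config("plain"))
        assert not plain.has_recurrent_blocks
        assert plain.n_side_outputs == 0
        full = CanalNet(mini_config("canal_net"))
        assert full.has_recurrent_blocks

    def test_side_output_head_count_equals_levels(self):
        net = CanalNet(mini_config("canal_net"))
        assert net.n_side_outputs == net.config.levels

    def test_inference_forward_is_bit_deterministic(self, rng):
        net = CanalNet(mini_config())
        net.set_training(False)
        x = rng.normal(size=(8, 16, 16))
        np.testing.assert_array_equal(net(x).data, net(x).data)

    def test_same_seed_same_weights(self):
        a = CanalNet(mini_config(seed=5))
        b = CanalNet(mini_config(seed=5))
        for (_, pa), (_, pb) in zip(a.named_parameters(), b.named_parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_gradient_reaches_first_encoder_layer(self, rng):
        net = CanalNet(mini_config("canal_net"))
        x = rng.normal(size=(8, 16, 16))
        truth = (rng.random((8, 16, 16)) > 0.8).astype(float)
        loss, _ = total_loss(net(x), truth)
        loss.backward()
        first = net.encoder_blocks[0].conv1.weight
        assert first.grad is not None
        assert np.abs(first.grad).max() > 0

    def test_wrong_input_shape_rejected(self, rng):
        net = CanalNet(mini_config())
        with pytest.raises(ValueError):
            net(rng.normal(size=(8, 16, 32)))

    def test_checkpoint_roundtrip(self, tmp_path, rng):
        net = CanalNet(mini_config())
        x = rng.normal(size=(8, 16, 16))
        net(x)  # update batch-norm running stats
        net.set_training(False)
        ref = net(x).data
        path = tmp_path / "ckpt.npz"
        net.save(path)
        loaded = CanalNet.load(path)
        assert loaded.config == net.config
        np.testing.assert_array_equal(loaded(x).data, ref)

    def test_volumetric_kernel_switch(self, rng):
        net = CanalNet(mini_config("plain", volumetric_kernels=True))
        out = net(rng.normal(size=(8, 16, 16)))
        assert out.shape == (8, 16, 16)
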