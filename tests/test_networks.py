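import numpy as np
import pytest

from nucseg.networks import (ENET_STAGE2_TYPES, NetworkSpec, SegmentationModel,
                             build_enet, build_multitask, build_symmetric,
                             plan_channels, receptive_field)
from nucseg.nn.blocks import Block
from nucseg.nn.core import F32


def _rand(shape, seed=0):
    return np.random.default_rng(seed).random(shape, dtype=np.float32)


class TestNetworkSpec:
    @pytest.mark.parametrize("n", [2, 11, 0])
    def test_rejects_bad_module_counts(self, n):
        with pytest.raises(ValueError):
            NetworkSpec(family="symmetric", n_modules=n)

    def test_rejects_unknown_family(self):
        with pytest.raises(ValueError):
            NetworkSpec(family="unet")

    def test_roundtrip_dict(self):
        spec = NetworkSpec(family="symmetric", n_modules=5, in_channels=2,
                           feature_plan=(8, 16, 32))
        assert NetworkSpec.from_dict(spec.to_dict()) == spec

    def test_feature_plan_remainder_goes_to_middle(self):
        assert plan_channels(3, (32, 64, 128)) == [32, 64, 128]
        assert plan_channels(4, (32, 64, 128)) == [32, 64, 64, 128]
        assert plan_channels(5, (32, 64, 128)) == [32, 64, 64, 64, 128]
        assert plan_channels(6, (32, 64, 128)) == [32, 32, 64, 64, 128, 128]


class TestBlock:
    def test_parameter_count_oracle_1x1(self):
        # hand-derived: conv 1x1 (in*out + out) + BN (2*out) + projection
        # 1x1 (in*out + out) when in != out
        rng = np.random.default_rng(0)
        blk = Block(rng, 4, 6, kernel="1x1")
        expected = (4 * 6 + 6) + 2 * 6 + (4 * 6 + 6)
        assert sum(p.size for p in blk.params()) == expected

    def test_parameter_count_oracle_no_projection(self):
        rng = np.random.default_rng(0)
        blk = Block(rng, 5, 5, kernel="1x1")
        assert sum(p.size for p in blk.params()) == (5 * 5 + 5) + 2 * 5

    def test_factorized_5_is_two_convs(self):
        rng = np.random.default_rng(0)
        blk = Block(rng, 3, 3, kernel="factorized-5")
        kernels = [(c.kh, c.kw) for c in blk.convs]
        assert kernels == [(5, 1), (1, 5)]

    def test_unknown_kernel_rejected(self):
        with pytest.raises(ValueError):
            Block(np.random.default_rng(0), 3, 3, kernel="5x5")


class TestSymmetric:
    def test_three_plus_three_blocks(self):
        model = build_symmetric(3, 1, 2, seed=0)
        assert len(model.net.enc_blocks) == 3
        assert len(model.net.dec_blocks) == 3

    def test_forward_shape_and_normalization(self):
        model = build_symmetric(3, 1, 2, seed=0)
        probs = model.forward(_rand((2, 1, 64, 64)))
        assert probs.shape == (2, 2, 64, 64)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    @pytest.mark.parametrize("n", [3, 4, 5, 6])
    def test_shape_contract_three_sizes(self, n):
        model = build_symmetric(n, 1, 2, seed=0,
                                feature_plan=(4, 8, 8))
        base = 2 ** n
        for k in (1, 2, 3):
            x = _rand((1, 1, base, base * k))
            probs = model.forward(x)
            assert probs.shape == (1, 2, base, base * k)
            np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_indivisible_input_rejected(self):
        model = build_symmetric(3, 1, 2, seed=0)
        with pytest.raises(ValueError):
            model.forward(_rand((1, 1, 60, 60)))

    def test_channel_mismatch_rejected(self):
        model = build_symmetric(3, 1, 2, seed=0)
        with pytest.raises(ValueError):
            model.forward(_rand((1, 3, 64, 64)))

    def test_parameter_count_monotone_in_depth(self):
        counts = [build_symmetric(n, 1, 2, seed=0).parameter_count
                  for n in range(3, 11)]
        assert all(b > a for a, b in zip(counts, counts[1:]))

    def test_seed_reproducibility(self):
        a = build_symmetric(4, 1, 2, seed=5)
        b = build_symmetric(4, 1, 2, seed=5)
        c = build_symmetric(4, 1, 2, seed=6)
        assert a.checksum() == b.checksum()
        assert a.checksum() != c.checksum()

    def test_transposed_up_mode(self):
        model = build_symmetric(3, 1, 2, seed=0, up_mode="transposed")
        probs = model.forward(_rand((1, 1, 32, 32)))
        assert probs.shape == (1, 2, 32, 32)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)


class TestEnet:
    def test_decoder_shallower_than_encoder(self):
        model = build_enet(1, 2, seed=0)
        assert len(model.net.decoder_units) < len(model.net.encoder_units)

    def test_forward_128(self):
        model = build_enet(1, 2, seed=0)
        probs = model.forward(_rand((1, 1, 128, 128)))
        assert probs.shape == (1, 2, 128, 128)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_mixes_conv_types(self):
        assert "normal" in ENET_STAGE2_TYPES
        assert any(t.startswith("dilated:") for t in ENET_STAGE2_TYPES)
        assert "asymmetric" in ENET_STAGE2_TYPES

    def test_dilated_receptive_fields(self):
        # oracle: analytic receptive-field recursion; every dilated unit
        # must see strictly further than its undilated twin
        model = build_enet(1, 2, seed=0)
        for unit in model.net.stage2:
            if unit.dilation > 1:
                rf_dilated = receptive_field(unit.conv_descriptors)
                undilated = [dict(d, dilation=1)
                             for d in unit.conv_descriptors]
                assert all(d["dilation"] >= 1 for d in unit.conv_descriptors)
                assert rf_dilated > receptive_field(undilated)

    def test_receptive_field_recursion(self):
        # closed-form sanity: two stacked 3x3 convs see 5x5
        assert receptive_field([{"kh": 3, "kw": 3, "stride": 1, "dilation": 1}]
                               * 2) == 5
        assert receptive_field([{"kh": 3, "kw": 3, "stride": 1,
                                 "dilation": 2}]) == 5


class TestForward:
    def test_inference_deterministic(self):
        model = build_symmetric(3, 1, 2, seed=0)
        x = _rand((1, 1, 32, 32))
        assert np.array_equal(model.forward(x), model.forward(x))

    def test_constant_input_translation_invariant_interior(self):
        # a constant input yields an output invariant to translations by
        # the downsampling factor (max-unpooling makes the map periodic
        # rather than constant, so strict constancy would be too strong)
        model = build_symmetric(3, 1, 2, seed=0)
        f = model.downsample_factor
        probs = model.forward(np.zeros((1, 1, 64, 64), dtype=F32))
        interior = probs[0, :, 16:48, 16:48]
        for i in range(f):
            for j in range(f):
                phase = interior[:, i::f, j::f]
                ref = np.broadcast_to(phase[:, :1, :1], phase.shape)
                np.testing.assert_allclose(phase, ref, atol=1e-5)

    def test_untrained_output_in_unit_interval(self):
        for model in (build_symmetric(3, 1, 2, seed=1), build_enet(1, 2, seed=1)):
            probs = model.forward(_rand((1, 1, 32, 32) if
                                        model.spec.family == "symmetric"
                                        else (1, 1, 64, 64)))
            assert probs.min() >= 0.0 and probs.max() <= 1.0


class TestMultitask:
    def test_two_normalized_heads(self):
        model = build_multitask(NetworkSpec(n_modules=3,
                                            feature_plan=(4, 8, 8)), seed=0)
        pr, pb = model.forward(_rand((1, 1, 32, 32)))
        for p in (pr, pb):
            assert p.shape == (1, 2, 32, 32)
            np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_trunk_count_matches_single_task(self):
        spec = NetworkSpec(n_modules=3, feature_plan=(4, 8, 8))
        multi = build_multitask(spec, seed=0)
        single = build_symmetric(spec=spec, seed=0)
        assert multi.net.trunk_parameter_count == single.net.trunk_parameter_count
        head = sum(p.size for p in single.net.classifier.params())
        assert single.parameter_count == single.net.trunk_parameter_count + head
        assert multi.parameter_count == multi.net.trunk_parameter_count + 2 * head


class TestCheckpoint:
    def test_save_load_roundtrip(self, tmp_path):
        model = build_symmetric(3, 1, 2, seed=3, feature_plan=(4, 8, 8))
        x = _rand((1, 1, 32, 32))
        before = model.forward(x)
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = SegmentationModel.load(path)
        assert loaded.spec == model.spec
        assert np.array_equal(loaded.forward(x), before)

    def test_checkpoint_is_self_describing(self, tmp_path):
        spec = NetworkSpec(family="enet", in_channels=2,
                           dropout_rate=0.05)
        model = build_enet(spec=spec, seed=1)
        path = tmp_path / "enet.npz"
        model.save(path)
        assert SegmentationModel.load(path).spec == spec
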