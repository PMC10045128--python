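"""Network structure, pooling/unpooling primitives, inference contracts, and a
finite-difference check of the hand-written backpropagation."""

import numpy as np
import pytest

from ratunet import nn
from ratunet.io_preprocess import MRVolume
from ratunet.network import (PoolRecord, RUNet, build_runet, keep_largest_component,
                             max_pool_with_indices, max_unpool, predict_volume)


class TestStructure:
    @pytest.mark.parametrize("n", [64, 128, 256])
    @pytest.mark.parametrize("width", [4, 64])
    def test_layer_inventory(self, n, width):
        """The printed architecture: 33 convs, 5 pools, 5 unpools; 14 + 19."""
        spec, _ = build_runet(n, width)
        assert spec.conv_count == 33
        assert spec.pool_count == 5
        assert spec.unpool_count == 5
        assert spec.encoder_conv_count == 14
        assert spec.decoder_conv_count == 19

    def test_invalid_input_size(self):
        with pytest.raises(ValueError):
            build_runet(100, 16)
        with pytest.raises(ValueError):
            build_runet(0, 16)
        with pytest.raises(ValueError):
            build_runet(64, 0)

    def test_channel_arithmetic(self):
        """All feature maps carry C channels; only concatenation inputs see 2C."""
        c = 6
        model = RUNet(64, c)
        assert model.conv_in.c_in == 1 and model.conv_in.c_out == c
        for blocks in model.enc_blocks:
            for blk in blocks:
                assert blk.conv.c_in == c and blk.conv.c_out == c
        for lvl in model.dec_levels:
            assert lvl["reduce"].conv.c_in == 2 * c
            assert lvl["reduce"].conv.c_out == c
            for blk in lvl["blocks"]:
                assert blk.conv.c_in == c and blk.conv.c_out == c
        assert model.final_reduce.conv.c_in == 2 * c
        assert model.final_block.conv.c_in == c
        assert model.conv_out.c_in == c and model.conv_out.c_out == 1
        assert model.conv_out.ksize == 1

    def test_forward_is_probability_map(self):
        _, model = build_runet(64, 4, seed=0)
        x = np.random.default_rng(0).normal(size=(3, 1, 64, 64)).astype(np.float32)
        p = model.forward(x)
        assert p.shape == (3, 1, 64, 64)
        assert p.min() >= 0.0 and p.max() <= 1.0

    def test_checkpoint_round_trip(self, tmp_path):
        _, model = build_runet(64, 4, seed=3)
        x = np.random.default_rng(1).normal(size=(2, 1, 64, 64)).astype(np.float32)
        p1 = model.forward(x)
        model.save(tmp_path / "ckpt.npz")
        clone = RUNet.load(tmp_path / "ckpt.npz")
        assert np.array_equal(clone.forward(x), p1)


class TestPooling:
    def test_basic_max_and_index(self):
        x = np.array([[[1.0, 2.0], [3.0, 4.0]]])
        pooled, rec = max_pool_with_indices(x)
        assert pooled.tolist() == [[[4.0]]]
        assert rec.indices.tolist() == [[[3]]]  # bottom-right of the window

    def test_tie_breaks_to_first_row_major(self):
        x = np.full((1, 4, 4), 7.0)
        pooled, rec = max_pool_with_indices(x)
        assert np.all(pooled == 7.0)
        assert np.all(rec.indices == 0)

    def test_halves_spatial_dims(self, rng):
        x = rng.normal(size=(3, 16, 24))
        pooled, _ = max_pool_with_indices(x)
        assert pooled.shape == (3, 8, 12)

    def test_odd_dims_rejected(self):
        with pytest.raises(ValueError):
            max_pool_with_indices(np.zeros((1, 5, 4)))

    def test_unpool_scatter(self):
        x = np.array([[[1.0, 2.0], [3.0, 4.0]]])
        pooled, rec = max_pool_with_indices(x)
        up = max_unpool(pooled, rec)
        assert up.tolist() == [[[0.0, 0.0], [0.0, 4.0]]]

    def test_unpool_round_trip_all_levels(self, rng):
        """pool(unpool(pool(x))) == pool(x) at every scale of the network.

        The identity holds on non-negative feature maps; with a negative
        window maximum the zero fill of unpooling would win the re-pool, so
        the inputs here are drawn uniform on [0, 1).
        """
        for size in (64, 32, 16, 8, 4):
            for _ in range(20):
                x = rng.random((2, size, size))
                pooled, rec = max_pool_with_indices(x)
                again, _ = max_pool_with_indices(max_unpool(pooled, rec))
                assert np.array_equal(again, pooled)

    def test_unpool_sparsity(self, rng):
        x = rng.normal(size=(4, 8, 8)) + 10.0  # strictly positive values
        pooled, rec = max_pool_with_indices(x)
        up = max_unpool(pooled, rec)
        assert np.count_nonzero(up) <= pooled.size

    def test_incompatible_record_rejected(self):
        x = np.zeros((1, 4, 4))
        pooled, rec = max_pool_with_indices(x)
        with pytest.raises(ValueError):
            max_unpool(np.zeros((1, 3, 3)), rec)


@pytest.fixture(scope="module")
def model():
    return RUNet(64, 4, seed=2)


class TestPredictVolume:

    def test_shape_and_range(self, model, rng):
        vol = MRVolume(rng.normal(size=(5, 64, 64)), (1.0, 0.4, 0.4))
        res = predict_volume(model, vol)
        assert res.probability.shape == (5, 64, 64)
        assert res.probability.min() >= 0.0 and res.probability.max() <= 1.0
        assert res.mask.shape == (5, 64, 64)

    def test_threshold_convention_and_consistency(self, model, rng):
        vol = MRVolume(rng.normal(size=(2, 64, 64)), (1.0, 0.4, 0.4))
        res = predict_volume(model, vol, threshold=0.5)
        assert np.array_equal(res.mask.voxels, (res.probability >= 0.5).astype(np.uint8))

    def test_stateless_across_slices(self, model, rng):
        one = rng.normal(size=(64, 64))
        vol = MRVolume(np.stack([one] * 9), (1.0, 0.4, 0.4))
        res = predict_volume(model, vol, batch_size=4)
        for z in range(1, 9):
            assert np.array_equal(res.probability[z], res.probability[0])

    def test_size_mismatch(self, model, rng):
        vol = MRVolume(rng.normal(size=(2, 128, 128)), (1.0, 0.2, 0.2))
        with pytest.raises(ValueError):
            predict_volume(model, vol)

    def test_keep_largest_component(self):
        m = np.zeros((1, 8, 8), dtype=np.uint8)
        m[0, 1:4, 1:4] = 1   # 9 voxels
        m[0, 6, 6] = 1       # stray voxel
        out = keep_largest_component(m)
        assert out.sum() == 9 and out[0, 6, 6] == 0


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Spot-check analytic gradients of the full graph, double precision."""
        model = RUNet(32, 2, seed=1, dtype=np.float64)
        for _, layer in model._param_layers():
            if isinstance(layer, nn.BatchNorm2d):
                layer.momentum = 0.0  # freeze running stats for repeat forwards
        rng = np.random.default_rng(2)
        x = rng.normal(size=(2, 1, 32, 32))
        g = (rng.random((2, 1, 32, 32)) > 0.7).astype(np.float64)

        def loss():
            p = model.forward(x, training=True)
            val, _ = nn.soft_dice_loss(p, g)
            return val

        p = model.forward(x, training=True)
        _, dgrad = nn.soft_dice_loss(p, g)
        model.backward(dgrad)
        analytic = {k: gr.copy() for k, _, gr in model.named_parameters()}

        eps = 1e-6
        check = np.random.default_rng(3)
        keys = list(analytic)
        for key in check.choice(len(keys), size=12, replace=False):
            name = keys[key]
            param = dict((k, p_) for k, p_, _ in model.named_parameters())[name]
            flat = param.ravel()
            i = int(check.integers(flat.size))
            old = flat[i]
            flat[i] = old + eps
            lp = loss()
            flat[i] = old - eps
            lm = loss()
            flat[i] = old
            numeric = (lp - lm) / (2 * eps)
            ana = analytic[name].ravel()[i]
            assert numeric == pytest.approx(ana, rel=1e-4, abs=1e-9), name
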