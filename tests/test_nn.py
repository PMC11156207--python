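"""U-Net layers (finite-difference checks), training recipe and inference."""

import numpy as np
import pytest

import choroidpipe.nn.layers as nn_layers
from choroidpipe.core import BScan
from choroidpipe.evaluation import dice_score
from choroidpipe.nn import (
    AdamW,
    AugmentationConfig,
    TrainConfig,
    UNet,
    UNetConfig,
    augment_sample,
    bce_with_logits,
    load_checkpoint,
    peripapillary_crop,
    predict,
    save_checkpoint,
    train_model,
)

from conftest import make_phantom, phantom_config

TINY = UNetConfig(depth=3, encoder_channels=(4, 6, 8), out_channels=2)


def directional_derivative_check(model, x, t, eps=1e-6):
    """Analytic grad . v vs central finite differences along random v."""
    z = model.forward(x, training=True).astype(np.float64)
    dz = (1.0 / (1.0 + np.exp(-z)) - t) / t.size
    model.zero_grad()
    model.backward(dz)
    vs, dot = {}, 0.0
    for i, (layer, name) in enumerate(model.parameters()):
        v = np.random.default_rng(100 + i).standard_normal(layer.params[name].shape)
        vs[(id(layer), name)] = v
        dot += float(np.sum(layer.grads[name].astype(np.float64) * v))

    def loss():
        zz = model.forward(x, training=True).astype(np.float64)
        return float(np.mean(np.logaddexp(0, zz) - t * zz))

    for layer, name in model.parameters():
        layer.params[name] = layer.params[name] + eps * vs[(id(layer), name)]
    lp = loss()
    for layer, name in model.parameters():
        layer.params[name] = layer.params[name] - 2 * eps * vs[(id(layer), name)]
    lm = loss()
    return dot, (lp - lm) / (2 * eps)


class TestBackpropagation:
    def test_full_network_gradient_exact_in_float64(self, monkeypatch):
        monkeypatch.setattr(nn_layers, "_F", np.float64)
        model = UNet(TINY, seed=1)
        rng = np.random.default_rng(0)
        x = rng.random((2, 1, 8, 8))
        t = (rng.random((2, 2, 8, 8)) > 0.5).astype(np.float64)
        analytic, numeric = directional_derivative_check(model, x, t)
        assert numeric == pytest.approx(analytic, rel=1e-5)

    @pytest.mark.parametrize("layer_name", ["conv3", "conv1", "bn", "pool", "up"])
    def test_single_layer_input_gradients(self, layer_name, monkeypatch):
        monkeypatch.setattr(nn_layers, "_F", np.float64)
        rng = np.random.default_rng(1)
        layer = {
            "conv3": lambda: nn_layers.Conv2d(3, 4, 3, rng),
            "conv1": lambda: nn_layers.Conv2d(3, 4, 1, rng),
            "bn": lambda: nn_layers.BatchNorm2d(3),
            "pool": lambda: nn_layers.MaxPool2d(),
            "up": lambda: nn_layers.BilinearUp2d(),
        }[layer_name]()
        x = rng.standard_normal((2, 3, 8, 8))
        dy = rng.standard_normal(layer.forward(x, True).shape)
        dx = layer.backward(dy)
        eps = 1e-6
        flat = x.ravel()
        for idx in rng.choice(flat.size, 6, replace=False):
            old = flat[idx]
            flat[idx] = old + eps
            lp = float(np.sum(layer.forward(x, True) * dy))
            flat[idx] = old - eps
            lm = float(np.sum(layer.forward(x, True) * dy))
            flat[idx] = old
            assert (lp - lm) / (2 * eps) == pytest.approx(
                float(dx.ravel()[idx]), rel=1e-5, abs=1e-9
            )


class TestArchitecture:
    def test_depth_seven_default(self):
        model = UNet()
        assert len(model.enc_blocks) == 7
        assert model.config.encoder_channels == (8, 32, 64, 64, 64, 64, 64)

    def test_output_shape_contract(self):
        model = UNet(UNetConfig(), seed=0)
        out = model.forward(np.zeros((1, 1, 128, 128), np.float32), training=False)
        assert out.shape == (1, 3, 128, 128)

    def test_fully_convolutional_on_wide_input(self):
        model = UNet(UNetConfig(), seed=0)
        n_params = model.n_parameters()
        out = model.forward(np.zeros((1, 1, 128, 192), np.float32), training=False)
        assert out.shape == (1, 3, 128, 192)
        assert model.n_parameters() == n_params

    def test_indivisible_input_rejected(self):
        model = UNet(UNetConfig(), seed=0)
        with pytest.raises(ValueError):
            model.forward(np.zeros((1, 1, 100, 100), np.float32))


class TestLossAndOptimizer:
    def test_bce_matches_direct_formula(self):
        rng = np.random.default_rng(2)
        z = rng.normal(size=(2, 3, 4, 4))
        t = rng.random((2, 3, 4, 4))
        loss, dz = bce_with_logits(z, t)
        p = 1 / (1 + np.exp(-z))
        direct = -np.mean(t * np.log(p) + (1 - t) * np.log(1 - p))
        assert loss == pytest.approx(direct, rel=1e-9)
        assert np.allclose(dz, (p - t) / z.size)

    def test_adamw_zero_lr_keeps_weights(self):
        model = UNet(TINY, seed=3)
        before = model.state_dict()
        opt = AdamW(model, lr=0.0, weight_decay=1e-8)
        for layer, name in model.parameters():
            layer.grads[name][...] = 1.0
        opt.step()
        after = model.state_dict()
        for k in before:
            assert np.array_equal(before[k], after[k])


class TestAugmentation:
    def _sample(self):
        rng = np.random.default_rng(5)
        img = rng.random((64, 64))
        tgt = np.stack([
            (rng.random((64, 64)) > 0.5).astype(float),
            (rng.random((64, 64)) > 0.8).astype(float),
            rng.random((64, 64)),
        ])
        return img, tgt

    def test_all_probabilities_zero_is_identity(self):
        img, tgt = self._sample()
        cfg = AugmentationConfig(hflip_p=0, photometric_p=0, affine_p=0, scale_p=0)
        out_img, out_tgt, col = augment_sample(img, tgt, 30, cfg, seed=0)
        assert np.array_equal(out_img, img)
        assert np.array_equal(out_tgt, tgt)
        assert col == 30

    def test_forced_flip_mirrors_columns_and_fovea(self):
        img, tgt = self._sample()
        cfg = AugmentationConfig(hflip_p=1.0, photometric_p=0, affine_p=0, scale_p=0)
        out_img, out_tgt, col = augment_sample(img, tgt, 20, cfg, seed=1)
        assert np.array_equal(out_img, img[:, ::-1])
        assert np.array_equal(out_tgt[0], tgt[0][:, ::-1])
        assert col == 64 - 1 - 20

    def test_same_seed_deterministic(self):
        img, tgt = self._sample()
        a = augment_sample(img, tgt, 32, AugmentationConfig(), seed=9)
        b = augment_sample(img, tgt, 32, AugmentationConfig(), seed=9)
        assert np.array_equal(a[0], b[0]) and a[2] == b[2]

    def test_geometric_transform_keeps_targets_aligned(self):
        img, tgt = self._sample()
        cfg = AugmentationConfig(hflip_p=0, photometric_p=0, affine_p=1.0, scale_p=0)
        out_img, out_tgt, _ = augment_sample(img, tgt, 32, cfg, seed=2)
        assert out_tgt.shape == tgt.shape
        assert set(np.unique(out_tgt[0])) <= {0.0, 1.0}  # binary stays binary

    def test_peripapillary_crop_offsets(self):
        img = np.tile(np.arange(1536, dtype=float), (8, 1))
        tgt = np.zeros((3, 8, 1536))
        offsets = set()
        for seed in range(40):
            c, ct = peripapillary_crop(img, tgt, seed=seed)
            assert c.shape == (8, 768) and ct.shape == (3, 8, 768)
            offset = int(c[0, 0])
            assert offset % 192 == 0 and 0 <= offset <= 1536 - 768
            offsets.add(offset)
        assert len(offsets) > 1  # the offset is actually randomised


class TestTraining:
    def _tiny_dataset(self, n=2):
        cfg = phantom_config(height=64, width=64, choroid_mean_thickness=300,
                             vessel_count=12, vessel_radius_range=(20, 60),
                             retina_thickness=150, fovea_pit_depth=50,
                             band_top_fraction=0.4, speckle=0.0)
        from choroidpipe.synthetic import generate_dataset

        return generate_dataset(cfg, n, seed=7)

    def test_zero_lr_leaves_weights_and_loss_constant(self):
        ds = self._tiny_dataset()
        model = UNet(UNetConfig(depth=3, encoder_channels=(4, 6, 8)), seed=0)
        before = model.state_dict()
        model, hist = train_model(model, ds, TrainConfig(epochs=3, lr=0.0, seed=0))
        after = model.state_dict()
        for k in before:
            if "running" in k:
                continue  # batch-norm statistics still update
            assert np.array_equal(before[k], after[k])
        assert np.allclose(hist["loss"], hist["loss"][0], atol=1e-6)

    def test_same_seed_identical_history(self):
        ds = self._tiny_dataset()
        cfg3 = UNetConfig(depth=3, encoder_channels=(4, 6, 8))
        _, h1 = train_model(UNet(cfg3, seed=1), ds, TrainConfig(epochs=3, seed=5))
        _, h2 = train_model(UNet(cfg3, seed=1), ds, TrainConfig(epochs=3, seed=5))
        assert h1["loss"] == h2["loss"]

    def test_loss_decreases_and_gradients_clipped(self):
        ds = self._tiny_dataset()
        model = UNet(UNetConfig(depth=4, encoder_channels=(8, 16, 32, 32)), seed=2)
        model, hist = train_model(
            model, ds, TrainConfig(epochs=25, grad_norm_clip=3.0, seed=0)
        )
        assert hist["loss"][-1] < 0.75 * hist["loss"][0]
        assert all(b < a for a, b in zip(hist["loss"], hist["loss"][1:]))
        assert max(hist["grad_norm"]) <= 3.0 + 1e-6

    def test_training_improves_over_untrained(self):
        ds = self._tiny_dataset(n=3)
        held_out = self._tiny_dataset(n=4)[3]
        cfg4 = UNetConfig(depth=4, encoder_channels=(8, 16, 32, 32))
        gains = []
        for seed in range(3):
            model = UNet(cfg4, seed=seed)
            base = dice_score(predict(model, held_out.image).region_prob,
                              held_out.region_mask)
            model, _ = train_model(model, ds, TrainConfig(epochs=20, seed=seed))
            trained = dice_score(predict(model, held_out.image).region_prob,
                                 held_out.region_mask)
            gains.append(trained - base)
        assert np.mean(gains) > 0

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train_model(UNet(TINY, seed=0), [], TrainConfig(epochs=1))


class TestPredict:
    def test_probabilities_in_unit_interval(self):
        model = UNet(UNetConfig(depth=3, encoder_channels=(4, 6, 8), out_channels=3),
                     seed=0)
        seg = predict(model, np.random.default_rng(0).random((64, 64)))
        for ch in (seg.region_prob, seg.vessel_prob, seg.fovea_prob):
            assert ch.min() >= 0 and ch.max() <= 1

    def test_non_divisible_input_padded_and_cropped(self):
        model = UNet(UNetConfig(depth=3, encoder_channels=(4, 6, 8)), seed=0)
        seg = predict(model, np.random.default_rng(1).random((50, 70)))
        assert seg.region_prob.shape == (50, 70)

    def test_overfit_single_phantom(self):
        s = make_phantom(seed=9, speckle=0.0, height=64, width=64,
                         choroid_mean_thickness=300, vessel_count=12,
                         vessel_radius_range=(20, 60), retina_thickness=150,
                         fovea_pit_depth=50, band_top_fraction=0.4)
        model = UNet(UNetConfig(depth=4, encoder_channels=(8, 16, 32, 32)), seed=0)
        model, _ = train_model(model, [s], TrainConfig(epochs=60, batch_size=1,
                                                       seed=0))
        seg = predict(model, BScan(s.image, s.scale_x, s.scale_y))
        assert dice_score(seg.region_prob, s.region_mask) >= 0.95

    def test_checkpoint_round_trip(self, tmp_path):
        model = UNet(UNetConfig(depth=3, encoder_channels=(4, 6, 8)), seed=4)
        x = np.random.default_rng(2).random((64, 64))
        before = predict(model, x)
        path = tmp_path / "model.npz"
        save_checkpoint(model, path)
        restored = load_checkpoint(path)
        after = predict(restored, x)
        assert np.array_equal(before.region_prob, after.region_prob)
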