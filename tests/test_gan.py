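import math

import numpy as np
import pytest

from hsistain import _nn
from hsistain.dataset import TrainingPair
from hsistain.gan import (CGANTranslator, LossWeights, ModelBundle, TrainConfig,
                          _ssim_and_grad, discriminator_loss, generator_loss,
                          predict_patches, train_model)
from hsistain.metrics import SSIMParams, ssim
from hsistain.phantom import phantom_patch_dataset


def micro_pairs(n=10, size=32, seed=0):
    return phantom_patch_dataset(n, patch_size=size, seed=seed, patches_per_strip=5)


class TestGeneratorLoss:
    def test_perfect_generator_fixed_point(self, rng):
        y = rng.integers(0, 256, size=(16, 16), dtype=np.uint8)
        terms = generator_loss(y, y, 1.0)
        assert terms["total"] == 0.0
        assert terms["adversarial"] == 0.0
        assert terms["l1"] == 0.0 and terms["ssim"] == 0.0

    def test_undecided_discriminator_contributes_log_two(self, rng):
        y = rng.integers(0, 256, size=(16, 16), dtype=np.uint8)
        terms = generator_loss(y, y, 0.5, LossWeights(100, 100))
        assert terms["total"] == pytest.approx(-math.log(0.5), abs=1e-12)
        assert terms["total"] == pytest.approx(0.6931, abs=1e-4)

    def test_constant_offset_images_cross_module_oracle(self):
        g = np.full((32, 32), 100, dtype=np.uint8)
        y = np.full((32, 32), 110, dtype=np.uint8)
        s = ssim(g, y, SSIMParams())
        expected = (-math.log(0.5) + 100 * (10 / 255)
                    - 100 * math.log((1 + s) / 2))
        terms = generator_loss(g, y, 0.5, LossWeights(100, 100))
        assert terms["total"] == pytest.approx(expected, abs=1e-10)

    def test_zero_weights_reduce_to_adversarial_term(self, rng):
        g = rng.integers(0, 256, size=(8, 8), dtype=np.uint8)
        y = rng.integers(0, 256, size=(8, 8), dtype=np.uint8)
        terms = generator_loss(g, y, 0.3, LossWeights(0, 0))
        assert terms["total"] == pytest.approx(-math.log(0.3), abs=1e-12)

    def test_invalid_scores_and_geometry_rejected(self):
        y = np.zeros((4, 4), dtype=np.uint8)
        with pytest.raises(ValueError, match="domain"):
            generator_loss(y, y, 0.0)
        with pytest.raises(ValueError, match="geometry"):
            generator_loss(y, np.zeros((4, 5), np.uint8), 0.5)
        with pytest.raises(ValueError, match="non-negative"):
            LossWeights(-1, 100)


class TestDiscriminatorLoss:
    def test_perfect_discriminator_limit(self):
        for eps in (1e-3, 1e-5, 1e-7):
            assert discriminator_loss(1 - eps, eps) < 3 * eps
        assert discriminator_loss(1.0, 0.0) == 0.0

    def test_undecided_value(self):
        assert discriminator_loss(0.5, 0.5) == pytest.approx(2 * math.log(2), abs=1e-12)

    def test_confident_correct_value(self):
        assert discriminator_loss(0.9, 0.1) == pytest.approx(0.21072103, abs=1e-7)

    def test_boundary_scores_rejected_where_log_diverges(self):
        with pytest.raises(ValueError):
            discriminator_loss(0.0, 0.5)
        with pytest.raises(ValueError):
            discriminator_loss(0.5, 1.0)


class TestGradients:
    def test_ssim_gradient_matches_finite_differences(self, rng):
        x = rng.random((2, 8, 8))
        y = rng.random((2, 8, 8))
        s, grad = _ssim_and_grad(x, y, 1e-4, 9e-4)
        eps = 1e-6
        for idx in [(0, 2, 3), (1, 7, 0), (0, 0, 0)]:
            xp = x.copy()
            xp[idx] += eps
            sp, _ = _ssim_and_grad(xp, y, 1e-4, 9e-4)
            assert (sp - s) / eps == pytest.approx(grad[idx], abs=1e-5)

    @pytest.mark.parametrize("layer_fn, shape", [
        (lambda rng: _nn.Conv2d(2, 3, 3, 1, rng), (2, 6, 6)),
        (lambda rng: _nn.Conv2d(2, 3, 3, 2, rng), (2, 6, 6)),
        (lambda rng: _nn.Conv2d(2, 2, 4, 2, rng), (2, 8, 8)),
        (lambda rng: _nn.InstanceNorm(2), (2, 5, 5)),
        (lambda rng: _nn.LeakyReLU(), (2, 4, 4)),
        (lambda rng: _nn.Tanh(), (2, 4, 4)),
        (lambda rng: _nn.Upsample2(), (2, 4, 4)),
    ])
    def test_layer_input_gradients_match_finite_differences(self, layer_fn, shape):
        rng = np.random.default_rng(3)
        layer = layer_fn(rng)
        x = rng.normal(0, 1, size=shape).astype(np.float64)
        out = layer.forward(x)
        w = rng.normal(0, 1, size=out.shape)  # random scalar projection
        loss = float((out * w).sum())
        gx = layer.backward(w.astype(np.float32))
        eps = 1e-4
        for idx in [(0, 1, 2), (1, 3, 3), (0, 0, 0)]:
            xp = x.copy()
            xp[idx] += eps
            lp = float((layer.forward(xp) * w).sum())
            fd = (lp - loss) / eps
            assert fd == pytest.approx(float(gx[idx]), rel=2e-2, abs=2e-3)

    def test_conv_weight_gradients_match_finite_differences(self):
        rng = np.random.default_rng(4)
        conv = _nn.Conv2d(2, 2, 3, 1, rng)
        x = rng.normal(0, 1, size=(2, 5, 5))
        w = rng.normal(0, 1, size=(2, 5, 5))
        conv.weight.grad[...] = 0
        loss = float((conv.forward(x) * w).sum())
        conv.backward(w.astype(np.float32))
        eps = 1e-3
        for idx in [(0, 0), (1, 5), (1, 17)]:
            orig = conv.weight.value[idx]
            conv.weight.value[idx] = orig + eps
            lp = float((conv.forward(x) * w).sum())
            conv.weight.value[idx] = orig
            assert (lp - loss) / eps == pytest.approx(
                float(conv.weight.grad[idx]), rel=2e-2, abs=2e-3)


class TestTraining:
    def test_zero_epoch_run_returns_initialized_bundle(self):
        pairs = micro_pairs(4)
        cfg = TrainConfig.tiny(seed=5)
        cfg.epochs = 0
        cfg.decay_epochs = 0
        bundle = train_model(pairs, "dab_ptau", cfg)
        assert bundle.train_log == []
        fresh = train_model(pairs, "dab_ptau", cfg)
        for a, b in zip(bundle.generator.params(), fresh.generator.params()):
            assert np.array_equal(a.value, b.value)

    def test_short_training_reduces_l1_term(self):
        pairs = micro_pairs(10)
        est = CGANTranslator("dab_ptau", TrainConfig.tiny(epochs=3, seed=1)).fit(pairs)
        assert est.train_log_[-1]["g_l1"] < est.train_log_[0]["g_l1"]
        assert len(est.train_log_) == 3

    def test_training_is_seed_reproducible(self):
        pairs = micro_pairs(4)
        a = CGANTranslator("dab_ptau", TrainConfig.tiny(epochs=1, seed=9)).fit(pairs)
        b = CGANTranslator("dab_ptau", TrainConfig.tiny(epochs=1, seed=9)).fit(pairs)
        assert a.train_log_ == b.train_log_
        for pa, pb in zip(a.generator_.params(), b.generator_.params()):
            assert np.array_equal(pa.value, pb.value)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            CGANTranslator("dab_ptau", TrainConfig.tiny(epochs=1)).fit([])

    def test_stain_kind_must_match_target(self):
        pairs = micro_pairs(4)
        with pytest.raises(ValueError, match="stain kind"):
            CGANTranslator("fluo_ptau", TrainConfig.tiny(epochs=1)).fit(pairs)

    def test_learning_rate_schedule(self):
        cfg = TrainConfig(epochs=140, decay_epochs=50)
        assert cfg.lr_at_epoch("dab_ptau", 0) == 1e-5
        assert cfg.lr_at_epoch("dab_ptau", 89) == 1e-5
        assert cfg.lr_at_epoch("dab_ptau", 90) == 1e-5
        assert cfg.lr_at_epoch("dab_ptau", 139) == pytest.approx(1e-5 / 50)
        assert cfg.lr_at_epoch("fluo_abeta", 0) == 5e-6

    def test_config_invariants(self):
        with pytest.raises(ValueError, match="batch_size"):
            TrainConfig(batch_size=2)
        with pytest.raises(ValueError, match="decay_epochs"):
            TrainConfig(epochs=10, decay_epochs=20)


@pytest.fixture(scope="module")
def fitted():
    pairs = micro_pairs(6)
    est = CGANTranslator("dab_ptau", TrainConfig.tiny(epochs=1, seed=2)).fit(pairs)
    return est, pairs


class TestInference:
    def test_inference_is_deterministic(self, fitted):
        est, pairs = fitted
        a = est.predict([pairs[0].x])[0]
        b = est.predict([pairs[0].x])[0]
        assert np.array_equal(a, b)
        assert a.dtype == np.uint8 and a.shape == pairs[0].y.shape

    def test_geometry_mismatch_rejected(self, fitted):
        est, _ = fitted
        with pytest.raises(ValueError, match="geometry"):
            est.predict([np.zeros((16, 16, 3), dtype=np.uint8)])

    def test_bundle_roundtrip_preserves_predictions(self, fitted, tmp_path):
        est, pairs = fitted
        bundle = est.to_bundle(dataset_hash="abc")
        bundle.save(tmp_path / "model.npz")
        back = ModelBundle.load(tmp_path / "model.npz")
        a = predict_patches(bundle, [pairs[0].x])[0]
        b = predict_patches(back, [pairs[0].x])[0]
        assert np.array_equal(a, b)
        assert back.manifest["dataset_hash"] == "abc"
        assert back.target == "dab_ptau"
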