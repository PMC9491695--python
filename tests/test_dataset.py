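import numpy as np
import pytest

from hsistain.dataset import (AugmentationPolicy, DiscardRules, TrainingPair,
                              augment, discard_damaged, make_patches,
                              mask_lumen_negative)
from hsistain.phantom import PhantomSpec, Vessel, render_phantom


def checker(rows, cols, channels=3, seed=0):
    rng = np.random.default_rng(seed)
    return rng.integers(0, 256, size=(rows, cols, channels), dtype=np.uint8)


class TestMakePatches:
    def test_test_patch_origins_follow_half_overlap_stride(self):
        x = checker(256, 512)
        pairs = make_patches(x, x.copy(), patch_size=256, holdout=(0, 0, 256, 512),
                             overlap_test=0.5)
        test = [p for p in pairs if p.role == "test"]
        origins = sorted(p.provenance["origin"] for p in test)
        assert origins == [(0, 0), (0, 128), (0, 256)]  # 128-px stride grid

    def test_train_count_matches_exhaustive_enumeration(self):
        x = checker(256, 768)
        pairs = make_patches(x, x.copy(), patch_size=256, holdout=None)
        # brute-force origin oracle: tail-aligned non-overlapping grid
        expected = {(r, c) for r in {0} for c in {0, 256, 512}}
        got = {p.provenance["origin"] for p in pairs}
        assert got == expected

    def test_train_val_never_intersect_holdout(self):
        x = checker(320, 640)
        holdout = (64, 192, 320, 512)
        pairs = make_patches(x, x.copy(), patch_size=64, holdout=holdout,
                             overlap_test=1 / 3, val_fraction=0.2, seed=5)
        r0, c0, r1, c1 = holdout
        for p in pairs:
            if p.role == "test":
                continue
            rr, cc = p.provenance["origin"]
            disjoint = (rr + 64 <= r0 or rr >= r1 or cc + 64 <= c0 or cc >= c1)
            assert disjoint, (p.role, p.provenance)

    def test_validation_split_is_seeded(self):
        x = checker(320, 640)
        roles1 = [p.role for p in make_patches(x, x.copy(), 64, None, 0.5, 0.25, seed=9)]
        roles2 = [p.role for p in make_patches(x, x.copy(), 64, None, 0.5, 0.25, seed=9)]
        roles3 = [p.role for p in make_patches(x, x.copy(), 64, None, 0.5, 0.25, seed=10)]
        assert roles1 == roles2
        assert roles1 != roles3
        assert roles1.count("val") == round(0.25 * len(roles1))

    def test_invalid_holdout_and_overlap_rejected(self):
        x = checker(128, 128)
        with pytest.raises(ValueError, match="does not fit"):
            make_patches(x, x.copy(), 64, holdout=(0, 0, 256, 256))
        with pytest.raises(ValueError, match="overlap_test"):
            make_patches(x, x.copy(), 64, holdout=(0, 0, 128, 128), overlap_test=0.25)

    def test_geometry_mismatch_rejected(self):
        with pytest.raises(ValueError, match="share"):
            make_patches(checker(64, 64), checker(64, 96), 32)


class TestLumenNegative:
    def test_artifact_only_patch_becomes_zero(self):
        y = np.zeros((32, 32), dtype=np.uint8)
        lumen = np.zeros((32, 32), dtype=bool)
        lumen[10:20, 10:20] = True
        y[lumen] = 180
        assert not mask_lumen_negative(y, lumen).any()

    def test_without_lumen_only_stretch_applies(self):
        y = np.zeros((32, 32), dtype=np.uint8)
        y[4:12, 4:12] = 100
        out = mask_lumen_negative(y, np.zeros((32, 32), bool))
        assert not out[y == 0].any()  # zero pixels stay zero
        assert (out[y == 100] == 255).all()  # stretched to full range

    def test_phantom_artifact_cleaned_to_reference_rendering(self):
        spec = PhantomSpec.example((96, 144), noise_sd=0.0, seed=2)
        pair = render_phantom(spec)
        lumen = pair.label_mask == 4
        cleaned = mask_lumen_negative(pair.fluor_image.data, lumen)
        clean = pair.fluor_image_clean.data.astype(float)
        # identical up to the percentile stretch
        assert np.abs(cleaned.astype(float) - clean).max() <= 12

    def test_mask_geometry_checked(self):
        with pytest.raises(ValueError, match="geometry"):
            mask_lumen_negative(np.zeros((8, 8), np.uint8), np.zeros((4, 4), bool))


class TestAugment:
    def make_pair(self, seed=0):
        return TrainingPair(checker(64, 64, seed=seed), checker(64, 64, seed=seed + 1))

    def test_factor_is_exactly_twelve(self):
        outputs = [augment(self.make_pair(i), seed=i) for i in range(5)]
        assert all(len(o) == 12 for o in outputs)
        assert sum(len(o) for o in outputs) == 60

    def test_identity_variant_bit_identical(self):
        pair = self.make_pair()
        out = augment(pair, seed=3)
        assert np.array_equal(out[0].x, pair.x)
        assert np.array_equal(out[0].y, pair.y)

    def test_deterministic_under_seed(self):
        pair = self.make_pair()
        a = augment(pair, seed=11)
        b = augment(pair, seed=11)
        c = augment(pair, seed=12)
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.x, pb.x) and np.array_equal(pa.y, pb.y)
        assert any(not np.array_equal(pa.x, pc.x) for pa, pc in zip(a, c))

    def test_flip_variants_transform_y_exactly(self):
        pair = self.make_pair()
        out = augment(pair, seed=0)
        by_op = {p.provenance["transform"][0]: p for p in out
                 if p.provenance["transform"][0] == "flip"
                 and p.provenance["transform"][1]["axis"] == "horizontal"}
        hflip = next(p for p in out
                     if p.provenance["transform"] == ("flip", {"axis": "horizontal"}))
        assert np.array_equal(hflip.y, np.flip(pair.y, axis=1))

    def test_jitter_applies_to_x_only(self):
        pair = self.make_pair()
        out = augment(pair, seed=1)
        hflip = next(p for p in out
                     if p.provenance["transform"] == ("flip", {"axis": "horizontal"}))
        assert np.array_equal(hflip.y, np.flip(pair.y, axis=1))
        assert not np.array_equal(hflip.x, np.flip(pair.x, axis=1))
        no_jitter = AugmentationPolicy(jitter_px=0.0)
        hflip0 = augment(pair, no_jitter, seed=1)[7]
        assert np.array_equal(hflip0.x, np.flip(pair.x, axis=1))

    def test_geometry_preserved_and_policy_validated(self):
        pair = self.make_pair()
        for p in augment(pair, seed=0):
            assert p.x.shape == pair.x.shape and p.y.shape == pair.y.shape
        with pytest.raises(ValueError, match="target_factor"):
            AugmentationPolicy(ops=(("identity", {}),), target_factor=12)


class TestDiscard:
    def test_blank_patch_discarded(self):
        blank_dab = TrainingPair(checker(32, 32), np.full((32, 32, 3), 250, np.uint8))
        kept, report = discard_damaged([blank_dab])
        assert kept == [] and report["blank"] == 1

    def test_pristine_phantom_patches_kept(self, phantom_pair):
        dab = phantom_pair.dab_image.data
        pairs = [TrainingPair(dab[:64, c:c + 64].copy(), dab[:64, c:c + 64].copy())
                 for c in (0, 64)]
        kept, report = discard_damaged(pairs)
        assert len(kept) == 2 and report == {"blank": 0, "registration_error": 0,
                                             "kept": 2}

    def test_landmark_error_rule_discards_exactly_k(self):
        pairs = [TrainingPair(checker(32, 32, seed=i), checker(32, 32, seed=i + 50),
                              registration_error=err)
                 for i, err in enumerate([0.5, 3.0, None, 2.5, 1.9])]
        kept, report = discard_damaged(pairs, DiscardRules(max_registration_error=2.0))
        assert report["registration_error"] == 2
        assert len(kept) == 3
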