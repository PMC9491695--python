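import dataclasses

import numpy as np
import pytest

from hsistain.hypercube import default_axis
from hsistain.phantom import (MASK_ABETA, MASK_PTAU, Deposit, PhantomSpec,
                              StainImage, apply_known_warp, make_tissue_spectrum,
                              render_phantom, _illumination)
from hsistain.registration import SimilarityTransform

AXIS = default_axis()
IN_PLATEAU = (AXIS >= 550) & (AXIS <= 650)


def cv(values):
    return values.std() / values.mean()


class TestTissueSpectra:
    def test_spectra_lie_in_unit_interval(self):
        for cls in ("tissue", "ptau", "abeta"):
            s = make_tissue_spectrum(AXIS, cls, 1.0)
            assert np.all(s > 0) and np.all(s <= 1)

    def test_ptau_flat_hat_more_uniform_than_tissue(self):
        tissue = make_tissue_spectrum(AXIS, "tissue")
        ptau = make_tissue_spectrum(AXIS, "ptau", 1.0)
        assert cv(ptau[IN_PLATEAU]) < cv(tissue[IN_PLATEAU])
        # plateau is elevated, not just flattened
        assert ptau[IN_PLATEAU].mean() > tissue[IN_PLATEAU].mean()

    def test_ptau_uniformity_increases_with_amplitude(self):
        cvs = [cv(make_tissue_spectrum(AXIS, "ptau", a)[IN_PLATEAU])
               for a in (0.25, 0.5, 0.75, 1.0)]
        assert all(b < a for a, b in zip(cvs, cvs[1:]))

    def test_zero_amplitude_is_identity(self):
        tissue = make_tissue_spectrum(AXIS, "tissue")
        assert np.array_equal(make_tissue_spectrum(AXIS, "abeta", 0.0), tissue)

    def test_abeta_attenuation_matches_direct_formula(self):
        # independent brute-force evaluation of the stated attenuation
        baseline = make_tissue_spectrum(AXIS, "tissue")
        expected = np.array([
            b * (1.0 - 0.3 * 1.0 * (500.0 / w) ** 4)
            for w, b in zip(AXIS, baseline)
        ])
        got = make_tissue_spectrum(AXIS, "abeta", 1.0)
        assert np.allclose(got, expected, atol=1e-12)
        window = (AXIS >= 450) & (AXIS <= 600)
        assert got[window].mean() < baseline[window].mean()
        # per-band deficit proportional to lambda^-4
        deficit = (baseline - got) / baseline
        assert np.allclose(deficit * AXIS**4, deficit[0] * AXIS[0] ** 4)

    def test_unknown_class_and_bad_inputs(self):
        with pytest.raises(ValueError, match="unknown spectrum class 'lipofuscin'"):
            make_tissue_spectrum(AXIS, "lipofuscin")
        with pytest.raises(ValueError, match="amplitude"):
            make_tissue_spectrum(AXIS, "abeta", 1.5)
        with pytest.raises(ValueError, match="420"):
            make_tissue_spectrum([400, 500], "tissue")


class TestRenderPhantom:
    def test_same_seed_bit_identical(self):
        spec = PhantomSpec.example((64, 96), noise_sd=0.02, seed=7)
        a, b = render_phantom(spec), render_phantom(spec)
        assert np.array_equal(a.hypercube.data, b.hypercube.data)
        assert np.array_equal(a.dab_image.data, b.dab_image.data)
        assert np.array_equal(a.fluor_image.data, b.fluor_image.data)
        assert np.array_equal(a.label_mask, b.label_mask)

    def test_distinct_seeds_differ(self):
        a = render_phantom(PhantomSpec.example((64, 96), noise_sd=0.02, seed=1))
        b = render_phantom(PhantomSpec.example((64, 96), noise_sd=0.02, seed=2))
        assert not np.array_equal(a.hypercube.data, b.hypercube.data)

    def test_noiseless_deposit_spectrum_is_exact(self):
        spec = PhantomSpec(
            image_shape=(64, 96), noise_sd=0.0,
            deposits=(Deposit("ptau", (40, 48), 6.0, 1.0),),
        )
        pair = render_phantom(spec)
        illum = _illumination((64, 96))
        expected = make_tissue_spectrum(spec.wavelengths, "ptau", 1.0)
        px = np.argwhere(pair.label_mask == MASK_PTAU)
        assert len(px) > 0
        for r, c in px[:20]:
            assert np.allclose(pair.hypercube.data[r, c] / illum[r, c], expected,
                               atol=1e-12)

    def test_no_deposits_means_dark_fluorescence(self):
        spec = PhantomSpec(image_shape=(48, 64), noise_sd=0.0)
        pair = render_phantom(spec)
        assert not pair.fluor_image.data[:, :, :2].any()

    def test_out_of_bounds_deposit_rejected(self):
        spec = PhantomSpec(image_shape=(48, 64), noise_sd=0.0)
        bad = dataclasses.replace(spec, deposits=(Deposit("abeta", (2, 5), 8.0, 1.0),))
        with pytest.raises(ValueError, match="exceeds image bounds"):
            render_phantom(bad)

    def test_class_separability_above_noise(self, phantom_pair):
        cube, mask = phantom_pair.hypercube, phantom_pair.label_mask
        means = {
            code: cube.data[mask == code].mean(axis=0)
            for code in (1, MASK_ABETA, MASK_PTAU)
        }
        codes = list(means)
        for i, a in enumerate(codes):
            for b in codes[i + 1:]:
                assert np.abs(means[a] - means[b]).max() > 5 * 0.02

    def test_mask_and_fluorescence_channels_consistent(self, phantom_pair):
        fluor = phantom_pair.fluor_image.data
        mask = phantom_pair.label_mask
        assert not fluor[mask == MASK_ABETA, 0].any()  # abeta has no red
        assert not fluor[mask == MASK_PTAU, 1].any()  # ptau has no green
        assert fluor[mask == MASK_ABETA, 1].all()
        assert fluor[mask == MASK_PTAU, 0].all()

    def test_lumen_artifact_only_in_artifact_rendering(self, phantom_pair):
        dirty = phantom_pair.fluor_image.data
        clean = phantom_pair.fluor_image_clean.data
        lumen = phantom_pair.label_mask == 4
        assert dirty[lumen].any()
        assert not clean[lumen].any()
        outside = ~lumen
        assert np.array_equal(dirty[outside], clean[outside])


class TestKnownWarp:
    def test_identity_transform_is_pixel_identical(self, phantom_pair):
        warped, inverse = apply_known_warp(phantom_pair.dab_image,
                                           SimilarityTransform())
        assert np.array_equal(warped.data, phantom_pair.dab_image.data)
        assert inverse.rotation_deg == 0 and inverse.scale == 1

    def test_translation_inverse_is_negated(self, phantom_pair):
        _, inverse = apply_known_warp(
            phantom_pair.dab_image, SimilarityTransform(0.0, 1.0, (5.0, -3.0)))
        assert inverse.translation == (-5.0, 3.0)

    def test_warp_roundtrip_within_interpolation_tolerance(self, phantom_pair):
        tf = SimilarityTransform(7.0, 1.1, (0.0, 0.0))
        warped, inverse = apply_known_warp(phantom_pair.dab_image, tf)
        back, _ = apply_known_warp(warped, inverse)
        rows, cols = back.data.shape[:2]
        interior = (slice(10, rows - 10), slice(10, cols - 10))
        diff = np.abs(back.data[interior].astype(float)
                      - phantom_pair.dab_image.data[interior].astype(float))
        assert diff.mean() < 2.0

    def test_degenerate_and_out_of_range_transforms_rejected(self, phantom_pair):
        with pytest.raises(ValueError):
            SimilarityTransform(0.0, 0.0)
        with pytest.raises(ValueError, match="rotation"):
            apply_known_warp(phantom_pair.dab_image, SimilarityTransform(20.0, 1.0))
        with pytest.raises(ValueError, match="scale"):
            apply_known_warp(phantom_pair.dab_image, SimilarityTransform(0.0, 1.5))


class TestSpecValidation:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="strictly increasing fractions"):
            PhantomSpec(layer_boundaries=(0.5, 0.2, 0.8))
        with pytest.raises(ValueError, match="amplitude"):
            PhantomSpec(deposits=(Deposit("ptau", (10, 10), 3.0, 1.5),))
        with pytest.raises(ValueError, match="noise_sd"):
            PhantomSpec(noise_sd=-0.1)
        with pytest.raises(ValueError, match="8-bit"):
            StainImage(np.zeros((4, 4, 3), dtype=np.float32), "dab")
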