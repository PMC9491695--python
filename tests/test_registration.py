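import numpy as np
import pytest

from hsistain.phantom import apply_known_warp
from hsistain.registration import (ControlPointSet, SimilarityTransform,
                                   complement_8bit, fit_lwm, load_control_points,
                                   most_contrast_band, register_lwm,
                                   register_similarity)


class TestComplement:
    def test_boundary_values(self):
        img = np.array([[0, 255], [128, 7]], dtype=np.uint8)
        out = complement_8bit(img)
        assert out[0, 0] == 255 and out[0, 1] == 0
        assert out[1, 0] == 127 and out[1, 1] == 248

    def test_involution(self, rng):
        img = rng.integers(0, 256, size=(33, 47), dtype=np.uint8)
        assert np.array_equal(complement_8bit(complement_8bit(img)), img)

    def test_requires_8bit(self):
        with pytest.raises(ValueError, match="8-bit"):
            complement_8bit(np.zeros((4, 4), dtype=np.uint16))


class TestSimilarity:
    def test_self_registration_is_identity(self, phantom_pair):
        img = phantom_pair.dab_image.data
        res = register_similarity(img, img)
        assert abs(res.transform.rotation_deg) < 0.1
        assert abs(res.transform.scale - 1.0) < 0.005
        assert np.hypot(*res.transform.translation) < 0.5
        assert res.score > 0.99

    def test_recovery_of_seeded_transforms(self, phantom_pair):
        """>= 95% of 50 random warps recovered within 0.5 deg / 1% / 1 px."""
        rng = np.random.default_rng(2024)
        img = phantom_pair.dab_image
        ok = 0
        for _ in range(50):
            truth = SimilarityTransform(
                float(rng.uniform(-12, 12)), float(rng.uniform(0.85, 1.2)),
                (float(rng.uniform(-8, 8)), float(rng.uniform(-8, 8))))
            warped, inverse = apply_known_warp(img, truth)
            res = register_similarity(warped.data, img.data)
            ok += (
                abs(res.transform.rotation_deg - inverse.rotation_deg) <= 0.5
                and abs(res.transform.scale / inverse.scale - 1.0) <= 0.01
                and abs(res.transform.translation[0] - inverse.translation[0]) <= 1.0
                and abs(res.transform.translation[1] - inverse.translation[1]) <= 1.0
            )
        assert ok >= 48  # 96% of 50

    def test_metric_invariant_to_complementing_both(self, phantom_pair):
        img = phantom_pair.dab_image
        warped, inverse = apply_known_warp(img, SimilarityTransform(5.0, 1.05, (3, -2)))
        res_a = register_similarity(warped.data, img.data)
        res_b = register_similarity(complement_8bit(warped.data),
                                    complement_8bit(img.data))
        assert abs(res_a.transform.rotation_deg - res_b.transform.rotation_deg) < 0.2
        assert abs(res_a.transform.scale - res_b.transform.scale) < 0.005

    def test_blank_inputs_flagged_degenerate(self):
        blank = np.full((32, 32), 128, dtype=np.uint8)
        res = register_similarity(blank, blank)
        assert res.degenerate
        assert res.transform == SimilarityTransform()
        assert np.isnan(res.score)

    def test_inverse_composition_is_identity(self):
        tf = SimilarityTransform(9.0, 1.15, (4.0, -6.0))
        m = tf.matrix((64, 64)) @ tf.inverse().matrix((64, 64))
        assert np.allclose(m, np.eye(3), atol=1e-12)


class TestMostContrastBand:
    def test_prefers_structured_band(self, phantom_pair):
        idx = most_contrast_band(phantom_pair.hypercube)
        data = phantom_pair.hypercube.data
        sds = data.reshape(-1, data.shape[2]).std(axis=0)
        assert sds[idx] == sds.max()


def quadratic_warp(points):
    x, y = points[:, 0], points[:, 1]
    return np.column_stack([
        5.0 + 1.02 * x + 0.01 * y + 4e-4 * x * x + 2e-4 * x * y,
        -3.0 + 0.99 * y + 0.02 * x + 3e-4 * y * y,
    ])


class TestLWM:
    def grid_points(self, n=5, span=80.0):
        g = np.linspace(5.0, span, n)
        xx, yy = np.meshgrid(g, g)
        return np.column_stack([xx.ravel(), yy.ravel()])

    def test_exact_at_control_points_with_six_pairs(self):
        fixed = np.array([[10, 10], [70, 12], [40, 40], [12, 70], [68, 66], [40, 8.0]])
        moving = fixed + [[3, -2]]
        tf = fit_lwm(ControlPointSet(fixed, moving))
        mapped = tf(fixed)
        assert np.abs(mapped - moving).max() < 0.5

    def test_agrees_with_global_similarity(self):
        fixed = self.grid_points()
        sim = SimilarityTransform(8.0, 1.1, (5.0, -4.0))
        h = sim.matrix((96, 96))
        moving = (np.column_stack([fixed, np.ones(len(fixed))]) @ h.T)[:, :2]
        tf = fit_lwm(ControlPointSet(fixed, moving))
        assert np.abs(tf(fixed) - moving).max() < 0.5

    def test_improves_on_similarity_for_quadratic_deformation(self):
        fixed = self.grid_points()
        moving = quadratic_warp(fixed)
        lwm_err = np.linalg.norm(fit_lwm(ControlPointSet(fixed, moving))(fixed)
                                 - moving, axis=1).mean()
        # best-fit similarity (orthogonal Procrustes, closed form) as the
        # independent baseline
        fc = fixed - fixed.mean(axis=0)
        mc = moving - moving.mean(axis=0)
        a = (fc[:, 0] * mc[:, 0] + fc[:, 1] * mc[:, 1]).sum()
        b = (fc[:, 0] * mc[:, 1] - fc[:, 1] * mc[:, 0]).sum()
        scale = np.hypot(a, b) / (fc**2).sum()
        th = np.arctan2(b, a)
        rot = scale * np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        sim_pred = fc @ rot.T + moving.mean(axis=0)
        sim_err = np.linalg.norm(sim_pred - moving, axis=1).mean()
        assert lwm_err < sim_err

    def test_warps_image_content(self, phantom_pair):
        img = phantom_pair.dab_image.data
        fixed = self.grid_points()
        moving = fixed + [[4.0, 0.0]]  # pure shift expressed as landmarks
        out = register_lwm(ControlPointSet(fixed, moving), img, cval=255.0)
        inner = (slice(20, 70), slice(20, 70))
        shifted = img[20:70, 24:74]
        assert np.abs(out[inner].astype(float) - shifted.astype(float)).mean() < 2.0

    def test_minimum_pair_count_enforced(self):
        pts = np.random.default_rng(0).uniform(0, 50, size=(5, 2))
        with pytest.raises(ValueError, match="at least 6"):
            fit_lwm(ControlPointSet(pts, pts))

    def test_collinear_neighborhood_identified(self):
        x = np.linspace(0, 100, 8)
        fixed = np.column_stack([x, 2 * x + 1])  # all on one line
        with pytest.raises(ValueError, match="degenerate.*control point"):
            fit_lwm(ControlPointSet(fixed, fixed))

    def test_control_point_file_roundtrip(self, tmp_path):
        path = tmp_path / "points.txt"
        path.write_text("1 2 3 4\n5 6 7 8\n")
        cps = load_control_points(path)
        assert len(cps) == 2
        assert np.array_equal(cps.fixed_points, [[1, 2], [5, 6]])
        assert np.array_equal(cps.moving_points, [[3, 4], [7, 8]])
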