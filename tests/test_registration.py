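"""Mutual information, warping, the registration objective and point
transfer."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neotherm.registration import (
    DegenerateImageError,
    OptimizerSettings,
    RegistrationMap,
    fit_registration,
    joint_histogram,
    marginal_entropies,
    mutual_information,
    point_transform_error,
    px_to_mm,
    registration_objective,
    to_grayscale,
    transform_keypoints,
    transform_points,
    warp_to_irt,
)

from ._reference import ref_resample_mean


class TestGrayscale:
    @pytest.mark.parametrize("color, expected", [
        ((255, 255, 255), 255),
        ((255, 0, 0), 76),     # 0.299 * 255 = 76.245
        ((0, 255, 0), 150),
        ((0, 0, 255), 29),
    ])
    def test_known_conversions(self, color, expected):
        img = np.full((2, 2, 3), color, dtype=np.uint8)
        assert (to_grayscale(img) == expected).all()

    @given(st.integers(0, 255))
    @settings(max_examples=40, deadline=None)
    def test_gray_input_is_identity(self, g):
        img = np.full((1, 1, 3), g, dtype=np.uint8)
        assert to_grayscale(img)[0, 0] == g

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(ValueError):
            to_grayscale(np.zeros((4, 4)))


class TestWarp:
    def test_identity_map_is_identity(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 255, (32, 32))
        out, mask = warp_to_irt(img, RegistrationMap.identity(), (32, 32))
        assert mask.all()
        np.testing.assert_allclose(out, img, atol=1e-9)

    def test_pure_translation_shifts_columns(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 255, (20, 40))
        rmap = RegistrationMap(affine=[[1, 0, 10], [0, 1, 0]])
        out, mask = warp_to_irt(img, rmap, (40, 20))
        np.testing.assert_allclose(out[:, 10:], img[:, :30], atol=1e-9)
        assert not mask[:, :10].any()

    def test_downscale_preserves_mean_vs_brute_force(self):
        # checkerboard under 0.5x scale: compare against the loop resampler
        img = np.indices((16, 16)).sum(axis=0) % 2 * 255.0
        rmap = RegistrationMap(affine=[[0.5, 0, 0], [0, 0.5, 0]])
        out, mask = warp_to_irt(img, rmap, (8, 8))
        ref_mean, ref_n = ref_resample_mean(img, rmap, (8, 8))
        assert mask.sum() == ref_n
        assert out[mask].mean() == pytest.approx(ref_mean, rel=1e-2)

    def test_crop_limits_valid_region(self):
        img = np.ones((20, 20))
        rmap = RegistrationMap(affine=[[1, 0, 0], [0, 1, 0]], crop_x=5, crop_y=0)
        _, mask = warp_to_irt(img, rmap, (20, 20))
        # sources are u + crop_x, valid while u + 5 <= 14
        assert mask[:, :10].all() and not mask[:, 10:].any()


class TestJointHistogram:
    def test_independent_two_by_two(self):
        h = joint_histogram(np.array([[0., 0.], [1., 1.]]),
                            np.array([[0., 1.], [0., 1.]]), bins=2)
        np.testing.assert_array_equal(h.counts, [[1, 1], [1, 1]])
        assert h.n == 4

    def test_identical_images_are_diagonal(self):
        img = np.array([[0., 0.], [1., 1.]])
        h = joint_histogram(img, img, bins=2)
        np.testing.assert_array_equal(h.counts, [[2, 0], [0, 2]])

    def test_single_bin_counts_mask(self):
        img = np.arange(12.0).reshape(3, 4)
        mask = img > 5
        h = joint_histogram(img, img, mask=mask, bins=1)
        assert h.counts[0, 0] == mask.sum() == h.n

    def test_marginals_reproduce_image_histograms(self):
        rng = np.random.default_rng(0)
        a, b = rng.uniform(0, 1, (10, 10)), rng.uniform(0, 1, (10, 10))
        h = joint_histogram(a, b, bins=8)
        np.testing.assert_array_equal(
            h.counts.sum(axis=1), np.histogram(a, bins=h.edges_a)[0])
        np.testing.assert_array_equal(
            h.counts.sum(axis=0), np.histogram(b, bins=h.edges_b)[0])

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="mask"):
            joint_histogram(np.zeros((2, 2)), np.zeros((2, 2)),
                            mask=np.zeros((2, 2), dtype=bool))


class TestMutualInformation:
    def _h(self, counts):
        counts = np.asarray(counts)
        return joint_histogram.__wrapped__ if False else __import__(
            "neotherm.registration", fromlist=["JointHistogram"]
        ).JointHistogram(counts=counts, edges_a=np.arange(counts.shape[0] + 1),
                         edges_b=np.arange(counts.shape[1] + 1),
                         n=int(counts.sum()))

    def test_independent_is_zero(self):
        assert mutual_information(self._h([[25, 25], [25, 25]])) == pytest.approx(0.0)

    def test_identical_binary_is_ln2(self):
        assert mutual_information(self._h([[50, 0], [0, 50]])) == pytest.approx(
            np.log(2), abs=1e-12)

    def test_label_permutation_invariance(self):
        assert mutual_information(self._h([[0, 50], [50, 0]])) == pytest.approx(
            np.log(2), abs=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=200, deadline=None)
    def test_symmetry_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 9))
        counts = rng.integers(0, 30, (k, k))
        if counts.sum() == 0:
            counts[0, 0] = 1
        h = self._h(counts)
        mi = mutual_information(h)
        assert mi == pytest.approx(mutual_information(h.transpose()), abs=1e-12)
        hx, hy = marginal_entropies(h)
        assert -1e-9 <= mi <= min(hx, hy) + 1e-9


class TestRegistrationObjective:
    def _phantom(self):
        from .conftest import small_phantom_config
        from neotherm.phantom import generate_phantom_pair
        cfg = small_phantom_config(noise_sd_irt=0.0, noise_sd_rgb=0.0)
        return generate_phantom_pair(cfg), cfg

    def test_equals_composed_stage_calls(self):
        (pair, truth), cfg = self._phantom()
        gray = to_grayscale(pair.rgb).astype(float)
        irt = pair.thermal.temperatures
        st_ = OptimizerSettings(min_overlap_fraction=1e-6)
        params = np.array([10.0, 6.0, 0.58, 0.60, 3.0, 37.0, 25.0])
        obj = registration_objective(params, gray, irt, st_)
        rmap = RegistrationMap.from_params(*params)
        warped, mask = warp_to_irt(gray, rmap, (irt.shape[1], irt.shape[0]))
        h = joint_histogram(warped, irt, mask, st_.bins)
        assert obj == pytest.approx(mutual_information(h), abs=1e-12)

    def test_truth_beats_translated_candidate(self):
        (pair, truth), cfg = self._phantom()
        gray = to_grayscale(pair.rgb).astype(float)
        irt = pair.thermal.temperatures
        st_ = OptimizerSettings()
        p_true = np.array([10.0, 6.0, 0.58, 0.60, 3.0, 37.0, 25.0])
        p_off = p_true + np.array([30.0, 0, 0, 0, 0, 0, 0])
        assert registration_objective(p_true, gray, irt, st_) >= \
            registration_objective(p_off, gray, irt, st_)

    def test_low_overlap_penalized(self):
        (pair, truth), cfg = self._phantom()
        gray = to_grayscale(pair.rgb).astype(float)
        irt = pair.thermal.temperatures
        params = np.array([10.0, 6.0, 0.58, 0.60, 3.0, 37.0, 25.0])
        loose = OptimizerSettings(min_overlap_fraction=1e-9)
        strict = OptimizerSettings(min_overlap_fraction=1.0)
        assert registration_objective(params, gray, irt, strict) < \
            registration_objective(params, gray, irt, loose)

    def test_constant_irt_scores_zero(self):
        rng = np.random.default_rng(0)
        gray = rng.uniform(0, 255, (30, 48))
        irt = np.full((19, 25), 30.0)
        st_ = OptimizerSettings(min_overlap_fraction=1e-9)
        params = np.array([0.0, 0.0, 0.5, 0.5, 0.0, 0.0, 0.0])
        assert registration_objective(params, gray, irt, st_) == pytest.approx(0.0)

    def test_non_invertible_candidate_scores_minus_inf(self):
        gray = np.random.default_rng(0).uniform(0, 255, (30, 48))
        irt = np.random.default_rng(1).uniform(25, 40, (19, 25))
        params = np.array([0.0, 0.0, 0.0, 0.5, 0.0, 0.0, 0.0])  # sx = 0
        st_ = OptimizerSettings()
        assert registration_objective(params, gray, irt, st_) == -np.inf


class TestFitRegistration:
    def _self_registration_case(self, seed=0):
        """IRT := downscaled grayscale of the cropped RGB under a known map."""
        rng = np.random.default_rng(seed)
        # a compact bright blob cluster on a dark background, as in the
        # dark-environment recordings the registration targets
        yy, xx = np.mgrid[0:150, 0:240].astype(float)
        base = np.full((150, 240), 8.0)
        for _ in range(6):
            cx, cy = rng.uniform(90, 170), rng.uniform(50, 110)
            r = rng.uniform(12, 30)
            amp = rng.uniform(120, 220)
            base += amp * np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * r**2)))
        base = np.clip(base, 0, 255)
        rgb = np.repeat(base[:, :, None], 3, axis=2).astype(np.uint8)
        true = RegistrationMap.from_params(tx=6.0, ty=-4.0, sx=0.55, sy=0.6,
                                           theta_deg=2.0, crop_x=20.0, crop_y=12.0)
        irt, _ = warp_to_irt(base, true, (128, 96))
        return rgb, irt, true

    def test_self_registration_recovers_map(self):
        rgb, irt, true = self._self_registration_case()
        bounds = {"tx": (-60.0, 60.0), "ty": (-60.0, 60.0),
                  "crop_x": (0.0, 60.0), "crop_y": (0.0, 40.0)}
        settings_ = OptimizerSettings(seed=0, bounds=bounds)
        rmap, mi, trace = fit_registration(rgb, irt, settings_)
        pts = np.random.default_rng(2).uniform(40, 200, (50, 2))
        err = np.linalg.norm(rmap.apply(pts) - true.apply(pts), axis=1).mean()
        assert err <= 2.0
        assert len(trace) >= 1

    def test_seeded_determinism(self):
        rgb, irt, _ = self._self_registration_case(1)
        settings_ = OptimizerSettings(seed=5, n_evals=120, n_global=60)
        a = fit_registration(rgb, irt, settings_)
        b = fit_registration(rgb, irt, settings_)
        np.testing.assert_array_equal(a[0].affine, b[0].affine)
        assert (a[0].crop_x, a[0].crop_y, a[1]) == (b[0].crop_x, b[0].crop_y, b[1])

    def test_constant_images_rejected(self):
        flat = np.zeros((20, 30), dtype=float)
        textured = np.random.default_rng(0).uniform(0, 255, (20, 30))
        with pytest.raises(DegenerateImageError, match="RGB"):
            fit_registration(flat, textured, OptimizerSettings(n_evals=5))
        with pytest.raises(DegenerateImageError, match="IRT"):
            fit_registration(textured, np.full((20, 30), 7.0),
                             OptimizerSettings(n_evals=5))


class TestTransformPoints:
    @pytest.mark.parametrize("rmap, pt, expected", [
        (RegistrationMap.identity(), (100, 50), (100, 50)),
        (RegistrationMap(affine=[[1, 0, 10], [0, 1, -5]]), (100, 50), (110, 45)),
        (RegistrationMap(affine=[[1, 0, 0], [0, 1, 0]], crop_x=160, crop_y=0),
         (200, 100), (40, 100)),
    ])
    def test_known_transforms(self, rmap, pt, expected):
        out = transform_points(np.array([pt], dtype=float), rmap)
        np.testing.assert_allclose(out[0], expected)

    @given(st.integers(0, 5000))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_recovers_points(self, seed):
        rng = np.random.default_rng(seed)
        rmap = RegistrationMap.from_params(
            tx=rng.uniform(-100, 100), ty=rng.uniform(-100, 100),
            sx=rng.uniform(0.3, 1.5), sy=rng.uniform(0.3, 1.5),
            theta_deg=rng.uniform(-15, 15),
            crop_x=rng.uniform(0, 200), crop_y=rng.uniform(0, 200))
        pts = rng.uniform(-500, 500, (20, 2))
        back = rmap.apply_inverse(rmap.apply(pts))
        np.testing.assert_allclose(back, pts, atol=1e-6)

    def test_visibility_passes_through_and_oob_flagged(self):
        from .conftest import full_keypoint_set
        kps = full_keypoint_set(np.random.default_rng(0), frame=(100, 100))
        kps.visibility[3] = 0
        rmap = RegistrationMap(affine=[[1, 0, 95], [0, 1, 0]])
        out, oob = transform_keypoints(kps, rmap, irt_size=(100, 100))
        np.testing.assert_array_equal(out.visibility, kps.visibility)
        assert oob.any()  # pushed past the right edge
        assert len(out.x) == 18


class TestPointError:
    def test_identical_points_give_zero(self):
        pts = np.random.default_rng(0).uniform(0, 100, (10, 2))
        st_ = point_transform_error(pts, pts)
        assert (st_.mae_x_px, st_.mae_y_px, st_.sd_x_px, st_.sd_y_px) == (0, 0, 0, 0)

    def test_single_offset_pair(self):
        st_ = point_transform_error([[103.0, 46.0]], [[100.0, 50.0]],
                                    mm_per_px=0.5)
        assert st_.mae_x_px == pytest.approx(3.0)
        assert st_.mae_y_px == pytest.approx(4.0)
        assert st_.mae_x_mm == pytest.approx(1.5)
        assert st_.mae_y_mm == pytest.approx(2.0)

    def test_matches_pairwise_recomputation(self):
        rng = np.random.default_rng(3)
        pred = rng.uniform(0, 300, (100, 2))
        gt = pred + rng.normal(0, 5, (100, 2))
        st_ = point_transform_error(pred, gt, mm_per_px=0.5)
        dx = [abs(p[0] - g[0]) for p, g in zip(pred, gt)]
        dy = [abs(p[1] - g[1]) for p, g in zip(pred, gt)]
        assert st_.mae_x_px == pytest.approx(sum(dx) / 100, abs=1e-12)
        assert st_.mae_y_px == pytest.approx(sum(dy) / 100, abs=1e-12)
        mean_dx = sum(dx) / 100
        sd_dx = (sum((d - mean_dx) ** 2 for d in dx) / 99) ** 0.5
        assert st_.sd_x_px == pytest.approx(sd_dx, abs=1e-12)

    def test_no_pairs_rejected(self):
        with pytest.raises(ValueError):
            point_transform_error(np.empty((0, 2)), np.empty((0, 2)))


class TestPxToMm:
    @pytest.mark.parametrize("px, expected_mm", [
        (16.4, 8.2), (22.4, 11.2), (0.0, 0.0),
    ])
    def test_clinical_resolution_pairs(self, px, expected_mm):
        assert px_to_mm(px, 0.5) == pytest.approx(expected_mm)

    def test_non_positive_resolution_rejected(self):
        with pytest.raises(ValueError):
            px_to_mm(10.0, 0.0)
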