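"""Unit and property tests for landmark registration and warping."""

import math

import numpy as np
import pytest
from skimage.transform import SimilarityTransform

from seqstain.errors import InputError
from seqstain.io_formats import LandmarkSet, RGBImage
from seqstain.registration import (
    Transform2D,
    build_stack,
    estimate_transform,
    refine_transform,
    registration_error,
    warp_image,
)
from seqstain.synthetic import SlideSimParams, generate_multiround_slide

from .oracles import brute_force_similarity_fit, similarity_sse


def _set(points, rid="m"):
    return LandmarkSet(points=np.asarray(points, dtype=float), round_id=rid)


class TestTransform2D:
    def test_compose_invert_is_identity(self, rng):
        t = Transform2D.from_similarity(1.3, 0.4, -5.0, 2.5)
        assert np.allclose(t.compose(t.invert()).matrix, np.eye(3), atol=1e-9)

    def test_parameter_round_trip(self):
        t = Transform2D.from_similarity(2.0, math.radians(30), -4.0, 7.0)
        assert t.scale == pytest.approx(2.0, abs=1e-12)
        assert t.rotation == pytest.approx(math.radians(30), abs=1e-12)
        assert t.translation == pytest.approx((-4.0, 7.0))

    def test_json_round_trip(self, tmp_path):
        t = Transform2D.from_similarity(0.97, -0.2, 3.0, 1.5)
        path = tmp_path / "t.json"
        t.to_json(path)
        back = Transform2D.from_json(path)
        assert back.model == "similarity"
        assert np.allclose(back.matrix, t.matrix, atol=0)

    def test_invalid_matrices_rejected(self):
        with pytest.raises(InputError):
            Transform2D(np.zeros((3, 3)))
        with pytest.raises(InputError):
            Transform2D.from_similarity(-1.0, 0.0, 0.0, 0.0)


class TestEstimateTransform:
    def test_identity_for_identical_sets(self):
        pts = [[0.0, 0.0], [10.0, 0.0], [3.0, 7.0]]
        t = estimate_transform(_set(pts, "a"), _set(pts, "b"))
        assert t.scale == pytest.approx(1.0, abs=1e-12)
        assert t.rotation == pytest.approx(0.0, abs=1e-12)
        assert t.translation == pytest.approx((0.0, 0.0), abs=1e-12)

    def test_exact_rigid_quarter_turn(self):
        """+90 degree rotation with translation (2, 3), zero residual."""
        moving = _set([[0, 0], [1, 0], [0, 1]])
        fixed = _set([[2, 3], [2, 4], [1, 3]], "f")
        t = estimate_transform(moving, fixed)
        assert t.scale == pytest.approx(1.0, abs=1e-12)
        assert t.rotation == pytest.approx(math.pi / 2, abs=1e-12)
        assert t.translation == pytest.approx((2.0, 3.0), abs=1e-12)
        assert registration_error(t, moving, fixed) == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_parameter_recovery(self, rng):
        """Any similarity transform is recovered to 1e-9 from clean marks."""
        for _ in range(50):
            s = float(rng.uniform(0.5, 2.0))
            th = float(rng.uniform(-math.pi, math.pi))
            tx, ty = rng.uniform(-50, 50, 2)
            true = Transform2D.from_similarity(s, th, tx, ty)
            src = rng.uniform(0, 100, (int(rng.integers(2, 8)), 2))
            moving, fixed = _set(src), _set(true.apply(src), "f")
            est = estimate_transform(moving, fixed)
            assert est.scale == pytest.approx(s, abs=1e-9)
            assert abs((est.rotation - th + math.pi) % (2 * math.pi) - math.pi) < 1e-9
            assert est.translation == pytest.approx((tx, ty), abs=1e-9)
            assert registration_error(est, moving, fixed) <= 1e-9

    def test_noisy_fit_matches_brute_force_minimizer(self, rng):
        """The closed form is the global SSE minimizer (numeric oracle)."""
        true = Transform2D.from_similarity(2.0, math.radians(30), -4.0, 7.0)
        src = rng.uniform(0, 50, (5, 2))
        dst = true.apply(src) + rng.normal(0, 0.5, (5, 2))
        est = estimate_transform(_set(src), _set(dst, "f"))
        ref = brute_force_similarity_fit(src, dst)
        assert est.scale == pytest.approx(ref[0], abs=1e-6)
        assert est.rotation == pytest.approx(ref[1], abs=1e-6)
        assert est.translation == pytest.approx((ref[2], ref[3]), abs=1e-6)
        # least-squares optimality: never worse than the generating transform
        est_sse = similarity_sse(
            [est.scale, est.rotation, *est.translation], src, dst
        )
        true_sse = similarity_sse([2.0, math.radians(30), -4.0, 7.0], src, dst)
        assert est_sse <= true_sse + 1e-12

    def test_matches_skimage_similarity(self, rng):
        src = rng.uniform(0, 100, (6, 2))
        dst = rng.uniform(0, 100, (6, 2))
        est = estimate_transform(_set(src), _set(dst, "f"))
        ref = SimilarityTransform.from_estimate(src, dst)
        assert np.allclose(est.matrix, ref.params, atol=1e-9)

    def test_rotation_equivariance(self, rng):
        """Pre-rotating both point sets conjugates the estimate."""
        src = rng.uniform(0, 100, (5, 2))
        dst = src * 1.2 + rng.normal(0, 1.0, (5, 2)) + [3.0, -2.0]
        r = Transform2D.from_similarity(1.0, 0.7, 0.0, 0.0)
        t_plain = estimate_transform(_set(src), _set(dst, "f"))
        t_rot = estimate_transform(_set(r.apply(src)), _set(r.apply(dst), "f"))
        conjugated = r.compose(t_plain).compose(r.invert())
        assert np.allclose(t_rot.matrix, conjugated.matrix, atol=1e-9)

    def test_affine_recovery_and_degeneracy(self, rng):
        a = np.array([[1.2, 0.3, 5.0], [-0.1, 0.8, -2.0], [0, 0, 1.0]])
        true = Transform2D(a, model="affine")
        src = rng.uniform(0, 50, (6, 2))
        est = estimate_transform(_set(src), _set(true.apply(src), "f"), model="affine")
        assert np.allclose(est.matrix, a, atol=1e-9)
        collinear = np.column_stack([np.arange(4.0), 2.0 * np.arange(4.0)])
        with pytest.raises(InputError, match="collinear"):
            estimate_transform(_set(collinear), _set(collinear * 2.0, "f"), model="affine")

    def test_coincident_points_rejected(self):
        pts = [[5.0, 5.0], [5.0, 5.0], [5.0, 5.0]]
        with pytest.raises(InputError):
            estimate_transform(_set(pts), _set([[0, 0], [1, 1], [2, 2]], "f"))

    def test_unequal_counts_rejected(self):
        with pytest.raises(InputError, match="unequal"):
            registration_error(
                Transform2D.identity(), _set([[0, 0], [1, 1]]), _set([[0, 0], [1, 1], [2, 2]], "f")
            )


class TestRegistrationError:
    def test_three_four_five(self):
        t = Transform2D.identity()
        assert registration_error(t, _set([[0.0, 0.0], [0, 0]]), _set([[3.0, 4.0], [3, 4]], "f")) == pytest.approx(5.0)

    def test_matches_explicit_loop(self, rng):
        t = Transform2D.from_similarity(1.1, 0.3, 2.0, -1.0)
        src = rng.uniform(0, 100, (7, 2))
        dst = rng.uniform(0, 100, (7, 2))
        got = registration_error(t, _set(src), _set(dst, "f"))
        sq = [
            (t.apply(p[None, :])[0, 0] - q[0]) ** 2 + (t.apply(p[None, :])[0, 1] - q[1]) ** 2
            for p, q in zip(src, dst)
        ]
        assert got == pytest.approx(math.sqrt(sum(sq) / 7), abs=1e-12)


class TestWarpImage:
    def test_identity_is_exact(self, default_slide):
        img = default_slide[0][0]
        out = warp_image(img, Transform2D.identity())
        assert np.array_equal(out.pixels, img.pixels)

    def test_integer_translation_shifts_and_fills_white(self, default_slide):
        img = default_slide[0][0]
        t = Transform2D.from_similarity(1.0, 0.0, 10.0, 0.0)
        out = warp_image(img, t)
        assert np.array_equal(out.pixels[:, 10:], img.pixels[:, :-10])
        assert np.all(out.pixels[:, :10] == 255)

    def test_round_trip_interior_within_two_levels(self, default_slide):
        """Warp there and back reproduces a band-limited image to +/-2 levels.

        Bilinear interpolation error scales with image curvature, so the
        round-trip bound applies to smooth content; the tile is low-pass
        filtered before the check.
        """
        from skimage.filters import gaussian

        raw = default_slide[0][0]
        smooth = np.clip(
            np.rint(gaussian(raw.pixels.astype(float), sigma=5, channel_axis=2)), 0, 255
        ).astype(np.uint8)
        img = RGBImage(pixels=smooth, mpp=raw.mpp)
        t = Transform2D.from_similarity(1.0, 0.05, 3.2, -1.7)
        back = warp_image(warp_image(img, t), t.invert())
        # stay clear of the white-filled band the intermediate warp creates
        # (corner displacement ~ |theta| * r + |t| ~ 18 px here)
        interior = (slice(25, -25), slice(25, -25))
        diff = back.pixels[interior].astype(int) - img.pixels[interior].astype(int)
        assert np.abs(diff).max() <= 2


class TestRefineTransform:
    def test_identical_images_fixed_point(self, default_slide):
        img = default_slide[0][0]
        report = refine_transform(img, img, Transform2D.identity(), max_iter=5)
        assert report.iterations == 0
        assert np.allclose(report.transform.matrix, np.eye(3), atol=1e-12)

    def test_recovers_known_offset(self, small_slide_params):
        """A (2, -1.5) px shift is found within 0.5 px from identity."""
        from dataclasses import replace

        params = replace(
            small_slide_params,
            round_transforms={"r1": (1.0, 0.0, 0.0, 0.0), "r2": (1.0, 0.0, 2.0, -1.5)},
            rounds=(("r1", None), ("r2", None)),
        )
        rounds, _, _ = generate_multiround_slide(params)
        report = refine_transform(rounds[0], rounds[1], Transform2D.identity(), max_iter=30)
        assert report.transform.translation == pytest.approx((2.0, -1.5), abs=0.5)
        assert report.cost_history[-1] < report.cost_history[0]

    def test_cost_never_increases(self):
        """Across seeded pairs the recorded cost sequence is non-increasing."""
        from dataclasses import replace

        for seed in range(6):
            params = SlideSimParams(
                shape=(128, 128), n_cells=12, seed=seed,
                rounds=(("r1", None), ("r2", None)),
                round_transforms={"r1": (1.0, 0.0, 0.0, 0.0),
                                  "r2": (1.0, 0.0, 1.0 + seed % 3, -1.0)},
            )
            rounds, _, _ = generate_multiround_slide(params)
            report = refine_transform(rounds[0], rounds[1], Transform2D.identity(), max_iter=8)
            hist = np.asarray(report.cost_history)
            assert np.all(np.diff(hist) <= 1e-15)

    def test_empty_overlap_is_an_error(self, small_slide_params):
        rounds, _, _ = generate_multiround_slide(small_slide_params)
        far = Transform2D.from_similarity(1.0, 0.0, 10000.0, 0.0)
        with pytest.raises(InputError, match="overlap"):
            refine_transform(rounds[0], rounds[0], far, max_iter=1)


class TestBuildStack:
    def test_single_round_passthrough(self, default_slide):
        rounds, _, _ = default_slide
        out = build_stack(rounds[:1], {}, reference="r1")
        assert np.array_equal(out[0].pixels, rounds[0].pixels)

    def test_identity_pair_is_pixel_identical(self, default_slide):
        img = default_slide[0][0]
        dup = RGBImage(pixels=img.pixels.copy(), mpp=img.mpp, round_id="r2")
        out = build_stack([img, dup], {"r2": Transform2D.identity()}, reference="r1")
        assert np.array_equal(out[1].pixels, img.pixels)

    def test_missing_transform_is_an_error(self, default_slide):
        rounds, _, _ = default_slide
        with pytest.raises(InputError, match="missing transform"):
            build_stack(rounds, {}, reference="r1")

    def test_three_rounds_align_landmarks_within_one_pixel(self):
        params = SlideSimParams(
            seed=3,
            rounds=(("r1", "CD8"), ("r2", "GZMB"), ("r3", None)),
            round_transforms={
                "r1": (1.0, 0.0, 0.0, 0.0),
                "r2": (1.02, 0.015, 3.0, -2.0),
                "r3": (0.99, -0.01, -2.5, 1.5),
            },
        )
        rounds, landmark_sets, truth = generate_multiround_slide(params)
        ref_set = landmark_sets[0]
        transforms = {
            s.round_id: estimate_transform(s, ref_set)
            for s in landmark_sets[1:]
        }
        stack = build_stack(rounds, transforms, reference="r1")
        assert all(img.shape == rounds[0].shape for img in stack)
        for s in landmark_sets[1:]:
            rmse = registration_error(transforms[s.round_id], s, ref_set)
            assert rmse <= 1.0
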