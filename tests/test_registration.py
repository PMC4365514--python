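"""Marker detection, NCC refinement, homography fitting and warping."""

import numpy as np
import pytest

from aeropheno.errors import (
    FitError,
    InvalidSpecError,
    RegistrationInfeasibleError,
    UndefinedCorrelationError,
)
from aeropheno.image import SensorImage
from aeropheno.registration import (
    MarkerObservation,
    RegistrationModel,
    detect_markers,
    fit_projective,
    refine_by_ncc,
    upscale_thermal,
    warp_to_aoi,
)


def disk_image(centers, radius=6.0, shape=(512, 512), rng=None, dark=True):
    """Textured background with anti-aliasing-free dark (or bright) disks."""
    rng = rng or np.random.default_rng(0)
    bg = rng.normal(30000.0, 1500.0, shape)
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    for r0, c0 in centers:
        inside = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2
        bg[inside] = 500.0 if dark else 64000.0
    return SensorImage(bg, ("B",))


EIGHT_CENTERS = [
    (40.0, 40.0), (40.0, 256.0), (40.0, 470.0), (256.0, 40.0),
    (256.0, 470.0), (470.0, 40.0), (470.0, 256.0), (470.0, 470.0),
]


class TestDetectMarkers:
    def test_eight_disks_found_within_half_pixel(self, rng):
        img = disk_image(EIGHT_CENTERS, rng=rng)
        found = detect_markers(img, "dark", expected_radius_px=(3, 12),
                               max_markers=8)
        assert len(found) == 8
        centers = sorted(m.center for m in found)
        for got, want in zip(centers, sorted(EIGHT_CENTERS)):
            assert abs(got[0] - want[0]) <= 0.5
            assert abs(got[1] - want[1]) <= 0.5

    def test_uniform_image_is_infeasible(self):
        img = SensorImage(np.full((128, 128), 1000.0), ("B",))
        with pytest.raises(RegistrationInfeasibleError) as exc:
            detect_markers(img, "dark")
        assert exc.value.detections == []

    def test_single_disk_reported_in_partial_list(self, rng):
        img = disk_image([(64.0, 64.0)], shape=(128, 128), rng=rng)
        with pytest.raises(RegistrationInfeasibleError) as exc:
            detect_markers(img, "dark", expected_radius_px=(3, 12))
        (only,) = exc.value.detections
        assert abs(only.center[0] - 64.0) <= 0.5
        assert abs(only.center[1] - 64.0) <= 0.5

    def test_bright_polarity(self, rng):
        img = disk_image(EIGHT_CENTERS, rng=rng, dark=False)
        found = detect_markers(img, "bright", expected_radius_px=(3, 12))
        assert len(found) == 8

    def test_sorted_by_score_descending(self, rng):
        img = disk_image(EIGHT_CENTERS, rng=rng)
        found = detect_markers(img, "dark", expected_radius_px=(3, 12))
        scores = [m.score for m in found]
        assert scores == sorted(scores, reverse=True)


def brute_force_ncc(search, templ):
    """Exhaustive normalized cross-correlation over all placements."""
    th, tw = templ.shape
    t = (templ - templ.mean()) / templ.std()
    best, best_pos = -np.inf, None
    for r in range(search.shape[0] - th + 1):
        for c in range(search.shape[1] - tw + 1):
            win = search[r : r + th, c : c + tw]
            if win.std() == 0:
                continue
            w = (win - win.mean()) / win.std()
            score = float((t * w).mean())
            if score > best:
                best, best_pos = score, (r, c)
    return best_pos, best


class TestRefineByNcc:
    def test_self_correlation_is_unit_score_zero_offset(self, rng):
        img = SensorImage(rng.normal(100, 20, (64, 64)), ("B",))
        marker = MarkerObservation(center=(32.0, 32.0), radius=5.0)
        out = refine_by_ncc(img, img, marker, window_px=8, slack_px=5)
        assert out.center == (32.0, 32.0)
        assert out.score == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("offset", [(0, 0), (3, -2), (-4, 5)])
    def test_planted_template_recovered_exactly(self, offset, rng):
        search = rng.normal(100, 10, (80, 80))
        templ_src = rng.normal(100, 10, (80, 80))
        r0, c0 = 40 + offset[0], 40 + offset[1]
        patch = templ_src[40 - 8 : 40 + 9, 40 - 8 : 40 + 9]
        search[r0 - 8 : r0 + 9, c0 - 8 : c0 + 9] = patch
        t_img = SensorImage(templ_src, ("B",))
        s_img = SensorImage(search, ("B",))
        marker = MarkerObservation(center=(40.0, 40.0), radius=5.0)
        out = refine_by_ncc(t_img, s_img, marker, window_px=8, slack_px=6)
        assert out.center == (float(r0), float(c0))
        assert out.score == pytest.approx(1.0, abs=1e-9)
        # exhaustive NCC over the same search region is the oracle
        region = search[40 - 14 : 40 + 15, 40 - 14 : 40 + 15]
        (br, bc), _ = brute_force_ncc(region, patch)
        assert (40 - 14 + br + 8, 40 - 14 + bc + 8) == (r0, c0)

    def test_constant_template_rejected(self, rng):
        t_img = SensorImage(np.full((64, 64), 5.0), ("B",))
        s_img = SensorImage(rng.normal(0, 1, (64, 64)), ("B",))
        marker = MarkerObservation(center=(32.0, 32.0), radius=5.0)
        with pytest.raises(UndefinedCorrelationError):
            refine_by_ncc(t_img, s_img, marker, window_px=8, slack_px=4)

    def test_score_invariant_to_affine_intensity_change(self, rng):
        base = rng.normal(100, 10, (80, 80))
        t_img = SensorImage(base, ("B",))
        marker = MarkerObservation(center=(40.0, 40.0), radius=5.0)
        ref = refine_by_ncc(t_img, SensorImage(base, ("B",)), marker, 8, slack_px=5)
        scaled = refine_by_ncc(
            t_img, SensorImage(3.7 * base + 250.0, ("B",)), marker, 8, slack_px=5
        )
        assert scaled.score == pytest.approx(ref.score, abs=1e-9)
        assert scaled.center == ref.center

    def test_window_outside_image_rejected(self, rng):
        img = SensorImage(rng.normal(0, 1, (32, 32)), ("B",))
        marker = MarkerObservation(center=(2.0, 2.0), radius=5.0)
        with pytest.raises(InvalidSpecError):
            refine_by_ncc(img, img, marker, window_px=8, slack_px=4)


def random_homography(rng):
    H = np.eye(3)
    H[:2, :2] += rng.normal(0, 0.05, (2, 2))
    H[:2, 2] = rng.normal(0, 10, 2)
    H[2, :2] = rng.normal(0, 1e-4, 2)
    return H / H[2, 2]


def apply_h(H, pts):
    hom = np.column_stack([pts, np.ones(len(pts))]) @ H.T
    return hom[:, :2] / hom[:, 2:3]


class TestFitProjective:
    def test_identity_four_points(self):
        pts = [(0.0, 0.0), (0.0, 10.0), (10.0, 0.0), (10.0, 10.0)]
        model = fit_projective(list(zip(pts, pts)))
        assert np.allclose(model.H, np.eye(3), atol=1e-9)
        assert model.rmse == pytest.approx(0.0, abs=1e-9)

    def test_known_homography_recovered_from_eight_points(self, rng):
        H = random_homography(rng)
        src = rng.uniform(0, 500, (8, 2))
        dst = apply_h(H, src)
        model = fit_projective(list(zip(map(tuple, src), map(tuple, dst))))
        assert np.abs(model.H - H).max() < 1e-6

    def test_exactly_consistent_points_have_zero_residual(self, rng):
        for _ in range(10):
            H = random_homography(rng)
            n = int(rng.integers(4, 12))
            src = rng.uniform(0, 300, (n, 2))
            model = fit_projective(list(zip(map(tuple, src),
                                            map(tuple, apply_h(H, src)))))
            assert model.rmse <= 1e-6

    def test_collinear_points_rejected(self):
        src = [(0.0, 0.0), (1.0, 1.0), (2.0, 2.0), (3.0, 3.0)]
        dst = [(0.0, 0.0), (0.0, 1.0), (1.0, 0.0), (1.0, 1.0)]
        with pytest.raises(FitError, match="collinear"):
            fit_projective(list(zip(src, dst)))

    def test_too_few_pairs_rejected(self):
        pts = [(0.0, 0.0), (0.0, 1.0), (1.0, 0.0)]
        with pytest.raises(FitError, match=">= 4"):
            fit_projective(list(zip(pts, pts)))

    def test_transform_roundtrip(self, rng):
        H = random_homography(rng)
        src = rng.uniform(0, 100, (6, 2))
        model = fit_projective(list(zip(map(tuple, src),
                                        map(tuple, apply_h(H, src)))))
        back = model.inverse_transform(model.transform(src))
        assert np.allclose(back, src, atol=1e-6)


def smooth_image(shape, rng):
    yy, xx = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    return (
        1000.0
        + 300.0 * np.sin(xx / 23.0)
        + 200.0 * np.cos(yy / 31.0)
        + 100.0 * np.sin((xx + yy) / 17.0)
    )


class TestWarp:
    def test_identity_model_is_exact_crop(self, rng):
        img = SensorImage(rng.normal(0, 1, (64, 64)), ("B",))
        model = RegistrationModel(
            correspondences=[((0, 0), (0, 0))] * 4, H=np.eye(3), rmse=0.0
        )
        out = warp_to_aoi(img, model, (32, 48))
        assert np.array_equal(out.pixels[:, :, 0], img.pixels[:32, :48, 0])

    def test_roundtrip_error_small_away_from_borders(self):
        img = SensorImage(smooth_image((200, 200), None), ("B",))
        H = np.array([[1.01, 0.02, 3.0], [-0.015, 0.99, -2.0], [1e-5, -1e-5, 1.0]])
        fwd = RegistrationModel([((0, 0), (0, 0))] * 4, H, 0.0)
        inv = RegistrationModel([((0, 0), (0, 0))] * 4, np.linalg.inv(H), 0.0)
        there = warp_to_aoi(img, fwd, (200, 200))
        back = warp_to_aoi(there, inv, (200, 200))
        center = np.s_[20:-20, 20:-20, 0]
        diff = np.abs(back.pixels[center] - img.pixels[center])
        dyn = img.pixels.max() - img.pixels.min()
        assert np.nanmean(diff) < 0.01 * dyn

    def test_all_outside_gives_all_invalid(self, rng):
        img = SensorImage(rng.normal(0, 1, (32, 32)), ("B",))
        H = np.eye(3)
        H[0, 2] = 10_000.0  # shifts the AoI far outside the source
        model = RegistrationModel([((0, 0), (0, 0))] * 4, H, 0.0)
        out = warp_to_aoi(img, model, (32, 32))
        assert np.isnan(out.pixels).all()


class TestUpscaleThermal:
    def test_identity_scale(self):
        img = SensorImage(np.arange(12.0).reshape(3, 4), ("T",))
        out = upscale_thermal(img, (3, 4))
        assert np.array_equal(out.pixels, img.pixels)

    def test_constant_preserved(self):
        img = SensorImage(np.full((20, 30), 25.0), ("T",))
        out = upscale_thermal(img, (120, 180))
        assert np.allclose(out.pixels, 25.0)

    def test_linear_ramp_stays_linear(self):
        ramp = np.outer(np.linspace(10, 30, 40), np.ones(50))
        out = upscale_thermal(SensorImage(ramp, ("T",)), (80, 100)).pixels[:, :, 0]
        expected = np.outer(np.linspace(10, 30, 80), np.ones(100))
        assert np.allclose(out, expected, atol=1e-6)

    def test_mean_preserved_for_integer_factor(self, rng):
        img = SensorImage(20.0 + rng.normal(0, 2, (40, 50)), ("T",))
        out = upscale_thermal(img, (240, 300))
        assert abs(out.pixels.mean() - img.pixels.mean()) < 1e-3 * abs(
            img.pixels.mean()
        )

    def test_downscale_rejected(self):
        img = SensorImage(np.zeros((40, 50)), ("T",))
        with pytest.raises(InvalidSpecError):
            upscale_thermal(img, (20, 25))


class TestPipelineRegistration:
    def test_all_markers_detected_in_every_sensor(self, pipeline_c4, bundle_c4):
        for sensor, markers in pipeline_c4["reg"].markers.items():
            assert len(markers) == len(bundle_c4.marker_positions_aoi)

    def test_markers_reregistered_within_one_pixel(self, pipeline_c4, bundle_c4):
        """Composed pipeline property: detected markers, mapped through the
        fitted homography, land within 1 px of the AoI-frame ground truth."""
        truth = np.asarray(bundle_c4.marker_positions_aoi)
        for sensor, model in pipeline_c4["reg"].models.items():
            detected = np.array(
                [m.center for m in pipeline_c4["reg"].markers[sensor]]
            )
            projected = model.transform(detected)
            # match each projection to its nearest true marker
            d = np.sqrt(
                ((projected[:, None, :] - truth[None, :, :]) ** 2).sum(axis=2)
            ).min(axis=1)
            assert d.max() <= 1.0, f"{sensor}: worst marker off by {d.max():.2f} px"

    def test_fitted_homography_close_to_truth(self, pipeline_c4, bundle_c4):
        for sensor, model in pipeline_c4["reg"].models.items():
            if sensor == "IR":
                continue  # fitted in the upscaled frame; checked via markers
            Ht = bundle_c4.true_H[sensor]
            corners = np.array([[0.0, 0.0], [0.0, 400.0], [400.0, 0.0],
                                [400.0, 400.0]])
            true_model = RegistrationModel([((0, 0), (0, 0))] * 4, Ht, 0.0)
            err = np.abs(model.transform(corners) - true_model.transform(corners))
            assert err.max() < 1.0
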