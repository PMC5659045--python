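import numpy as np
import pytest

from retinascreen.core_io import FundusImage
from retinascreen.optic_disc import (DegeneratePointSet, candidate_arcade_fits,
                                     choose_arcade_fit, detect_od,
                                     fit_parabola, segment_od,
                                     window_response)


class TestFitParabola:
    def test_exact_recovery_from_noiseless_points(self):
        k = np.arange(5.0)
        l = 2 * k ** 2 + 3 * k + 1
        p = fit_parabola(np.column_stack([l, k]), "y_of_x")
        assert (p.a0, p.a1, p.a2) == pytest.approx((2.0, 3.0, 1.0), abs=1e-9)
        assert p.residual == pytest.approx(0.0, abs=1e-12)
        assert p.vertex[1] == pytest.approx(-3 / 4)

    def test_collinear_points_rejected(self):
        k = np.arange(10.0)
        l = 2 * k + 1
        with pytest.raises(DegeneratePointSet):
            fit_parabola(np.column_stack([l, k]), "y_of_x")

    def test_matches_normal_equations_oracle(self, rng):
        k = rng.uniform(-3, 3, 100)
        l = 0.7 * k ** 2 - 1.2 * k + 0.3 + rng.normal(0, 0.05, 100)
        p = fit_parabola(np.column_stack([l, k]), "y_of_x")
        A = np.column_stack([k ** 2, k, np.ones_like(k)])
        ref = np.linalg.solve(A.T @ A, A.T @ l)
        assert (p.a0, p.a1, p.a2) == pytest.approx(tuple(ref), abs=1e-9)

    def test_noisy_quadratic_coefficient_recovered(self, rng):
        k = rng.uniform(-2, 2, 200)
        l = k ** 2 + rng.normal(0, 0.1, 200)
        p = fit_parabola(np.column_stack([l, k]), "y_of_x")
        assert p.a0 == pytest.approx(1.0, abs=0.02)

    def test_too_few_points(self):
        with pytest.raises(DegeneratePointSet):
            fit_parabola(np.array([[0.0, 0.0], [1.0, 1.0]]), "y_of_x")


class TestChooseArcadeFit:
    def test_left_opening_arcade_prefers_x_of_y(self):
        t = np.linspace(-60, 60, 200)
        rows = 100 + t
        cols = 30 + 0.02 * t ** 2
        p = choose_arcade_fit(np.column_stack([rows, cols]))
        assert p.orientation == "x_of_y"
        assert p.vertex == pytest.approx((100, 30), abs=1.0)

    def test_downward_u_prefers_y_of_x(self):
        t = np.linspace(-60, 60, 200)
        cols = 100 + t
        rows = 30 + 0.02 * t ** 2
        p = choose_arcade_fit(np.column_stack([rows, cols]))
        assert p.orientation == "y_of_x"

    def test_straight_skeleton_propagates_error(self):
        pts = np.column_stack([np.arange(50.0), np.arange(50.0)])
        with pytest.raises(DegeneratePointSet):
            choose_arcade_fit(pts)

    def test_candidates_clamped_to_image(self):
        t = np.linspace(0, 60, 100)           # half an arcade only
        rows = 100 + t
        cols = 30 + 0.02 * t ** 2
        fits = candidate_arcade_fits(np.column_stack([rows, cols]), (120, 120))
        for p in fits:
            assert 0 <= p.vertex[0] <= 119 and 0 <= p.vertex[1] <= 119


def _flat_image(value=120, shape=(200, 200)):
    rgb = np.full(shape + (3,), value, dtype=np.uint8)
    return FundusImage(rgb=rgb, field_of_view_mask=np.ones(shape, bool))


class TestWindowResponse:
    def test_uniform_image_gives_zero(self):
        img = _flat_image()
        assert window_response(img, (100, 100), 40) == pytest.approx(0.0)

    def test_variance_doubling_doubles_response(self, rng):
        shape = (200, 200)
        base = rng.normal(0, 10, shape)
        rgb1 = np.clip(120 + base[..., None] * [1, 1, 1], 0, 255).astype(np.uint8)
        rgb2 = np.clip(120 + np.sqrt(2) * base[..., None] * [1, 1, 1], 0, 255).astype(np.uint8)
        img1 = FundusImage(rgb=rgb1, field_of_view_mask=np.ones(shape, bool))
        img2 = FundusImage(rgb=rgb2, field_of_view_mask=np.ones(shape, bool))
        r1 = window_response(img1, (100, 100), 60)
        r2 = window_response(img2, (100, 100), 60)
        # doubling the intensity variance at (nearly) fixed mean doubles R
        assert r2 / r1 == pytest.approx(2.0, rel=0.15)

    def test_od_beats_flat_background(self, phantom1):
        from scipy import ndimage
        img, gt = phantom1
        d = img.shape[1] / 6
        r_od = window_response(img, gt.od_center, d)
        # the most structure-free in-FOV point: maximal distance from every
        # ground-truth structure
        union = np.zeros(img.shape, bool)
        for m in gt.masks.values():
            union |= m.data
        union |= ~img.field_of_view_mask
        dist = ndimage.distance_transform_edt(~union)
        flat = np.unravel_index(np.argmax(dist), dist.shape)
        r_bg = window_response(img, (float(flat[0]), float(flat[1])), d)
        assert r_od > r_bg

    def test_window_outside_image_rejected(self):
        img = _flat_image()
        with pytest.raises(ValueError):
            window_response(img, (5, 5), 40)


class TestSegmentOD:
    def test_bright_disc_radius_recovered(self):
        shape = (300, 300)
        rr, cc = np.mgrid[0:300, 0:300]
        disc = np.hypot(rr - 150, cc - 150) <= 40
        g = np.where(disc, 220, 90).astype(np.uint8)
        rgb = np.stack([np.full(shape, 140, np.uint8), g,
                        np.full(shape, 40, np.uint8)], axis=2)
        img = FundusImage(rgb=rgb, field_of_view_mask=np.ones(shape, bool))
        from retinascreen.core_io import PipelineConfig
        cfg = PipelineConfig()
        # radius window (300/14, 300/10) ~ (21, 30): widen via config for
        # this synthetic disc
        cfg.od_radius_frac_min = 30 / 300
        cfg.od_radius_frac_max = 50 / 300
        res = segment_od(img, (150, 150), cfg)
        assert res.radius == pytest.approx(40, abs=2)
        assert res.center == pytest.approx((150, 150), abs=3)

    def test_no_structure_falls_back_low_confidence(self):
        img = _flat_image()
        res = segment_od(img, (100, 100))
        assert res.low_confidence
        assert res.mask.data.any()

    def test_phantom_od_detected_despite_vessel_crossings(self, phantom1,
                                                          vessels1, cfg):
        img, gt = phantom1
        res = detect_od(img, vessels1.skeleton, cfg)
        err = np.hypot(res.center[0] - gt.od_center[0],
                       res.center[1] - gt.od_center[1])
        assert err <= gt.od_radius
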