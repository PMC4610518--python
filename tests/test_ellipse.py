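"""Mirror completion, conic least-squares ellipse fitting, and pixel
measurements (tangent level, area)."""

import numpy as np
import pytest
from skimage.measure import EllipseModel

from vesselcam.ellipse import (
    EllipseParams,
    ellipse_from_conic,
    fit_ellipse,
    measure,
    mirror_segment,
    sample_ellipse,
)

from conftest import sample_ellipse_points

METHODS = ("ls_conic", "direct", "taubin")


class TestMirrorSegment:
    def arc(self):
        # symmetric about col 50 so the reflection-symmetry check is exact
        cols = np.arange(21, 80, dtype=float)
        rows = 60.0 + 0.01 * (cols - 50.0) ** 2
        return cols, rows

    def test_doubles_the_point_count(self):
        cols, rows = self.arc()
        pts = mirror_segment(cols, rows, 50.0, (160, 120))
        assert pts.shape == (2 * len(cols), 2)

    def test_copy_bottom_sits_at_requested_offset(self):
        cols, rows = self.arc()
        pts = mirror_segment(cols, rows, 50.0, (160, 120))
        copy = pts[len(cols):]
        assert copy[:, 1].max() == pytest.approx(160 - 1 - 50)

    def test_column_extent_preserved(self):
        cols, rows = self.arc()
        pts = mirror_segment(cols, rows, 50.0, (160, 120))
        copy = pts[len(cols):]
        assert copy[:, 0].min() == pytest.approx(cols.min())
        assert copy[:, 0].max() == pytest.approx(cols.max())

    def test_symmetric_about_horizontal_midline(self):
        """For a symmetric arc the combined set is mirror-symmetric about
        the horizontal line midway between arc top and copy bottom."""
        cols, rows = self.arc()
        pts = mirror_segment(cols, rows, 50.0, (160, 120))
        mid = (rows.min() + pts[len(cols):, 1].max()) / 2.0
        reflected = np.column_stack([pts[:, 0], 2 * mid - pts[:, 1]])
        # the reflected set equals the original set (as sets of points)
        order_a = np.lexsort((pts[:, 1].round(9), pts[:, 0].round(9)))
        order_b = np.lexsort((reflected[:, 1].round(9), reflected[:, 0].round(9)))
        np.testing.assert_allclose(pts[order_a], reflected[order_b], atol=1e-9)

    def test_out_of_bounds_offset_rejected(self):
        cols, rows = self.arc()
        with pytest.raises(ValueError):
            mirror_segment(cols, rows, 200.0, (160, 120))
        with pytest.raises(ValueError):
            mirror_segment(cols, rows, -1.0, (160, 120))

    def test_empty_arc_rejected(self):
        with pytest.raises(ValueError):
            mirror_segment(np.array([]), np.array([]), 50.0, (160, 120))


class TestFitEllipse:
    @pytest.mark.parametrize("method", METHODS)
    def test_exact_circle_recovered(self, method):
        pts = sample_ellipse_points(60, 80, 10, 10, 0.0, n=8)
        e = fit_ellipse(pts, method)
        assert e.center[0] == pytest.approx(60, abs=1e-6)
        assert e.center[1] == pytest.approx(80, abs=1e-6)
        assert e.semi_major == pytest.approx(10, abs=1e-6)
        assert e.semi_minor == pytest.approx(10, abs=1e-6)

    @pytest.mark.parametrize("method", METHODS)
    def test_exact_tilted_ellipse_recovered(self, method):
        pts = sample_ellipse_points(60, 80, 30, 12, 0.4)
        e = fit_ellipse(pts, method)
        assert e.center == pytest.approx((60, 80), abs=1e-6)
        assert e.semi_major == pytest.approx(30, abs=1e-6)
        assert e.semi_minor == pytest.approx(12, abs=1e-6)
        assert e.tilt == pytest.approx(0.4, abs=1e-6)

    def test_collinear_points_give_no_ellipse(self):
        x = np.arange(5, dtype=float)
        assert fit_ellipse(np.column_stack([x, 2 * x + 1])) is None

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_ellipse(np.zeros((4, 2)))

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            fit_ellipse(np.zeros((6, 2)), method="ransac")

    def test_methods_agree_on_well_conditioned_noisy_input(self):
        rng = np.random.default_rng(1)
        pts = sample_ellipse_points(60, 80, 40, 25, 0.3, n=60)
        pts = pts + rng.normal(0, 0.1, pts.shape)
        fits = [fit_ellipse(pts, m) for m in METHODS]
        for e in fits[1:]:
            assert e.semi_major == pytest.approx(fits[0].semi_major, rel=0.01)
            assert e.semi_minor == pytest.approx(fits[0].semi_minor, rel=0.01)
            assert e.center == pytest.approx(fits[0].center, rel=0.01)

    @pytest.mark.parametrize("method", METHODS)
    def test_parameter_recovery_under_half_pixel_jitter(self, method):
        """Center and axes recovered within 2% under sigma = 0.5 px."""
        rng = np.random.default_rng(7)
        pts = sample_ellipse_points(60, 90, 45, 30, 0.25, n=80)
        pts = pts + rng.normal(0, 0.5, pts.shape)
        e = fit_ellipse(pts, method)
        assert e.semi_major == pytest.approx(45, rel=0.02)
        assert e.semi_minor == pytest.approx(30, rel=0.02)
        assert e.center[0] == pytest.approx(60, abs=45 * 0.02)
        assert e.center[1] == pytest.approx(90, abs=45 * 0.02)

    def test_translation_and_rotation_equivariance(self):
        pts = sample_ellipse_points(0, 0, 20, 9, 0.1, n=24)
        base = fit_ellipse(pts)
        # translate
        shifted = fit_ellipse(pts + [13.0, -7.0])
        assert shifted.center == pytest.approx(
            (base.center[0] + 13, base.center[1] - 7), abs=1e-6)
        assert shifted.semi_major == pytest.approx(base.semi_major, abs=1e-6)
        # rotate by 0.3 rad about the origin
        ang = 0.3
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        rotated = fit_ellipse(pts @ R.T)
        assert rotated.semi_major == pytest.approx(base.semi_major, abs=1e-6)
        assert rotated.semi_minor == pytest.approx(base.semi_minor, abs=1e-6)
        assert rotated.tilt == pytest.approx(base.tilt + ang, abs=1e-6)

    def test_agrees_with_independent_reference_fitter(self):
        """Cross-check against scikit-image's ellipse estimator."""
        rng = np.random.default_rng(3)
        pts = sample_ellipse_points(55, 75, 38, 22, 0.5, n=50)
        pts = pts + rng.normal(0, 0.3, pts.shape)
        ours = fit_ellipse(pts, "direct")
        ref = EllipseModel.from_estimate(pts)
        assert ref
        _, _, ra, rb, _ = ref.params
        ref_major, ref_minor = max(ra, rb), min(ra, rb)
        assert ours.semi_major == pytest.approx(ref_major, rel=0.01)
        assert ours.semi_minor == pytest.approx(ref_minor, rel=0.01)


class TestMeasure:
    def make(self, cx, cy, a, b, tilt):
        pts = sample_ellipse_points(cx, cy, a, b, tilt, n=32)
        return fit_ellipse(pts)

    def test_axis_aligned_geometry(self):
        e = self.make(60, 100, 30, 20, 0.0)
        m = measure(e, (160, 120))
        assert m.level_px == pytest.approx(160 - 80, abs=1e-9)  # y_top = 80
        assert m.area_px2 == pytest.approx(np.pi * 30 * 20, rel=1e-9)

    def test_circle_area(self):
        e = self.make(60, 80, 15, 15, 0.0)
        assert measure(e, (160, 120)).area_px2 == pytest.approx(np.pi * 225, rel=1e-9)

    def test_tilted_vertical_extent_matches_parametric_oracle(self):
        e = self.make(60, 80, 30, 12, 0.4)
        th = np.linspace(0, 2 * np.pi, 1_000_001)
        ys = sample_ellipse(e, theta=th)[:, 1]
        brute = (ys.max() - ys.min()) / 2.0
        assert e.vertical_half_extent() == pytest.approx(brute, abs=1e-3)

    def test_area_invariant_under_tilt(self):
        areas = [measure(self.make(60, 80, 30, 12, t), (160, 120)).area_px2
                 for t in (0.0, 0.3, 0.9, 1.4)]
        np.testing.assert_allclose(areas, areas[0], rtol=1e-9)

    def test_invalid_conic_rejected_by_params_type(self):
        with pytest.raises(ValueError):
            EllipseParams(conic=(1, 0, -1, 0, 0, -1), center=(0, 0),
                          semi_major=1.0, semi_minor=1.0, tilt=0.0)

    def test_conic_roundtrip(self):
        e = self.make(40, 70, 25, 10, -0.7)
        back = ellipse_from_conic(e.conic)
        assert back.center == pytest.approx(e.center, abs=1e-9)
        assert back.semi_major == pytest.approx(e.semi_major, abs=1e-9)
        assert back.tilt == pytest.approx(e.tilt, abs=1e-9)
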