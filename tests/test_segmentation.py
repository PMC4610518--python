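"""Segmentation: disk pre-blur, Sobel gradient mask, morphological
refinement, Hessian vesselness, and the noise-degradation comparison."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from vesselcam.segmentation import (
    degradation_study,
    preblur,
    refine_mask,
    sobel_mask,
    vesselness,
    vesselness_mask,
)


def thin_curve_image(rows=80, cols=100, background=0.1, value=0.9):
    """Bright 2-px quadratic curve on a uniform dark background."""
    image = np.full((rows, cols), background)
    x = np.arange(cols)
    y = np.rint(0.004 * (x - cols / 2) ** 2 + rows / 3).astype(int)
    pts = []
    for xi, yi in zip(x, y):
        for r in (yi, yi + 1):
            if 0 <= r < rows:
                image[r, xi] = value
                pts.append((r, xi))
    return image, np.array(pts)


class TestPreblur:
    def test_constant_image_unchanged(self):
        image = np.full((20, 30), 0.4)
        np.testing.assert_allclose(preblur(image, 3), image)

    def test_impulse_response_is_disk_plateau(self):
        image = np.zeros((21, 21))
        image[10, 10] = 1.0
        out = preblur(image, 3)
        from skimage.morphology import disk

        kernel = disk(3).astype(float)
        kernel /= kernel.sum()
        inside = out[10 - 3:10 + 4, 10 - 3:10 + 4]
        np.testing.assert_allclose(inside, kernel, atol=1e-12)

    def test_blur_reduces_high_frequency_energy(self, scene40):
        image, _ = scene40
        rng = np.random.default_rng(0)
        noisy = np.clip(image + rng.normal(0, 0.1, image.shape), 0, 1)

        def high_band_power(img):
            f = np.abs(np.fft.fftshift(np.fft.fft2(img))) ** 2
            r, c = img.shape
            yy, xx = np.mgrid[0:r, 0:c]
            dist = np.hypot(yy - r / 2, xx - c / 2)
            return f[dist > min(r, c) / 4].sum()

        assert high_band_power(preblur(noisy, 3)) < 0.25 * high_band_power(noisy)

    def test_invalid_radius_rejected(self):
        with pytest.raises(ValueError):
            preblur(np.zeros((5, 5)), 0)


class TestSobelMask:
    def test_constant_image_gives_empty_mask(self):
        assert not sobel_mask(np.full((30, 30), 0.7), 0.005).any()

    def test_step_edge_localized(self):
        image = np.zeros((40, 40))
        image[:, 20:] = 1.0
        mask = sobel_mask(image, 0.1)
        cols = np.flatnonzero(mask.any(axis=0))
        assert set(cols) <= {19, 20}

    def test_arc_pixels_covered_at_paper_threshold(self, scene40):
        """The rendered contact line is essentially fully captured by the
        documented low threshold."""
        image, truth = scene40
        mask = sobel_mask(image, 0.005)
        covered = mask[truth.arc_points[:, 0], truth.arc_points[:, 1]].mean()
        assert covered >= 0.90

    def test_invariant_under_intensity_inversion(self, scene40):
        image, _ = scene40
        np.testing.assert_array_equal(sobel_mask(image, 0.01),
                                      sobel_mask(1.0 - image, 0.01))

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            sobel_mask(np.zeros((5, 5)), -0.1)


class TestRefineMask:
    def test_gap_smaller_than_line_length_bridged(self):
        mask = np.zeros((9, 20), dtype=bool)
        mask[4, 2:8] = True
        mask[4, 9:15] = True  # 1-px gap at column 8
        out = refine_mask(mask, line_length=3)
        _, n = ndi.label(out)
        assert n == 1

    def test_empty_mask_stays_empty(self):
        assert not refine_mask(np.zeros((10, 10), dtype=bool), 3).any()

    def test_enclosed_hole_filled(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:15, 5:15] = True
        mask[8:11, 8:11] = False
        out = refine_mask(mask, 3)
        # background component count drops from 2 (outside + hole) to 1
        _, n_before = ndi.label(~mask)
        _, n_after = ndi.label(~out)
        assert n_before == 2 and n_after == 1

    def test_component_count_does_not_increase(self, scene40):
        image, _ = scene40
        mask = sobel_mask(preblur(image, 3), 0.005)
        _, n_in = ndi.label(mask)
        _, n_out = ndi.label(refine_mask(mask, 3))
        assert n_out <= n_in

    def test_near_idempotent_on_fixture_scene(self, scene40):
        image, _ = scene40
        once = refine_mask(sobel_mask(preblur(image, 3), 0.005), 3)
        twice = refine_mask(once, 3)
        assert (once ^ twice).mean() < 0.01


class TestVesselness:
    def test_constant_image_gives_zero_response(self):
        assert vesselness(np.full((30, 30), 0.5)).max() == 0.0

    def test_bright_curve_dominates_background(self):
        image, pts = thin_curve_image()
        resp = vesselness(image)
        on_curve = resp[pts[:, 0], pts[:, 1]]
        off = np.ones_like(resp, dtype=bool)
        off[pts[:, 0], pts[:, 1]] = False
        off &= ndi.binary_dilation(~off, iterations=4) == 0  # away from curve
        assert np.median(on_curve) >= 10 * max(resp[off].mean(), 1e-12)

    def test_quarter_turn_equivariance(self):
        """Rotating the image a quarter turn rotates the response; compared
        away from the borders, where the Hessian estimate is unaffected by
        padding."""
        image, _ = thin_curve_image(rows=90, cols=90)
        a = np.rot90(vesselness(image))[5:-5, 5:-5]
        b = vesselness(np.rot90(image))[5:-5, 5:-5]
        np.testing.assert_allclose(a, b, atol=0.05)

    def test_oblique_rotation_preserves_detectability(self):
        """An obliquely rotated curve still dominates the background by an
        order of magnitude (raster jagging lowers the absolute response of
        a 2-px curve, but not its separability)."""
        from skimage.transform import rotate

        image, pts = thin_curve_image(rows=90, cols=90, background=0.1)
        rot = rotate(image, 30, mode="edge")
        resp = vesselness(rot)
        curve = np.zeros_like(image, dtype=bool)
        curve[pts[:, 0], pts[:, 1]] = True
        curve_rot = ndi.binary_erosion(
            rotate(curve.astype(float), 30, order=0) > 0.5)
        off = ~ndi.binary_dilation(curve_rot, iterations=5)
        off[:5] = off[-5:] = False
        off[:, :5] = off[:, -5:] = False
        assert np.median(resp[curve_rot]) >= 10 * max(resp[off].mean(), 1e-12)

    def test_empty_or_invalid_scales_rejected(self):
        with pytest.raises(ValueError):
            vesselness(np.zeros((10, 10)), scales=())
        with pytest.raises(ValueError):
            vesselness(np.zeros((10, 10)), scales=(0.0,))


@pytest.fixture(scope="module")
def degradation_report(scene40):
    image, truth = scene40
    return degradation_study(image, truth, [0.0, 0.1, 0.2], seed=11)


class TestDegradationStudy:
    @pytest.fixture
    def report(self, degradation_report):
        return degradation_report

    def test_report_shape(self, report):
        assert len(report) == 3 * 2
        assert set(report["filter"]) == {"sobel", "vesselness"}

    def test_noise_free_recall_high_for_both_filters(self, report):
        clean = report[report["density"] == 0.0]
        assert (clean["arc_recall"] >= 0.9).all()

    def test_vesselness_outlasts_sobel(self, report):
        """The Hessian tube filter keeps the arc detectable at a noise
        density where the fixed-threshold Sobel route has already lost it."""
        piv = report.pivot(index="density", columns="filter", values="arc_recall")
        gap = piv.index[(piv["sobel"] < 0.5) & (piv["vesselness"] >= 0.5)]
        assert len(gap) > 0

    def test_requires_scene_truth(self, scene40):
        image, _ = scene40
        with pytest.raises(ValueError):
            degradation_study(image, None, [0.0])


def test_vesselness_mask_on_clean_scene_is_sparse_and_covers_arc(scene40):
    image, truth = scene40
    mask = vesselness_mask(image)
    assert mask.mean() < 0.1
    assert mask[truth.arc_points[:, 0], truth.arc_points[:, 1]].mean() > 0.8
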