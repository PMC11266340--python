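"""Preprocessing, ROI machinery, CNR profiles and resolution fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from muracam import (
    assess_lateral,
    cnr,
    fit_cnr_profile,
    preprocess,
    roi_diameter,
    sample_rois,
    select_signal_roi,
)
from muracam.assess import FWHM_PER_SIGMA, disc_kernel


class TestPreprocess:
    def test_constant_image_unchanged(self):
        img = np.full((64, 64), 3.5)
        assert np.allclose(preprocess(img).pixels, img)

    def test_hot_pixel_removed_before_smoothing(self):
        rng = np.random.default_rng(0)
        img = rng.normal(100.0, 1.0, (64, 64)).clip(0)
        img[30, 30] = 1e6
        out = preprocess(img).pixels
        # an untreated hot pixel would survive sigma=1 smoothing at ~1.6e5
        assert out[30, 30] < 200.0
        assert out.min() >= 0

    def test_metadata_flagged(self, noisy_30):
        out = preprocess(noisy_30)
        assert out.meta["preprocessed"] is True


class TestRoiDiameter:
    def test_pinhole_conversion_at_30mm(self, geometry):
        # FOV 21.12 mm over 256 px -> 0.0825 mm/px; 0.65 / 0.0825 -> 8
        assert roi_diameter(geometry, 30.0, "mlem") == 8

    def test_mura_uses_reconstruction_window(self, geometry):
        # FOV 7.44 mm over 150 px -> 0.0496 mm/px; 0.65 / 0.0496 -> 13
        assert roi_diameter(geometry, 30.0, "mura") == 13

    def test_single_pixel_source(self, geometry):
        d = roi_diameter(geometry, 30.0, "mlem",
                         source_fwhm_mm=0.0825)
        assert d == 1

    def test_degenerate_clamped_with_warning(self, geometry):
        with pytest.warns(UserWarning, match="clamping"):
            d = roi_diameter(geometry, 30.0, "mlem", source_fwhm_mm=0.001)
        assert d == 1

    def test_nonpositive_distance_rejected(self, geometry):
        with pytest.raises(ValueError):
            roi_diameter(geometry, -3.0, "mlem")


class TestSampleRois:
    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(side=st.integers(4, 12), diameter=st.integers(1, 6),
           seed=st.integers(0, 100))
    def test_matches_brute_force_enumeration(self, side, diameter, seed):
        diameter = min(diameter, side)
        rng = np.random.default_rng(seed)
        img = rng.random((side, side))
        table = sample_rois(img, diameter)
        disc = disc_kernel(diameter)
        m = side - diameter + 1
        assert table.means.shape == (m, m)
        for i in range(m):
            for j in range(m):
                vals = img[i:i + diameter, j:j + diameter][disc]
                assert table.means[i, j] == pytest.approx(vals.mean())
                assert table.stds[i, j] == pytest.approx(vals.std(), abs=1e-9)

    def test_placement_counts_match_printed_ranges(self):
        rng = np.random.default_rng(1)
        # MURA-decoded slice at 30 mm: 150 px, ROI 13 px
        t = sample_rois(rng.random((150, 150)), 13)
        assert t.n_positions == (150 - 13 + 1) ** 2 == 19044
        assert 14000 <= t.n_positions <= 31000
        # full-detector MLEM slice: 256 px, ROI 8 px
        t = sample_rois(rng.random((256, 256)), 8)
        assert t.n_positions == (256 - 8 + 1) ** 2 == 62001
        assert 54000 <= t.n_positions <= 65000

    def test_diameter_equal_to_side_gives_single_roi(self):
        img = np.arange(25.0).reshape(5, 5)
        t = sample_rois(img, 5)
        assert t.n_positions == 1

    def test_oversized_diameter_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            sample_rois(np.zeros((5, 5)), 6)


class TestSignalSelection:
    def _blob(self, side, row, col, amp=10.0):
        # peak plus a faint 2D ramp so the best ROI placement is unique
        img = np.add.outer(np.linspace(0.0, 0.01, side),
                           np.linspace(0.0, 0.001, side))
        img[row, col] = amp
        return img

    def test_central_source_selected(self):
        img = self._blob(60, 30, 30)
        t = sample_rois(img, 5)
        sel = select_signal_roi(t)
        ci, cj = t.center(*sel.position)
        assert abs(ci - 30) <= 2.5 and abs(cj - 30) <= 2.5

    def test_border_ghost_ignored(self):
        """A brighter spot near the border must not displace the signal."""
        img = self._blob(60, 30, 30, amp=10.0) + self._blob(60, 3, 3, amp=50.0)
        t = sample_rois(img, 5)
        sel = select_signal_roi(t)
        ci, cj = t.center(*sel.position)
        assert abs(ci - 30) <= 2.5 and abs(cj - 30) <= 2.5

    def test_equal_maxima_tie_break_warns_row_major(self):
        img = np.zeros((40, 40))
        img[15, 15] = img[24, 24] = 5.0
        t = sample_rois(img, 3)
        with pytest.warns(UserWarning, match="equal signal maxima"):
            sel = select_signal_roi(t)
        assert sel.position[0] <= 23

    def test_overlapping_rois_excluded_from_background(self):
        img = self._blob(40, 20, 20)
        t = sample_rois(img, 5)
        sel = select_signal_roi(t)
        pi, pj = sel.position
        assert not sel.background[pi, pj]
        assert not sel.background[pi + 4, pj]   # center distance 4 < d=5
        assert sel.background[pi + 5, pj]       # center distance d


class TestCnr:
    def test_zero_contrast(self):
        assert cnr(4.0, [4.0, 4.0], [1.0, 1.0]) == 0.0

    def test_arithmetic(self):
        assert cnr(10.0, [4.0], [2.0]) == pytest.approx(3.0)
        # mean of background means / stds
        assert cnr(10.0, [2.0, 6.0], [1.0, 3.0]) == pytest.approx(3.0)

    def test_degenerate_background_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            cnr(10.0, [4.0], [0.0])
        with pytest.raises(ValueError, match="background"):
            cnr(10.0, [], [])

    def test_affine_intensity_invariance(self):
        """CNR depends only on relative intensities."""
        rng = np.random.default_rng(8)
        img = rng.random((50, 50))
        img[25, 25] = 5.0

        def image_cnr(x):
            t = sample_rois(x, 5)
            sel = select_signal_roi(t)
            return cnr(t.means[sel.position], t.means[sel.background],
                       t.stds[sel.background])

        assert image_cnr(3.0 * img + 11.0) == pytest.approx(image_cnr(img))


class TestFitCnrProfile:
    def test_exact_profile_recovered(self):
        z = np.arange(15.0, 45.5, 0.5)
        alpha, beta, gamma, delta = 1.0, 10.0, 30.0, 2.0
        y = alpha + (beta - alpha) * np.exp(-(z - gamma) ** 2 / (2 * delta ** 2))
        prof = fit_cnr_profile(z, y)
        assert prof.params == pytest.approx((alpha, beta, gamma, delta),
                                            abs=1e-6)
        assert prof.fwhm_mm == pytest.approx(4.71, abs=0.01)

    def test_unit_sigma_gives_fwhm_2_35(self):
        z = np.linspace(25, 35, 41)
        y = 5 * np.exp(-(z - 30) ** 2 / 2.0)
        prof = fit_cnr_profile(z, y)
        assert prof.fwhm_mm == pytest.approx(2.35, abs=0.01)
        assert round(FWHM_PER_SIGMA, 2) == 2.35

    def test_peak_location_robust_to_noise(self):
        """Monte-Carlo: 5% amplitude noise on 60 samples keeps the fitted
        peak within half a fine-grid step of the truth."""
        rng = np.random.default_rng(0)
        z = np.linspace(15, 45, 60)
        truth = 1 + 9 * np.exp(-(z - 30) ** 2 / (2 * 2.0 ** 2))
        errors = []
        for _ in range(100):
            y = truth + rng.normal(0.0, 0.05 * 9, z.size)
            errors.append(abs(fit_cnr_profile(z, y).peak_z_mm - 30.0))
        assert max(errors) < 0.5

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            fit_cnr_profile([1, 2, 3], [0, 1, 0])


class TestAssessLateral:
    def test_known_gaussian_blob(self):
        side, sigma = 100, 3.0
        yy, xx = np.mgrid[:side, :side]
        img = np.exp(-((yy - 50) ** 2 + (xx - 50) ** 2) / (2 * sigma ** 2))
        fov_mm = 10.0
        fwhm = assess_lateral(img, fov_mm)
        expected = FWHM_PER_SIGMA * sigma * fov_mm / side
        assert fwhm == pytest.approx(expected, rel=0.02)

    def test_flat_image_fails(self):
        with pytest.raises(RuntimeError, match="flat"):
            assess_lateral(np.ones((50, 50)), 10.0)
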