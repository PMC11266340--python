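"""3D-MLEM: normalization maps, update properties, depth recovery."""

import numpy as np
import pytest

from muracam import normalization_map, rasterize_psf, reconstruct_3d
from muracam.mlem import initialize_state, mlem_iterate


class TestNormalizationMap:
    def test_impulse_psf_gives_unit_sensitivity(self):
        imp = np.zeros((64, 64))
        imp[31, 31] = 1.0  # 'same'-convolution center for even sides
        assert np.allclose(normalization_map(imp), 1.0)

    def test_center_equals_psf_sum_when_support_fits(self, geometry, pattern):
        h = rasterize_psf(geometry, pattern, 50.0, mode="THT").normalized()
        n = normalization_map(h)
        c = geometry.detector_pixels // 2
        assert n[c, c] == pytest.approx(1.0, abs=1e-9)

    def test_corner_below_center(self, geometry, pattern):
        h = rasterize_psf(geometry, pattern, 50.0, mode="THT").normalized()
        n = normalization_map(h)
        c = geometry.detector_pixels // 2
        assert n[0, 0] < n[c, c]

    def test_all_zero_psf_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            normalization_map(np.zeros((16, 16)))


class TestUpdateProperties:
    def test_fixed_point_when_forward_matches_data(self, geometry, pattern):
        """If the forward projection reproduces p exactly, the bracketed
        ratio back-projects to n_z and slices stay put."""
        state = initialize_state(np.ones((256, 256)), geometry, [30.0],
                                 t=0.0, pattern=pattern)
        rng = np.random.default_rng(0)
        state.slices[0] = rng.random((256, 256))
        p = state.forward()[1]
        new = mlem_iterate(state, p)
        rel = np.abs(new.slices[0] - state.slices[0]) / (state.slices[0] + 1e-12)
        assert rel.max() < 1e-6

    def test_single_slice_log_likelihood_non_decreasing(self, geometry,
                                                        pattern):
        """Classic MLEM monotonicity in the noiseless single-slice case."""
        g0 = geometry
        p_img = rasterize_psf(g0, pattern, 30.0, mode="THT").normalized() * 1e5
        stack = reconstruct_3d(p_img, g0, [30.0], iterations=40, t=0.0,
                               pattern=pattern)
        ll = stack.meta["log_likelihood"]
        assert len(ll) == 40
        for a, b in zip(ll, ll[1:]):
            assert b >= a - 1e-8 * abs(a)

    def test_slices_stay_non_negative(self, geometry, noisy_30, pattern):
        stack = reconstruct_3d(noisy_30, geometry, [25.0, 30.0, 35.0],
                               iterations=8, pattern=pattern)
        for s in stack.slices:
            assert np.all(s.pixels >= 0)
            assert np.all(np.isfinite(s.pixels))

    def test_zero_iterations_returns_uniform_init(self, geometry, noisy_30,
                                                  pattern):
        stack = reconstruct_3d(noisy_30, geometry, [25.0, 30.0],
                               iterations=0, pattern=pattern)
        total = noisy_30.pixels.sum()
        for s in stack.slices:
            assert np.allclose(s.pixels, total / (2 * 256 * 256))

    def test_count_consistency_without_transmission(self, geometry, pattern):
        """n_z makes the converged forward projection carry the detector
        counts (noiseless, shadow fully on the detector, t = 0)."""
        g0 = geometry
        from muracam import SourceScene, simulate_detector_image
        img = simulate_detector_image(
            SourceScene(sources=[(0, 0, 50.0, 1e6)]),
            type(g0)(transmission_t=0.0), noisy=False, pattern=pattern)
        state = initialize_state(img.pixels, g0, [50.0], t=0.0,
                                 pattern=pattern)
        for _ in range(40):
            state = mlem_iterate(state, img.pixels)
        total_fwd = state.forward()[1].sum()
        assert total_fwd == pytest.approx(img.pixels.sum(), rel=0.01)


class TestReconstruct3d:
    def test_depth_recovery_on_noiseless_source(self, geometry, noiseless_30,
                                                pattern):
        stack = reconstruct_3d(noiseless_30, geometry,
                               np.arange(15.0, 46.0, 5.0), iterations=40,
                               pattern=pattern)
        maxima = [s.pixels.max() for s in stack.slices]
        assert stack.z_values[int(np.argmax(maxima))] == 30.0

    def test_background_far_below_mura(self, geometry, noisy_30, pattern):
        """Normalized MLEM slices have a background noise level orders of
        magnitude below MURA Decoding's on the same input."""
        from muracam import mura_decode
        from muracam.assess import sample_rois, select_signal_roi

        def bg_sigma(img, d):
            x = (img - img.min()) / (img.max() - img.min())
            t = sample_rois(x, d)
            sel = select_signal_roi(t)
            return t.stds[sel.background].mean()

        mura = mura_decode(noisy_30, geometry, 30.0, pattern=pattern).pixels
        stack = reconstruct_3d(noisy_30, geometry, np.arange(20.0, 41.0, 5.0),
                               iterations=40, pattern=pattern)
        mlem = stack[stack.nearest_index(30.0)].pixels
        assert bg_sigma(mura, 13) > 100 * bg_sigma(mlem, 8)

    def test_original_variant_shares_one_normalization(self, geometry,
                                                       noisy_30, pattern):
        state = initialize_state(noisy_30.pixels, geometry, [25.0, 35.0],
                                 variant="original", pattern=pattern)
        assert np.allclose(state.norm_maps[0], state.norm_maps[1])

    def test_invalid_arguments(self, geometry, noisy_30, pattern):
        with pytest.raises(ValueError, match="non-empty"):
            reconstruct_3d(noisy_30, geometry, [], pattern=pattern)
        with pytest.raises(ValueError, match="variant"):
            reconstruct_3d(noisy_30, geometry, [30.0], variant="turbo",
                           pattern=pattern)
        with pytest.raises(ValueError, match="iterations"):
            reconstruct_3d(noisy_30, geometry, [30.0], iterations=-1,
                           pattern=pattern)
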