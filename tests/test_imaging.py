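"""Image-quality control: blur scoring, restoration, noise, contrast,
morphology and the conditional pipeline."""

import numpy as np
import pytest

from predetach import imaging, synthetic
from oracles import laplacian_variance_reference


def blur_frames(frame: np.ndarray, sigma: float) -> np.ndarray:
    return synthetic.degrade(frame[None], synthetic.DegradationSpec(blur_sigma=sigma),
                             seed=0)[0]


class TestScoreBlur:
    def test_constant_image_scores_zero(self):
        for level in (0, 128, 255):
            img = np.full((16, 16, 3), level, dtype=np.uint8)
            variance, blurred = imaging.score_blur(img)
            assert variance == 0.0
            assert blurred

    def test_matches_reference_convolution(self, checkerboard):
        variance, _ = imaging.score_blur(checkerboard)
        L = imaging.lightness_channel(checkerboard)
        assert variance == pytest.approx(laplacian_variance_reference(L), rel=1e-9)

    def test_sharp_scores_above_blurred(self, checkerboard):
        v_sharp, _ = imaging.score_blur(checkerboard)
        v_blur, _ = imaging.score_blur(blur_frames(checkerboard, 2.0))
        assert v_sharp > v_blur

    def test_threshold_comparison_is_strict(self, checkerboard):
        variance, _ = imaging.score_blur(checkerboard)
        assert imaging.score_blur(checkerboard, threshold=variance + 0.1)[1]
        assert not imaging.score_blur(checkerboard, threshold=variance)[1]

    def test_rejects_non_rgb(self):
        with pytest.raises(TypeError):
            imaging.score_blur(np.zeros((16, 16), dtype=np.uint8))


class TestRestoreSharpness:
    def test_unsharp_amount_zero_is_identity(self, checkerboard):
        out = imaging.restore_sharpness(checkerboard, "unsharp", amount=0.0)
        assert np.array_equal(out, checkerboard)

    @pytest.mark.parametrize("method,kwargs", [
        ("unsharp", dict(amount=1.0, radius=2.0)),
        ("deconvolution", dict()),
    ])
    def test_restoration_increases_sharpness(self, checkerboard, method, kwargs):
        blurred = blur_frames(checkerboard, 2.0)
        if method == "deconvolution":
            kwargs["psf"] = imaging.gaussian_psf(2.0)
        restored = imaging.restore_sharpness(blurred, method, **kwargs)
        assert imaging.score_blur(restored)[0] > imaging.score_blur(blurred)[0]

    def test_deconvolution_requires_psf(self, checkerboard):
        with pytest.raises(ValueError):
            imaging.restore_sharpness(checkerboard, "deconvolution")


class TestImpulseNoise:
    def test_mid_grey_scores_zero(self):
        img = np.full((32, 32, 3), 128, dtype=np.uint8)
        assert np.array_equal(imaging.detect_impulse_noise(img), np.zeros(3))

    def test_all_black_is_degenerate_full_fraction(self):
        img = np.zeros((16, 16, 3), dtype=np.uint8)
        assert np.array_equal(imaging.detect_impulse_noise(img), np.ones(3))

    def test_injected_fraction_recovered(self):
        frames = np.full((1, 100, 100, 3), 100, dtype=np.uint8)
        noisy = synthetic.degrade(frames,
                                  synthetic.DegradationSpec(noise_fraction=0.05),
                                  seed=2)[0]
        frac = imaging.detect_impulse_noise(noisy)
        assert np.all(np.abs(frac - 0.05) <= 0.005)

    def test_median_removes_impulses(self):
        frames = np.full((1, 100, 100, 3), 100, dtype=np.uint8)
        noisy = synthetic.degrade(frames,
                                  synthetic.DegradationSpec(noise_fraction=0.05),
                                  seed=2)[0]
        clean = imaging.median_denoise(noisy, 3)
        assert imaging.detect_impulse_noise(clean).max() < 0.005

    def test_median_single_outlier_removed(self):
        img = np.zeros((9, 9, 3), dtype=np.uint8)
        img[4, 4] = 255
        assert imaging.median_denoise(img, 3).max() == 0

    def test_median_identity_on_constant_and_idempotent(self, checkerboard):
        const = np.full((16, 16, 3), 77, dtype=np.uint8)
        assert np.array_equal(imaging.median_denoise(const), const)
        once = imaging.median_denoise(checkerboard, 3)
        twice = imaging.median_denoise(once, 3)
        assert np.max(np.abs(once.astype(int) - twice.astype(int))) <= 1

    def test_even_kernel_rejected(self, checkerboard):
        with pytest.raises(ValueError):
            imaging.median_denoise(checkerboard, 4)


class TestEnhanceContrast:
    def test_high_contrast_frame_skipped(self, checkerboard):
        out, applied = imaging.enhance_contrast(checkerboard)
        assert not applied
        assert np.array_equal(out, checkerboard)

    def test_compressed_frame_enhanced(self, canonical_spec, canonical_trajectories):
        stack = synthetic.render_frames(canonical_trajectories, canonical_spec)
        low = synthetic.degrade(stack[:1],
                                synthetic.DegradationSpec(contrast_scale=0.3),
                                seed=0)[0]
        out, applied = imaging.enhance_contrast(low)
        assert applied
        assert imaging.contrast_score(out) > imaging.contrast_score(low)

    def test_constant_frame_passthrough(self):
        img = np.full((32, 32, 3), 90, dtype=np.uint8)
        out, _ = imaging.enhance_contrast(img)
        assert np.array_equal(out, img)

    def test_chroma_channels_preserved(self, canonical_spec, canonical_trajectories):
        from skimage.color import rgb2lab
        stack = synthetic.render_frames(canonical_trajectories, canonical_spec)
        low = synthetic.degrade(stack[:1],
                                synthetic.DegradationSpec(contrast_scale=0.3),
                                seed=0)[0]
        out, applied = imaging.enhance_contrast(low)
        assert applied
        lab_in = rgb2lab(low / 255.0)
        lab_out = rgb2lab(out / 255.0)
        # a, b untouched up to 8-bit quantisation of the round trip
        assert np.abs(lab_out[..., 1:] - lab_in[..., 1:]).max() < 2.5


class TestMorphology:
    def test_constant_identity(self):
        img = np.full((16, 16, 3), 50, dtype=np.uint8)
        assert np.array_equal(imaging.morphological_cleanup(img), img)

    def test_isolated_speck_removed(self):
        img = np.zeros((15, 15, 3), dtype=np.uint8)
        img[7, 7] = 200
        assert imaging.morphological_cleanup(img, radius=1).max() == 0

    def test_large_blob_nearly_preserved(self):
        img = np.zeros((40, 40, 3), dtype=np.uint8)
        img[10:30, 10:30] = 200
        out = imaging.morphological_cleanup(img, radius=1)
        before = (img[..., 0] > 0).sum()
        after = (out[..., 0] > 0).sum()
        assert abs(after - before) / before < 0.10


class TestPreprocess:
    def degraded_frame(self, canonical_spec, canonical_trajectories, **deg):
        stack = synthetic.render_frames(canonical_trajectories, canonical_spec)
        return stack[0], synthetic.degrade(
            stack[:1], synthetic.DegradationSpec(**deg), seed=0)[0]

    def test_clean_frame_untouched(self, canonical_spec, canonical_trajectories):
        clean, _ = self.degraded_frame(canonical_spec, canonical_trajectories)
        out, report = imaging.preprocess(clean)
        assert report.applied_steps == []
        assert not report.is_blurred
        assert np.array_equal(out, clean)

    def test_degraded_frame_repaired(self, canonical_spec, canonical_trajectories):
        _, bad = self.degraded_frame(canonical_spec, canonical_trajectories,
                                     blur_sigma=2.0, noise_fraction=0.05,
                                     contrast_scale=0.3)
        out, report = imaging.preprocess(bad)
        assert {"unsharp", "median", "clahe"} <= set(report.applied_steps)
        assert imaging.score_blur(out)[0] > report.laplacian_variance_L
        assert imaging.detect_impulse_noise(out).max() \
            < imaging.detect_impulse_noise(bad).max()

    def test_blurred_only_skips_noise_stages(self, canonical_spec,
                                             canonical_trajectories):
        _, bad = self.degraded_frame(canonical_spec, canonical_trajectories,
                                     blur_sigma=2.0)
        _, report = imaging.preprocess(bad)
        assert "unsharp" in report.applied_steps
        assert "median" not in report.applied_steps
        assert "morphology" not in report.applied_steps

    def test_deterministic(self, canonical_spec, canonical_trajectories):
        _, bad = self.degraded_frame(canonical_spec, canonical_trajectories,
                                     blur_sigma=2.0, noise_fraction=0.02)
        out1, _ = imaging.preprocess(bad)
        out2, _ = imaging.preprocess(bad)
        assert np.array_equal(out1, out2)
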