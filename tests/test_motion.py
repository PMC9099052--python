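import numpy as np
import pytest

from fosters import motion, phantom, sampling
from fosters.config import MotionConfig, RegistrationConfig
from fosters.containers import DynamicImageSeries, MotionTrace

from conftest import small_config


class TestFatRoi:
    def test_bright_disc_box_includes_dilation_margin(self):
        img = np.zeros((40, 40, 2))
        yy, xx = np.mgrid[0:40, 0:40]
        disc = (yy - 20) ** 2 + (xx - 20) ** 2 <= 5**2
        img[disc] = 1.0
        cfg = RegistrationConfig(mask_threshold=0.5, dilation_radius=3)
        mask, box = motion.fat_roi(img, cfg)
        y0, y1, x0, x1 = box
        assert (y0, x0) == (20 - 5 - 3, 20 - 5 - 3)
        assert (y1, x1) == (20 + 5 + 3 + 1, 20 + 5 + 3 + 1)

    def test_zero_dilation_gives_tight_box(self):
        img = np.zeros((20, 20, 1))
        img[8:12, 5:9] = 1.0
        cfg = RegistrationConfig(mask_threshold=0.5, dilation_radius=0)
        _, box = motion.fat_roi(img, cfg)
        assert box == (8, 12, 5, 9)

    def test_all_below_threshold_rejected(self):
        with pytest.raises(ValueError):
            motion.fat_roi(np.zeros((10, 10, 2)))

    def test_central_component_preferred_over_edge_component(self):
        img = np.zeros((40, 40, 1))
        img[0:4, :] = 1.0  # chest-wall-like band at the edge
        img[18:24, 18:24] = 1.0  # central structure
        cfg = RegistrationConfig(mask_threshold=0.5, dilation_radius=0)
        _, box = motion.fat_roi(img, cfg)
        assert box == (18, 24, 18, 24)


class TestNgf:
    def test_similarity_invariant_to_positive_scaling(self, rng):
        # gradient normalization: scaling one image leaves NGF unchanged
        # (in the small-eps regime)
        u = rng.standard_normal((20, 20))
        v = rng.standard_normal((20, 20))
        s1 = motion.ngf_similarity(u, v, eps=1e-12)
        s2 = motion.ngf_similarity(u, 7.3 * v, eps=1e-12)
        assert s1 == pytest.approx(s2, rel=1e-6)


class TestEstimateTranslations:
    def test_identical_frames_give_zero_trace(self, rng):
        frame = rng.uniform(0, 1, (30, 30))
        series = np.repeat(frame[:, :, None], 4, axis=2)
        trace = motion.estimate_translations(series, (2, 28, 2, 28))
        assert np.abs(trace.dx).max() < 0.05
        assert np.abs(trace.dy).max() < 0.05

    def test_programmed_fractional_shift_recovered(self, small_truth):
        fat = small_truth.fat_series[..., :1]
        from fosters.fourier import shift_image

        shifted = shift_image(fat[..., 0], -1.5, 2.5)
        series = np.stack([fat[..., 0], shifted], axis=2)
        _, box = motion.fat_roi(series)
        trace = motion.estimate_translations(series, box)
        assert trace.dy[1] == pytest.approx(-1.5, abs=0.5)
        assert trace.dx[1] == pytest.approx(2.5, abs=0.5)

    def test_box_outside_image_rejected(self, rng):
        series = rng.uniform(0, 1, (10, 10, 3))
        with pytest.raises(ValueError):
            motion.estimate_translations(series, (0, 20, 0, 10))


class TestSelectReferenceFrame:
    @pytest.mark.parametrize("dy, expected", [
        ([-2.0, 0.0, 2.0], 1),   # mean 0, frame 1 closest
        ([1.0, 2.0, 9.0], 1),    # mean 4, closest is 2
        ([-1.0, 1.0], 0),        # tie broken to lowest index
    ])
    def test_si_displacement_closest_to_mean(self, dy, expected):
        trace = MotionTrace(dx=np.zeros(len(dy)), dy=np.array(dy))
        assert motion.select_reference_frame(trace) == expected

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            motion.select_reference_frame(MotionTrace(dx=[], dy=[]))


class TestApplyPhaseShift:
    def test_zero_trace_is_identity(self, small_kt):
        _, kt = small_kt
        nt = kt.samples.shape[3]
        out = motion.apply_phase_shift(
            kt, MotionTrace(dx=np.zeros(nt), dy=np.zeros(nt)))
        np.testing.assert_array_equal(out.samples, kt.samples)

    def test_integer_shift_is_exact_circular_shift(self, rng):
        from fosters.config import AcquisitionParams
        from fosters.containers import KTData
        from fosters.fourier import fft2c, ifft2c

        img = rng.uniform(0, 1, (16, 16))
        k = fft2c(img)[None, :, :, None, None].astype(complex)
        pattern = sampling.generate_kt_mask(16, 16, 1, R=1, seed=0)
        kt = KTData(samples=k, mask=pattern,
                    coil_maps=np.ones((1, 16, 16), complex),
                    acq=AcquisitionParams())
        out = motion.apply_phase_shift(
            kt, MotionTrace(dx=np.array([0.0]), dy=np.array([3.0])))
        back = ifft2c(out.samples[0, :, :, 0, 0]).real
        np.testing.assert_allclose(back, np.roll(img, 3, axis=0), atol=1e-12)

    def test_shift_then_unshift_restores_input(self, small_kt):
        _, kt = small_kt
        nt = kt.samples.shape[3]
        trace = MotionTrace(dx=np.linspace(-2, 2, nt),
                            dy=np.linspace(1, -1, nt))
        out = motion.apply_phase_shift(motion.apply_phase_shift(kt, trace),
                                       trace.negated())
        assert np.abs(out.samples - kt.samples).max() < 1e-12

    def test_energy_conserved_per_frame(self, small_kt):
        _, kt = small_kt
        nt = kt.samples.shape[3]
        trace = MotionTrace(dx=np.full(nt, 1.7), dy=np.full(nt, -0.3))
        out = motion.apply_phase_shift(kt, trace)
        for t in range(nt):
            a = np.sum(np.abs(kt.samples[:, :, :, t]) ** 2)
            b = np.sum(np.abs(out.samples[:, :, :, t]) ** 2)
            assert b == pytest.approx(a, rel=1e-12)

    def test_trace_length_mismatch_rejected(self, small_kt):
        _, kt = small_kt
        with pytest.raises(ValueError):
            motion.apply_phase_shift(kt, MotionTrace(dx=[1.0], dy=[1.0]))


class TestNonrigidRefine:
    def test_pca_projection_exact_on_low_rank_series(self, rng):
        # rank-2 series (mean + 2 components) is reproduced exactly with K=2
        ny = nx = 16
        nt = 10
        basis = rng.standard_normal((ny * nx, 2))
        weights = rng.standard_normal((2, nt))
        series = (basis @ weights + 5.0).reshape(ny, nx, nt)
        approx = motion.pca_synthetic_series(series, 2)
        np.testing.assert_allclose(approx, series, atol=1e-8)

    def test_too_many_components_rejected(self, rng):
        series = rng.uniform(0, 1, (8, 8, 4))
        with pytest.raises(ValueError):
            motion.pca_synthetic_series(series, 4)

    def test_motionless_series_has_negligible_deformation(self):
        cfg = small_config(motion=MotionConfig(amplitude=0, amplitude_lr=0))
        truth = phantom.render_truth(cfg)
        series = DynamicImageSeries(data=truth.water_series,
                                    frame_times=truth.frame_times)
        refined, fields = motion.nonrigid_refine(series, return_fields=True)
        assert np.abs(fields).mean() < 0.1

    def test_metadata_preserved(self, small_truth):
        series = DynamicImageSeries(data=small_truth.water_series,
                                    frame_times=small_truth.frame_times,
                                    pixel_spacing=1.6)
        refined = motion.nonrigid_refine(series)
        assert refined.data.shape == series.data.shape
        np.testing.assert_array_equal(refined.frame_times, series.frame_times)
        assert refined.pixel_spacing == series.pixel_spacing


def test_end_to_end_rigid_correction_reduces_residual(small_kt, small_cfg):
    """Rigid stage on the small moving phantom: estimate from pass-1 fat,
    correct the k-space, and verify residual displacement shrinks."""
    from fosters import dixon, recon
    from fosters.config import ReconConfig

    truth, kt = small_kt
    p1 = recon.solve_lrs(kt, ReconConfig(n_iter=10))
    wf1 = dixon.separate_water_fat(p1, kt.acq)
    trace = motion.estimate_motion(wf1.fat, wf1.water)
    true_rel = truth.motion_trace.re_referenced(trace.reference_frame)
    resid = np.sqrt(np.mean((trace.dy - true_rel.dy) ** 2
                            + (trace.dx - true_rel.dx) ** 2))
    programmed = np.sqrt(np.mean(true_rel.dy**2 + true_rel.dx**2))
    assert resid < 0.5
    assert resid < programmed / 2
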