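import numpy as np
import pytest
from scipy import ndimage, signal, stats

from svheart import (Geometry, SimConfig, generate_speckle_frame,
                     render_video, simulate_recording, simulate_rr_series,
                     simulate_tilt_waveform, synthesize_ecg)
from svheart.simulate import CARDIAC_PULSE_WIDTH_S


class TestSpeckleFrame:
    def test_same_seed_is_deterministic(self):
        a = generate_speckle_frame((64, 64), 4.0, seed=5)
        b = generate_speckle_frame((64, 64), 4.0, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_fully_developed_contrast_is_unity(self, speckle_frame):
        # exponential intensity statistics: sd/mean = 1
        contrast = speckle_frame.std() / speckle_frame.mean()
        assert contrast == pytest.approx(1.0, abs=0.05)

    def test_intensity_is_exponential(self, speckle_frame):
        d = stats.kstest(speckle_frame.ravel(), "expon",
                         args=(0, speckle_frame.mean())).statistic
        assert d < 0.02

    def test_grain_size_controls_correlation_width(self):
        def fwhm(frame):
            spec = np.abs(np.fft.fft2(frame - frame.mean())) ** 2
            ac = np.fft.fftshift(np.fft.ifft2(spec).real)
            row = ac[ac.shape[0] // 2]
            return np.sum(row > 0.5 * row.max())

        wide = generate_speckle_frame((256, 256), 8.0, seed=1)
        narrow = generate_speckle_frame((256, 256), 2.0, seed=1)
        assert fwhm(wide) > fwhm(narrow)

    def test_mean_normalized(self, speckle_frame):
        assert speckle_frame.mean() == pytest.approx(1.0)
        assert np.all(speckle_frame >= 0)

    def test_grain_too_large_rejected(self):
        with pytest.raises(ValueError):
            generate_speckle_frame((32, 32), 10.0, seed=0)


class TestRRSeries:
    def test_constant_without_variability(self):
        cfg = SimConfig(duration_s=30, mean_hr_bpm=60, sdnn_s=0.0,
                        rsa_depth=0.0)
        rr = simulate_rr_series(cfg)
        np.testing.assert_allclose(rr, 1.0)
        assert np.sum(rr) >= 30

    def test_mean_rr_matches_heart_rate(self):
        cfg = SimConfig(duration_s=300, mean_hr_bpm=70, sdnn_s=0.03,
                        rsa_depth=0.0, seed=3)
        rr = simulate_rr_series(cfg)
        se = 0.03 / np.sqrt(rr.size)
        assert abs(rr.mean() - 60.0 / 70.0) < 3 * se

    def test_rsa_modulation_peaks_at_respiratory_rate(self):
        cfg = SimConfig(duration_s=300, rsa_depth=0.1, sdnn_s=0.0)
        rr = simulate_rr_series(cfg)
        tk = np.cumsum(rr)
        freqs = np.linspace(0.05, 0.5, 200)
        power = signal.lombscargle(tk, rr - rr.mean(), 2 * np.pi * freqs)
        assert freqs[np.argmax(power)] == pytest.approx(0.25, abs=0.02)

    def test_intervals_clipped_positive(self):
        cfg = SimConfig(duration_s=60, mean_hr_bpm=200, sdnn_s=0.5, seed=0)
        rr = simulate_rr_series(cfg)
        assert np.all(rr >= 0.3)


class TestTiltWaveform:
    def test_zero_cardiac_amplitude_gives_pure_sinusoid(self):
        cfg = SimConfig(duration_s=8, cardiac_tilt_amp_rad=0.0)
        alpha, beats = simulate_tilt_waveform(np.array([1.0] * 10), cfg)
        t = np.arange(alpha.size) / cfg.frame_rate_hz
        expected = cfg.resp_tilt_amp_rad * np.sin(
            2 * np.pi * cfg.resp_rate_hz * t)
        np.testing.assert_allclose(alpha, expected, atol=1e-18)

    def test_single_beat_pulse_is_localized(self):
        cfg = SimConfig(duration_s=8, resp_tilt_amp_rad=0.0)
        alpha, beats = simulate_tilt_waveform(np.array([4.0]), cfg)
        assert beats.tolist() == [4.0]
        half = CARDIAC_PULSE_WIDTH_S / 2
        t = np.arange(alpha.size) / cfg.frame_rate_hz
        outside = np.abs(t - 4.0) > half + 1.0 / cfg.frame_rate_hz
        np.testing.assert_allclose(alpha[outside], 0.0, atol=1e-18)
        assert np.any(alpha != 0)

    def test_damping_scales_cardiac_component_linearly(self):
        rr = np.array([1.0] * 6)
        base = SimConfig(duration_s=6, resp_tilt_amp_rad=0.0)
        half_cfg = SimConfig(duration_s=6, resp_tilt_amp_rad=0.0, damping=0.5)
        a1, _ = simulate_tilt_waveform(rr, base)
        a2, _ = simulate_tilt_waveform(rr, half_cfg)
        np.testing.assert_allclose(a2, 0.5 * a1)


class TestRenderVideo:
    def test_zero_tilt_no_noise_repeats_base(self, speckle_frame):
        base = speckle_frame[:32, :32]
        cfg = SimConfig(duration_s=1, frame_shape=(32, 32), noise_sd=0.0)
        stack = render_video(base, np.zeros(5), cfg.geometry, cfg)
        for frame in stack.frames:
            np.testing.assert_allclose(frame, base, atol=1e-6)

    def test_unit_tilt_shifts_one_pixel(self, speckle_frame):
        base = speckle_frame[:64, :64]
        geom = Geometry()
        cfg = SimConfig(duration_s=1, frame_shape=(64, 64), noise_sd=0.0,
                        shift_axis_deg=0.0)
        alpha = np.arctan(geom.pixel_pitch / geom.K)
        stack = render_video(base, np.array([0.0, alpha]), geom, cfg)
        expected = np.fft.ifft2(
            ndimage.fourier_shift(np.fft.fft2(base), (0.0, 1.0))).real
        np.testing.assert_allclose(stack.frames[1], expected, atol=1e-5)

    def test_excessive_shift_rejected(self, speckle_frame):
        base = speckle_frame[:32, :32]
        geom = Geometry()
        cfg = SimConfig(duration_s=1, frame_shape=(32, 32))
        alpha = np.arctan(20 * geom.pixel_pitch / geom.K)
        with pytest.raises(ValueError, match="frame size"):
            render_video(base, np.array([0.0, alpha]), geom, cfg)


class TestSynthesizeECG:
    def test_r_peaks_at_constructed_positions(self):
        rr = np.ones(59)
        record, truth = synthesize_ecg(rr, 300.0, noise_sd=0.0,
                                       duration_s=60.0)
        assert len(truth) == 59
        np.testing.assert_array_equal(truth.peaks, 300 * np.arange(1, 60))

    def test_noise_free_maxima_coincide_with_truth(self):
        rr = np.full(10, 0.9)
        record, truth = synthesize_ecg(rr, 300.0, noise_sd=0.0)
        for r in truth.peaks:
            lo, hi = max(r - 60, 0), min(r + 60, len(record))
            assert lo + np.argmax(record.samples[lo:hi]) == r

    def test_too_short_record_rejected(self):
        with pytest.raises(ValueError, match="template"):
            synthesize_ecg(np.array([0.4]), 300.0, duration_s=0.3)


class TestRecordingClosure:
    def test_determinism_and_ground_truth_bounds(self, short_sim_config):
        rec1 = simulate_recording(short_sim_config)
        rec2 = simulate_recording(short_sim_config)
        np.testing.assert_array_equal(rec1.video.frames, rec2.video.frames)
        np.testing.assert_array_equal(rec1.ecg.samples, rec2.ecg.samples)
        np.testing.assert_array_equal(rec1.truth_r_peaks.peaks,
                                      rec2.truth_r_peaks.peaks)

        for beats in (rec1.truth_sv_beats.times_s, rec1.truth_r_peaks.times_s):
            assert np.all(np.diff(beats) > 0)
            assert beats[0] >= 0
            assert beats[-1] <= short_sim_config.duration_s
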