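"""Synthetic paired speckle-video / ECG recordings with known ground truth.

The generator emulates one sleep-lab style measurement: a fully developed
laser-speckle pattern that translates on the sensor as the illuminated
surface tilts under cardiac and respiratory motion, imaged at the video
frame rate, plus a single-lead ECG whose R-peak sample indices are exported
exactly.  Because the true beat times and the true tilt waveform are known,
every downstream stage (registration, beat detection, matching, agreement)
can be validated without access to real recordings.

Physical chain: RR intervals (with respiratory sinus arrhythmia and
Gaussian beat-to-beat variability) -> surface tilt alpha(t) (respiratory
sinusoid + one biphasic cardiac pulse per beat) -> speckle shift
s(t) = K*tan(alpha)/pixel_pitch pixels -> frames shifted by exact spectral
phase ramps with additive sensor noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .config import Geometry, SimConfig
from .io import BeatSeries, ECGRecord, FrameStack
from .registration import tilt_to_shift

__all__ = [
    "generate_speckle_frame",
    "simulate_rr_series",
    "simulate_tilt_waveform",
    "render_video",
    "synthesize_ecg",
    "simulate_recording",
    "SyntheticRecording",
]

#: Fixed full width of the biphasic cardiac tilt pulse (s).
CARDIAC_PULSE_WIDTH_S = 0.120


def generate_speckle_frame(shape: tuple[int, int], grain_px: float,
                           seed: int | np.random.Generator) -> np.ndarray:
    """Generate one fully developed speckle intensity frame.

    A complex circular-Gaussian random field is low-pass filtered to a
    correlation length of ``grain_px`` pixels (periodic boundary, so the
    frame tiles seamlessly under spectral shifting); the intensity is its
    squared magnitude, normalized to mean 1.  Any linear filter of a
    circular-Gaussian field is itself Gaussian, so the intensity follows the
    exponential law of fully developed speckle (contrast sd/mean = 1)
    regardless of grain size.
    """
    if grain_px < 1:
        raise ValueError("grain_px must be >= 1")
    if grain_px > min(shape) / 4:
        raise ValueError("grain_px must not exceed min(shape)/4")
    rng = np.random.default_rng(seed)
    field = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    sigma = grain_px / 2.0
    field = (ndimage.gaussian_filter(field.real, sigma, mode="wrap")
             + 1j * ndimage.gaussian_filter(field.imag, sigma, mode="wrap"))
    intensity = np.abs(field) ** 2
    return intensity / intensity.mean()


def simulate_rr_series(cfg: SimConfig,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw RR intervals covering the configured duration.

    RR_k = 60/mean_hr * (1 + rsa_depth * sin(2*pi*resp_rate*t_k)) + eps_k,
    with eps_k ~ N(0, sdnn_s) and t_k the cumulative time of beat k;
    intervals are clipped to >= 0.3 s.  The cumulative sum of the returned
    intervals reaches at least ``duration_s``.
    """
    if not 30.0 <= cfg.mean_hr_bpm <= 200.0:
        raise ValueError("mean_hr_bpm must lie in [30, 200]")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    base = 60.0 / cfg.mean_hr_bpm
    rr = []
    t = 0.0
    while t < cfg.duration_s:
        rsa = 1.0 + cfg.rsa_depth * np.sin(2 * np.pi * cfg.resp_rate_hz * t)
        interval = base * rsa + rng.normal(0.0, cfg.sdnn_s)
        interval = max(interval, 0.3)
        rr.append(interval)
        t += interval
    return np.asarray(rr)


def _cardiac_pulse(rate_hz: float) -> np.ndarray:
    """Biphasic pulse template: derivative of a Gaussian, unit peak amplitude.

    Full width CARDIAC_PULSE_WIDTH_S (support +-60 ms, sigma = width/6 so the
    tails vanish at the edges).
    """
    half = CARDIAC_PULSE_WIDTH_S / 2.0
    sigma = CARDIAC_PULSE_WIDTH_S / 6.0
    t = np.arange(-round(half * rate_hz), round(half * rate_hz) + 1) / rate_hz
    pulse = -t / sigma ** 2 * np.exp(-t ** 2 / (2 * sigma ** 2))
    return pulse / np.abs(pulse).max()


def simulate_tilt_waveform(rr: np.ndarray,
                           cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Build the surface-tilt series alpha(t) at the video frame rate.

    The tilt is a respiratory sinusoid of amplitude ``resp_tilt_amp_rad``
    plus one biphasic cardiac pulse of amplitude
    ``damping * cardiac_tilt_amp_rad`` anchored at each cumulative RR time.
    Returns ``(alpha, beat_times_s)``; the anchor times within the duration
    are the ground-truth SV beat times.
    """
    rr = np.asarray(rr, dtype=float)
    if rr.size == 0:
        raise ValueError("rr must be nonempty")
    n = int(round(cfg.duration_s * cfg.frame_rate_hz))
    t = np.arange(n) / cfg.frame_rate_hz
    alpha = cfg.resp_tilt_amp_rad * np.sin(2 * np.pi * cfg.resp_rate_hz * t)

    pulse = _cardiac_pulse(cfg.frame_rate_hz) * cfg.damping * cfg.cardiac_tilt_amp_rad
    half = len(pulse) // 2
    beat_times = np.cumsum(rr)
    beat_times = beat_times[beat_times < cfg.duration_s]
    for tb in beat_times:
        center = int(round(tb * cfg.frame_rate_hz))
        lo, hi = center - half, center + half + 1
        src_lo, src_hi = max(0, -lo), len(pulse) - max(0, hi - n)
        alpha[max(lo, 0):min(hi, n)] += pulse[src_lo:src_hi]
    return alpha, beat_times


def render_video(base: np.ndarray, tilt: np.ndarray, geom: Geometry,
                 cfg: SimConfig,
                 rng: np.random.Generator | None = None) -> FrameStack:
    """Render the speckle video: frame t is ``base`` translated by the
    tilt-induced shift, plus additive Gaussian sensor noise.

    The shift s(t) = K*tan(alpha(t))/pixel_pitch pixels is applied along a
    fixed axis at ``shift_axis_deg`` via an exact spectral phase ramp
    (periodic boundary — no new content enters the frame, so registration
    can be validated to its resolution limit).
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    s = tilt_to_shift(np.asarray(tilt, dtype=float), geom)
    if np.max(np.abs(s)) > min(base.shape) / 4:
        raise ValueError("shift exceeds frame size/4; wraparound would dominate")
    theta = np.deg2rad(cfg.shift_axis_deg)
    sx, sy = s * np.cos(theta), s * np.sin(theta)

    base_f = np.fft.fft2(base)
    frames = np.empty((len(s), *base.shape), dtype=np.float32)
    for k in range(len(s)):
        if sx[k] == 0.0 and sy[k] == 0.0:
            frame = base.copy()
        else:
            shifted = ndimage.fourier_shift(base_f, (sy[k], sx[k]))
            frame = np.fft.ifft2(shifted).real
        if cfg.noise_sd > 0:
            frame = frame + rng.normal(0.0, cfg.noise_sd, base.shape)
        frames[k] = frame
    return FrameStack(frames, rate_hz=cfg.frame_rate_hz)


def _pqrst_template(rate_hz: float) -> tuple[np.ndarray, int]:
    """One PQRST-like beat on a flat baseline; returns (template, r_index).

    Gaussian bumps: small P, narrow dominant R flanked by Q/S dips, broad T.
    Amplitudes are arbitrary units with R normalized to 1.
    """
    t = np.arange(-round(0.3 * rate_hz), round(0.45 * rate_hz) + 1) / rate_hz

    def bump(center, sigma, amp):
        return amp * np.exp(-((t - center) ** 2) / (2 * sigma ** 2))

    wave = (bump(-0.17, 0.025, 0.12)    # P
            + bump(-0.025, 0.010, -0.15)  # Q
            + bump(0.0, 0.008, 1.0)       # R
            + bump(0.025, 0.010, -0.25)   # S
            + bump(0.19, 0.045, 0.30))    # T
    r_index = int(np.argmax(wave))
    return wave / wave[r_index], r_index


def synthesize_ecg(rr: np.ndarray, rate_hz: float, noise_sd: float = 0.02,
                   rng: np.random.Generator | None = None,
                   duration_s: float | None = None
                   ) -> tuple[ECGRecord, BeatSeries]:
    """Place a PQRST-like template at each cumulative RR time.

    Returns the ECG record and a BeatSeries holding the exact R sample
    indices (the simulation ground truth).
    """
    rr = np.asarray(rr, dtype=float)
    if rr.size == 0:
        raise ValueError("rr must be nonempty")
    total = duration_s if duration_s is not None else float(np.sum(rr)) + 0.5
    template, r_idx = _pqrst_template(rate_hz)
    n = int(round(total * rate_hz))
    if n < len(template):
        raise ValueError("record shorter than one beat template")
    rng = np.random.default_rng(0) if rng is None else rng

    signal = np.zeros(n)
    beat_times = np.cumsum(rr)
    beat_times = beat_times[beat_times < total]
    r_samples = []
    for tb in beat_times:
        center = int(round(tb * rate_hz))
        lo = center - r_idx
        hi = lo + len(template)
        src_lo, src_hi = max(0, -lo), len(template) - max(0, hi - n)
        signal[max(lo, 0):min(hi, n)] += template[src_lo:src_hi]
        if 0 <= center < n:
            r_samples.append(center)
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, n)
    record = ECGRecord(signal, rate_hz=rate_hz)
    truth = BeatSeries(np.asarray(r_samples, dtype=int), "ecg",
                       rate_hz=rate_hz, unit="samples")
    return record, truth


@dataclass
class SyntheticRecording:
    """One simulated measurement plus its ground truth."""

    video: FrameStack
    ecg: ECGRecord
    truth_sv_beats: BeatSeries   # cardiac pulse anchor times (seconds)
    truth_r_peaks: BeatSeries    # exact R sample indices
    rr_s: np.ndarray             # the generating RR intervals
    tilt_rad: np.ndarray         # the tilt waveform driving the video


def simulate_recording(cfg: SimConfig) -> SyntheticRecording:
    """Generate one paired speckle-video / ECG recording.

    Deterministic: the same ``cfg`` (including ``seed``) yields bit-identical
    video and ECG.  Independent child generators are spawned per component so
    that, e.g., changing the ECG noise level does not perturb the video.
    """
    root = np.random.default_rng(cfg.seed)
    seeds = root.spawn(4)
    base = generate_speckle_frame(cfg.frame_shape, cfg.grain_px, seeds[0])
    rr = simulate_rr_series(cfg, rng=seeds[1])
    tilt, sv_beats = simulate_tilt_waveform(rr, cfg)
    video = render_video(base, tilt, cfg.geometry, cfg, rng=seeds[2])
    ecg, r_peaks = synthesize_ecg(rr, cfg.ecg_rate_hz, noise_sd=cfg.ecg_noise_sd,
                                  rng=seeds[3], duration_s=cfg.duration_s)
    truth_sv = BeatSeries(sv_beats, "sv", rate_hz=cfg.frame_rate_hz, unit="s")
    return SyntheticRecording(video, ecg, truth_sv, r_peaks, rr, tilt)
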