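"""Cardiac peak detection in the SV principal signal and in the ECG.

SV side: the displacement series is (optionally) band-passed to the cardiac
vibration band, demodulated by the Hilbert envelope, band-passed to
0.5-3 Hz — the *principal signal* — and peaks are accepted by adaptive
thresholding over 5 s non-overlapping windows with an exponentially updated
signal-peak level.  All filters are zero-phase (forward-backward Butterworth)
so peak times are not biased by filter delay.

ECG side: an Engelse-Zeelenberg R-peak detector — four-sample difference
differentiator, short FIR smoothing, biphasic threshold crossings opening a
search window, adaptive threshold from recent detection amplitudes with
decay on long gaps and a 200 ms refractory period.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sps

from .config import DetectorConfig
from .io import BeatSeries, ECGRecord

__all__ = ["principal_signal", "detect_sv_peaks", "detect_r_peaks"]


def _bandpass(x: np.ndarray, band: tuple[float, float], rate_hz: float,
              order: int) -> np.ndarray:
    lo, hi = band
    nyq = rate_hz / 2.0
    if not 0 < lo < hi < nyq:
        raise ValueError(f"band {band} outside (0, {nyq}) Hz at rate {rate_hz}")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=rate_hz, output="sos")
    return sps.sosfiltfilt(sos, x)


def principal_signal(dr: np.ndarray, rate_hz: float,
                     cfg: DetectorConfig | None = None) -> np.ndarray:
    """Demodulate the displacement series into the cardiac principal signal.

    Optional cardiac-band pre-filter -> Hilbert envelope (analytic-signal
    magnitude) -> band-pass to ``env_band_hz``.  Output length equals input
    length.
    """
    cfg = cfg or DetectorConfig()
    x = np.asarray(dr, dtype=float)
    if x.ndim != 1:
        raise ValueError("dr must be 1-D")
    if x.size / rate_hz < 2.0 / cfg.env_band_hz[0]:
        raise ValueError("record too short for the configured envelope band")
    if cfg.pre_band_hz is not None:
        x = _bandpass(x, cfg.pre_band_hz, rate_hz, cfg.filter_order)
    env = np.abs(sps.hilbert(x))
    return _bandpass(env, cfg.env_band_hz, rate_hz, cfg.filter_order)


def detect_sv_peaks(principal: np.ndarray, rate_hz: float,
                    cfg: DetectorConfig | None = None) -> BeatSeries:
    """Adaptive-threshold peak detection on the principal signal.

    Candidates are strict 3-point local maxima.  Within each non-overlapping
    ``window_s`` window the acceptance threshold is ``thresh_frac`` times
    the running signal-peak level; every accepted peak updates the level as
    0.125*amplitude + 0.875*level.  The level is initialized from the first
    window's maximum, which makes detection invariant to a positive rescale
    of the input.  Accepted peaks closer than ``refractory_s`` keep the
    larger amplitude.
    """
    cfg = cfg or DetectorConfig()
    x = np.asarray(principal, dtype=float)
    if x.size < 3 or np.ptp(x) == 0:
        return BeatSeries(np.array([], dtype=int), "sv", rate_hz, unit="samples")

    cand = np.flatnonzero((x[1:-1] > x[:-2]) & (x[1:-1] > x[2:])) + 1
    if cand.size == 0:
        return BeatSeries(np.array([], dtype=int), "sv", rate_hz, unit="samples")

    win = max(int(round(cfg.window_s * rate_hz)), 1)
    level = float(np.max(x[:win]))
    accepted: list[int] = []
    for start in range(0, x.size, win):
        thresh = cfg.thresh_frac * level
        for idx in cand[(cand >= start) & (cand < start + win)]:
            if x[idx] > thresh:
                accepted.append(int(idx))
                level = 0.125 * x[idx] + 0.875 * level

    peaks = _enforce_refractory(np.asarray(accepted, dtype=int), x,
                                int(round(cfg.refractory_s * rate_hz)))
    return BeatSeries(peaks, "sv", rate_hz, unit="samples")


def _enforce_refractory(peaks: np.ndarray, amp: np.ndarray,
                        min_gap: int) -> np.ndarray:
    """Drop the smaller of any two peaks closer than ``min_gap`` samples."""
    peaks = list(peaks)
    changed = True
    while changed and len(peaks) > 1:
        changed = False
        for i in range(len(peaks) - 1):
            if peaks[i + 1] - peaks[i] < min_gap:
                drop = i if amp[peaks[i]] < amp[peaks[i + 1]] else i + 1
                del peaks[drop]
                changed = True
                break
    return np.asarray(peaks, dtype=int)


# ---------------------------------------------------------------------------
# ECG R-peak detection (Engelse-Zeelenberg scheme)
# ---------------------------------------------------------------------------

_EZ_RATE = 300.0          # internal detection rate (Hz)
_EZ_SMOOTH = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0
_EZ_WINDOW_S = 0.160      # search window opened by a threshold crossing
_EZ_REFRACTORY_S = 0.200
_EZ_THRESH_FRAC = 0.48    # threshold as fraction of recent detection level
_EZ_DECAY_GAP_S = 3.0     # halve the level after this long without a beat


def detect_r_peaks(ecg: ECGRecord) -> BeatSeries:
    """Engelse-Zeelenberg R-peak detection with adaptive thresholding.

    The signal is differentiated as y[n] = x[n] - x[n-4], smoothed with a
    [1,4,6,4,1] FIR kernel, and scanned for positive threshold crossings
    that are followed by a negative crossing within 160 ms (the biphasic
    signature of a QRS).  Each qualifying crossing opens a search window in
    which the R peak is the maximum of the raw signal.  The threshold is
    ``0.48`` times a running level updated from each detection's
    differentiated amplitude; the level is halved whenever no beat has been
    seen for 3 s, and detections within 200 ms of the previous beat are
    suppressed.  Records not sampled near 300 Hz are resampled internally
    for detection, but peak indices always refer to the original record.
    """
    x = np.asarray(ecg.samples, dtype=float)
    if x.size < 10 or np.ptp(x) == 0:
        warnings.warn("flat or too-short ECG: no R peaks detected")
        return BeatSeries(np.array([], dtype=int), "ecg", ecg.rate_hz,
                          unit="samples", t0=ecg.t0)

    if abs(ecg.rate_hz - _EZ_RATE) / _EZ_RATE > 0.01:
        up, down = _resample_ratio(ecg.rate_hz, _EZ_RATE)
        xd = sps.resample_poly(x, up, down)
        det_rate = ecg.rate_hz * up / down
    else:
        xd, det_rate = x, ecg.rate_hz

    y = np.zeros_like(xd)
    y[4:] = xd[4:] - xd[:-4]
    y2 = np.convolve(y, _EZ_SMOOTH, mode="same")

    win = int(round(_EZ_WINDOW_S * det_rate))
    refr = int(round(_EZ_REFRACTORY_S * det_rate))
    decay_gap = int(round(_EZ_DECAY_GAP_S * det_rate))

    # Seed the level from the largest differentiated amplitude in the first
    # two seconds (any heart rate >= 30 bpm puts a beat there).
    lead = min(int(round(2.0 * det_rate)), y2.size)
    level = float(np.max(np.abs(y2[:lead])))
    if level == 0:
        warnings.warn("no deflections found: no R peaks detected")
        return BeatSeries(np.array([], dtype=int), "ecg", ecg.rate_hz,
                          unit="samples", t0=ecg.t0)

    peaks: list[int] = []
    last_event = 0
    i = 4
    while i < y2.size:
        if i - last_event > decay_gap:
            level *= 0.5
            last_event = i
        if y2[i] > _EZ_THRESH_FRAC * level:
            seg_end = min(i + win, y2.size)
            if np.min(y2[i:seg_end]) < -_EZ_THRESH_FRAC * level:
                r_det = i + int(np.argmax(xd[i:seg_end]))
                r_orig = _refine_on_original(x, r_det, det_rate, ecg.rate_hz, win)
                if not peaks or r_orig - peaks[-1] >= int(round(
                        _EZ_REFRACTORY_S * ecg.rate_hz)):
                    peaks.append(r_orig)
                    level = 0.125 * float(np.max(np.abs(y2[i:seg_end]))) \
                        + 0.875 * level
                    last_event = r_det
                i = i + win + refr
                continue
        i += 1

    if not peaks:
        warnings.warn("no QRS complexes found in ECG")
    return BeatSeries(np.asarray(sorted(set(peaks)), dtype=int), "ecg",
                      ecg.rate_hz, unit="samples", t0=ecg.t0)


def _resample_ratio(rate_in: float, rate_out: float) -> tuple[int, int]:
    from fractions import Fraction
    frac = Fraction(rate_out / rate_in).limit_denominator(1000)
    return frac.numerator, frac.denominator


def _refine_on_original(x: np.ndarray, idx_det: int, det_rate: float,
                        orig_rate: float, win_det: int) -> int:
    """Map a detection-domain index back and take the local argmax of x."""
    center = int(round(idx_det * orig_rate / det_rate))
    half = max(int(round(win_det * orig_rate / det_rate / 2)), 1)
    lo = max(center - half, 0)
    hi = min(center + half + 1, x.size)
    return lo + int(np.argmax(x[lo:hi]))
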