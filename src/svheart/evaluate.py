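"""Instantaneous heart rate, agreement analysis, and group statistics.

IHR is 60/IBI in beats per minute.  Agreement between the ECG- and
SV-derived IHR series is summarized Bland-Altman style: mean difference
(bias), sample SD of the differences, and 1.96-SD limits of agreement.
Differences are oriented ECG - SV, so an SV overestimate yields a negative
bias.  Group comparisons of per-measurement summaries use Shapiro-Wilk as
the normality gate, Kruskal-Wallis for distribution-free comparisons and
Welch's t-test for unequal group sizes.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .io import BeatSeries, BlandAltmanResult, IBIPair

__all__ = ["ibi_to_ihr", "bland_altman", "group_tests", "ensemble_average",
           "LOA_MULTIPLIER"]

LOA_MULTIPLIER = 1.96


def ibi_to_ihr(ibi: float | np.ndarray) -> float | np.ndarray:
    """Instantaneous heart rate (bpm) from an inter-beat interval (s)."""
    ibi_arr = np.asarray(ibi, dtype=float)
    if np.any(ibi_arr <= 0):
        raise ValueError("inter-beat intervals must be > 0")
    out = 60.0 / ibi_arr
    return float(out) if np.isscalar(ibi) or ibi_arr.ndim == 0 else out


def bland_altman(ihr_ecg: np.ndarray, ihr_sv: np.ndarray) -> BlandAltmanResult:
    """Bland-Altman agreement of two paired IHR series (bpm).

    bias = mean(ECG - SV); sd = sample SD (n-1 denominator);
    LOA = bias +- 1.96*sd.
    """
    a = np.asarray(ihr_ecg, dtype=float)
    b = np.asarray(ihr_sv, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired series must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    diff = a - b
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    return BlandAltmanResult(bias=bias, sd=sd,
                             loa_low=bias - LOA_MULTIPLIER * sd,
                             loa_high=bias + LOA_MULTIPLIER * sd,
                             n=int(a.size))


def group_tests(groups: list[np.ndarray], alpha: float = 0.05) -> dict:
    """Statistical comparison of per-measurement summary values across groups.

    For each group (e.g. the mean absolute IHR difference per measurement,
    split by gender or BMI class) the Shapiro-Wilk normality p-value is
    reported, gated at ``alpha``.  Across groups: Kruskal-Wallis H (no
    normality assumption) and, for exactly two groups, Welch's t with
    Welch-Satterthwaite degrees of freedom (robust to unequal sizes and
    variances).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    for g in arrs:
        if g.size < 3:
            raise ValueError("Shapiro-Wilk needs at least 3 values per group")

    shapiro = [stats.shapiro(g) for g in arrs]
    kw = stats.kruskal(*arrs)
    report: dict = {
        "shapiro": [{"W": float(r.statistic), "p": float(r.pvalue),
                     "normal": bool(r.pvalue > alpha)} for r in shapiro],
        "kruskal": {"H": float(kw.statistic), "p": float(kw.pvalue)},
        "alpha": alpha,
    }
    if len(arrs) == 2:
        tt = stats.ttest_ind(arrs[0], arrs[1], equal_var=False)
        v0, v1 = arrs[0].var(ddof=1), arrs[1].var(ddof=1)
        n0, n1 = arrs[0].size, arrs[1].size
        if v0 == 0 and v1 == 0:
            df = float(n0 + n1 - 2)
            t = 0.0 if np.mean(arrs[0]) == np.mean(arrs[1]) else float("inf")
            p = 1.0 if t == 0.0 else 0.0
        else:
            df = (v0 / n0 + v1 / n1) ** 2 / (
                (v0 / n0) ** 2 / (n0 - 1) + (v1 / n1) ** 2 / (n1 - 1))
            t, p = float(tt.statistic), float(tt.pvalue)
        report["welch"] = {"t": t, "p": p, "df": float(df)}
    return report


def ensemble_average(dr: np.ndarray, beats: BeatSeries,
                     rate_hz: float) -> tuple[np.ndarray, np.ndarray]:
    """Average the waveform around each beat into one template.

    Windows one median IBI long are centered on each peak; windows that
    would cross the record bounds are dropped.  The result is returned with
    the time axis normalized to [0, 1] and the amplitude min-max normalized
    (arbitrary units), as ``(t_norm, waveform)``.
    """
    x = np.asarray(dr, dtype=float)
    if len(beats) < 2:
        raise ValueError("need at least 2 beats for an ensemble average")
    if beats.unit == "samples":
        idx = np.asarray(beats.peaks, dtype=int)
    else:
        idx = np.round((beats.times_s - beats.t0) * rate_hz).astype(int)

    window = int(round(float(np.median(np.diff(idx)))))
    if window < 2:
        raise ValueError("median inter-beat interval too short")
    half = window // 2
    segments = [x[p - half:p - half + window] for p in idx
                if p - half >= 0 and p - half + window <= x.size]
    if not segments:
        raise ValueError("no beat window fits inside the record")

    mean = np.mean(segments, axis=0)
    rng_amp = np.ptp(mean)
    if rng_amp > 0:
        mean = (mean - mean.min()) / rng_amp
    t_norm = np.linspace(0.0, 1.0, window)
    return t_norm, mean


def ihr_pair_from_ibis(ibi: IBIPair) -> tuple[np.ndarray, np.ndarray]:
    """Convenience: paired IHR series (bpm) from selected IBIs."""
    return ibi_to_ihr(ibi.ibi_ecg), ibi_to_ihr(ibi.ibi_sv)
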