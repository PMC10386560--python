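"""One-to-one ECG-SV beat pairing, recall/precision, and IBI selection.

For each detected ECG R peak an acceptance interval is built from 0.4 times
the distances to its neighbouring R peaks (narrower than the half-distance
0.5 would give).  The SV peak nearest to the R peak inside the interval is
paired with it; if none lies inside, or the nearest one was already claimed
by an earlier R peak, the R peak is discarded — no fallback to the
second-nearest candidate.  Consecutive differences of the matched lists give
paired inter-beat intervals, from which any pair whose ECG interval spans a
discarded original R peak (a "false interval") is excluded from both sides.
"""

from __future__ import annotations

import numpy as np

from .io import BeatSeries, IBIPair, MatchedBeats

__all__ = ["match_beats", "compute_recall_precision", "select_ibis",
           "INTERVAL_FRACTION"]

#: Fraction of the neighbour distance defining each R peak's acceptance
#: interval (0.5 would be the half-distance; 0.4 is deliberately narrower).
INTERVAL_FRACTION = 0.4


def _interval(m: np.ndarray, j: int) -> tuple[float, float]:
    """Acceptance interval around R peak j (0-based), bounds inclusive."""
    if j == 0:
        return 0.0, m[0] + INTERVAL_FRACTION * (m[1] - m[0])
    if j < len(m) - 1:
        return (m[j] - INTERVAL_FRACTION * (m[j] - m[j - 1]),
                m[j] + INTERVAL_FRACTION * (m[j + 1] - m[j]))
    return m[j] - INTERVAL_FRACTION * (m[j] - m[j - 1]), m[j]


def match_beats(m_ecg: BeatSeries | np.ndarray,
                n_sv: BeatSeries | np.ndarray) -> MatchedBeats:
    """Pair each ECG R peak with its nearest in-interval SV peak.

    Both inputs must be strictly increasing and in the same time unit.
    An equidistant tie between two SV candidates keeps the earlier one; an R
    peak whose nearest candidate is already paired is discarded outright.
    Requires at least 2 ECG peaks (the intervals are neighbour-defined).
    """
    unit, rate = "s", 300.0
    if isinstance(m_ecg, BeatSeries):
        unit, rate = m_ecg.unit, m_ecg.rate_hz
        if isinstance(n_sv, BeatSeries) and n_sv.unit != unit:
            raise ValueError("m_ecg and n_sv must share one time unit")
    m = np.asarray(m_ecg.peaks if isinstance(m_ecg, BeatSeries) else m_ecg,
                   dtype=float)
    n = np.asarray(n_sv.peaks if isinstance(n_sv, BeatSeries) else n_sv,
                   dtype=float)
    for arr, name in ((m, "m_ecg"), (n, "n_sv")):
        if arr.size > 1 and not np.all(np.diff(arr) > 0):
            raise ValueError(f"{name} must be strictly increasing")
    if m.size < 2:
        raise ValueError("need at least 2 ECG peaks to define intervals")

    m_valid: list[float] = []
    n_valid: list[float] = []
    taken: set[int] = set()
    for j in range(m.size):
        lo, hi = _interval(m, j)
        inside = np.flatnonzero((n >= lo) & (n <= hi))
        if inside.size == 0:
            continue
        # nearest to m_j; np.argmin keeps the first (earlier) on ties
        ni = inside[int(np.argmin(np.abs(n[inside] - m[j])))]
        if ni in taken:
            continue
        taken.add(int(ni))
        m_valid.append(float(m[j]))
        n_valid.append(float(n[ni]))

    return MatchedBeats(np.asarray(m_valid), np.asarray(n_valid),
                        n_ecg_total=int(m.size), n_sv_total=int(n.size),
                        unit=unit, rate_hz=rate)


def compute_recall_precision(matched: MatchedBeats) -> tuple[float, float]:
    """recall = |Mvalid| / N_ECG;  precision = |Nvalid| / N_SV."""
    if matched.n_ecg_total == 0 or matched.n_sv_total == 0:
        raise ValueError("recall/precision undefined with zero detected peaks")
    return (len(matched.m_valid) / matched.n_ecg_total,
            len(matched.n_valid) / matched.n_sv_total)


def select_ibis(n_ecg_all: BeatSeries | np.ndarray,
                matched: MatchedBeats) -> IBIPair:
    """Drop "false intervals" and return paired IBIs in seconds.

    A candidate interval pair — consecutive differences of the matched ECG
    and SV lists — is excluded from BOTH modalities when the ECG interval
    spans at least one originally detected R peak that was discarded during
    matching (such an interval merges two true beats and would flatter the
    agreement statistics).  ``kept_index`` records the surviving positions.
    """
    all_peaks = np.asarray(
        n_ecg_all.peaks if isinstance(n_ecg_all, BeatSeries) else n_ecg_all,
        dtype=float)
    m_valid, n_valid = matched.m_valid, matched.n_valid
    if not np.all(np.isin(m_valid, all_peaks)):
        raise ValueError("every matched ECG peak must be an original R peak")

    if m_valid.size < 2:
        empty = np.array([])
        return IBIPair(empty, empty, np.array([], dtype=int))

    discarded = np.setdiff1d(all_peaks, m_valid)
    kept = [i for i in range(m_valid.size - 1)
            if not np.any((discarded > m_valid[i]) & (discarded < m_valid[i + 1]))]
    kept = np.asarray(kept, dtype=int)

    scale = 1.0 if matched.unit == "s" else 1.0 / matched.rate_hz
    return IBIPair(np.diff(m_valid)[kept] * scale,
                   np.diff(n_valid)[kept] * scale, kept)
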