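"""End-to-end composition: video + ECG -> matched IHR agreement."""

from __future__ import annotations

import numpy as np

from .config import DetectorConfig
from .detect import detect_r_peaks, detect_sv_peaks, principal_signal
from .evaluate import bland_altman, ibi_to_ihr
from .io import ECGRecord, FrameStack
from .match import compute_recall_precision, match_beats, select_ibis
from .registration import derive_dr, extract_displacement_trace


def run_pipeline(video: FrameStack, ecg: ECGRecord,
                 detector: DetectorConfig | None = None,
                 upsampling: int = 100) -> dict:
    """Run every stage on one recording and collect the results.

    Returns a dict with the displacement trace, both beat series (seconds),
    the matched pairs, the selected IBIs, the paired IHR series and the
    Bland-Altman summary plus recall/precision of the SV detector against
    the ECG beats.
    """
    detector = detector or DetectorConfig()

    trace = derive_dr(extract_displacement_trace(video, upsampling))
    principal = principal_signal(trace.dr, trace.rate_hz, detector)
    sv_beats = detect_sv_peaks(principal, trace.rate_hz, detector)
    r_peaks = detect_r_peaks(ecg)

    sv_s = sv_beats.times_s + trace.t0
    ecg_s = r_peaks.times_s
    matched = match_beats(
        np.asarray(ecg_s), np.asarray(sv_s))
    recall, precision = compute_recall_precision(matched)
    ibis = select_ibis(np.asarray(ecg_s), matched)

    out = {
        "trace": trace,
        "principal": principal,
        "sv_beats_s": sv_s,
        "r_peaks_s": ecg_s,
        "matched": matched,
        "ibis": ibis,
        "recall": recall,
        "precision": precision,
        "bland_altman": None,
    }
    if len(ibis) >= 2:
        ihr_ecg = ibi_to_ihr(ibis.ibi_ecg)
        ihr_sv = ibi_to_ihr(ibis.ibi_sv)
        out["ihr_ecg"] = ihr_ecg
        out["ihr_sv"] = ihr_sv
        out["bland_altman"] = bland_altman(ihr_ecg, ihr_sv)
    return out
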