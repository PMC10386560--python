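"""Domain containers and file readers/writers.

Time convention: timestamps are seconds as floats; peak positions are kept
as integer sample indices internally (exact arithmetic for the matching
stage) and converted to seconds at the boundaries.  Frame stacks are stored
as multi-page TIFF or 3-D ``.npy``; signals, beats and inter-beat intervals
as headed CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "FrameStack",
    "DisplacementTrace",
    "ECGRecord",
    "BeatSeries",
    "MatchedBeats",
    "IBIPair",
    "BlandAltmanResult",
    "read_frame_stack",
    "write_frame_stack",
    "read_signal_csv",
    "write_signal_csv",
    "read_beats_csv",
    "write_beats_csv",
    "read_ibi_csv",
    "write_ibi_csv",
    "align_by_timestamps",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class FrameStack:
    """A time-ordered stack of equal-shape grayscale frames.

    ``frames`` is a (n_frames, rows, cols) array of non-negative intensity;
    unsigned integer input is accepted and converted to float on access by
    the processing stages.
    """

    frames: np.ndarray
    rate_hz: float = 300.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a 3-D (n, rows, cols) array")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be > 0")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def duration_s(self) -> float:
        return len(self) / self.rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return self.t0 + np.arange(len(self)) / self.rate_hz


@dataclass
class DisplacementTrace:
    """Per-consecutive-frame-pair speckle shifts.

    ``dx``/``dy`` are (column, row) shifts in pixels, positive when the
    pattern moves toward increasing index; element k is the shift from frame
    k to frame k+1 and carries the time of frame k.  ``dr`` is the single
    orientation-independent series (principal-axis projection), left unset
    until derived.
    """

    dx: np.ndarray
    dy: np.ndarray
    rate_hz: float
    t0: float = 0.0
    dr: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.dx = np.asarray(self.dx, dtype=float)
        self.dy = np.asarray(self.dy, dtype=float)
        if self.dx.shape != self.dy.shape or self.dx.ndim != 1:
            raise ValueError("dx and dy must be equal-length 1-D arrays")
        if self.dr is not None:
            self.dr = np.asarray(self.dr, dtype=float)
            if self.dr.shape != self.dx.shape:
                raise ValueError("dr must have the same length as dx/dy")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be > 0")

    def __len__(self) -> int:
        return self.dx.size

    @property
    def times_s(self) -> np.ndarray:
        return self.t0 + np.arange(len(self)) / self.rate_hz


@dataclass
class ECGRecord:
    """A uniformly sampled single-lead ECG (amplitude in arbitrary units)."""

    samples: np.ndarray
    rate_hz: float = 300.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be 1-D")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be > 0")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def times_s(self) -> np.ndarray:
        return self.t0 + np.arange(len(self)) / self.rate_hz


@dataclass
class BeatSeries:
    """Strictly increasing cardiac peak times for one modality.

    ``unit`` records whether ``peaks`` holds integer sample indices
    (``"samples"``, relative to the record start) or seconds (``"s"``,
    absolute, i.e. including the record's t0).
    """

    peaks: np.ndarray
    modality: str  # "sv" or "ecg"
    rate_hz: float
    unit: str = "samples"
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.peaks = np.asarray(self.peaks)
        if self.peaks.ndim != 1:
            raise ValueError("peaks must be 1-D")
        if self.peaks.size > 1 and not np.all(np.diff(self.peaks) > 0):
            raise ValueError("peaks must be strictly increasing")
        if self.modality not in ("sv", "ecg"):
            raise ValueError("modality must be 'sv' or 'ecg'")
        if self.unit not in ("samples", "s"):
            raise ValueError("unit must be 'samples' or 's'")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be > 0")

    def __len__(self) -> int:
        return self.peaks.size

    @property
    def times_s(self) -> np.ndarray:
        """Peak times in seconds (absolute, including t0)."""
        if self.unit == "s":
            return np.asarray(self.peaks, dtype=float)
        return self.t0 + np.asarray(self.peaks, dtype=float) / self.rate_hz

    def to_seconds(self) -> "BeatSeries":
        return BeatSeries(self.times_s, self.modality, self.rate_hz,
                          unit="s", t0=self.t0)


@dataclass
class MatchedBeats:
    """One-to-one matched ECG/SV peak lists and the original counts."""

    m_valid: np.ndarray  # ECG peak times
    n_valid: np.ndarray  # SV peak times
    n_ecg_total: int
    n_sv_total: int
    unit: str = "s"
    rate_hz: float = 300.0

    def __post_init__(self) -> None:
        self.m_valid = np.asarray(self.m_valid, dtype=float)
        self.n_valid = np.asarray(self.n_valid, dtype=float)
        if self.m_valid.shape != self.n_valid.shape:
            raise ValueError("m_valid and n_valid must have equal length")
        for arr, name in ((self.m_valid, "m_valid"), (self.n_valid, "n_valid")):
            if arr.size > 1 and not np.all(np.diff(arr) > 0):
                raise ValueError(f"{name} must be strictly increasing")
        if len(self.m_valid) > self.n_ecg_total:
            raise ValueError("more matches than detected ECG peaks")
        if len(self.n_valid) > self.n_sv_total:
            raise ValueError("more matches than detected SV peaks")

    def __len__(self) -> int:
        return self.m_valid.size

    def times_s(self) -> tuple[np.ndarray, np.ndarray]:
        if self.unit == "s":
            return self.m_valid, self.n_valid
        return self.m_valid / self.rate_hz, self.n_valid / self.rate_hz


@dataclass
class IBIPair:
    """One-to-one mapped inter-beat intervals after false-interval exclusion.

    ``kept_index`` lists which consecutive-pair positions of the matched ECG
    list survived the exclusion of intervals that span a discarded R peak.
    """

    ibi_ecg: np.ndarray  # seconds
    ibi_sv: np.ndarray   # seconds
    kept_index: np.ndarray

    def __post_init__(self) -> None:
        self.ibi_ecg = np.asarray(self.ibi_ecg, dtype=float)
        self.ibi_sv = np.asarray(self.ibi_sv, dtype=float)
        self.kept_index = np.asarray(self.kept_index, dtype=int)
        if not (self.ibi_ecg.shape == self.ibi_sv.shape == self.kept_index.shape):
            raise ValueError("ibi_ecg, ibi_sv and kept_index must have equal length")
        if np.any(self.ibi_ecg <= 0) or np.any(self.ibi_sv <= 0):
            raise ValueError("inter-beat intervals must be > 0")

    def __len__(self) -> int:
        return self.ibi_ecg.size


@dataclass(frozen=True)
class BlandAltmanResult:
    """Mean bias, SD of differences and 1.96-SD limits of agreement (bpm)."""

    bias: float
    sd: float
    loa_low: float
    loa_high: float
    n: int

    def as_dict(self) -> dict:
        return {"bias": self.bias, "sd": self.sd, "loa_low": self.loa_low,
                "loa_high": self.loa_high, "n": self.n}


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_frame_stack(path: str | Path, rate_hz: float = 300.0,
                     t0: float = 0.0) -> FrameStack:
    """Read a frame stack from a multi-page TIFF or 3-D ``.npy`` file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        frames = tifffile.imread(path)
    elif path.suffix.lower() == ".npy":
        frames = np.load(path)
    else:
        raise ValueError(f"unsupported frame-stack format: {path.suffix}")
    frames = np.asarray(frames)
    if frames.ndim == 1:  # ragged TIFF pages load as object arrays
        raise ValueError("frames must all share one shape")
    if frames.ndim != 3:
        raise ValueError("expected a stack of 2-D grayscale frames")
    if frames.shape[0] < 2:
        raise ValueError("a frame stack needs at least 2 frames")
    return FrameStack(frames, rate_hz=rate_hz, t0=t0)


def write_frame_stack(stack: FrameStack, path: str | Path) -> None:
    """Write frames to multi-page TIFF or ``.npy`` (bit-exact round-trip)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, stack.frames, photometric="minisblack")
    elif path.suffix.lower() == ".npy":
        np.save(path, stack.frames)
    else:
        raise ValueError(f"unsupported frame-stack format: {path.suffix}")


def read_signal_csv(path: str | Path, rate_tol: float = 0.01) -> ECGRecord:
    """Read a uniformly sampled signal from CSV columns ``time_s,value``.

    The rate is inferred from the median time step; timestamps deviating
    from uniformity by more than ``rate_tol`` (fractional) are rejected.
    """
    df = pd.read_csv(path)
    for col in ("time_s", "value"):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("time_s must be strictly increasing")
    step = float(np.median(dt))
    if np.any(np.abs(dt - step) > rate_tol * step):
        raise ValueError("non-uniform sampling beyond tolerance")
    return ECGRecord(df["value"].to_numpy(dtype=float),
                     rate_hz=1.0 / step, t0=float(t[0]))


def write_signal_csv(record: ECGRecord, path: str | Path) -> None:
    pd.DataFrame({"time_s": record.times_s,
                  "value": record.samples}).to_csv(path, index=False)


def read_beats_csv(path: str | Path, modality: str,
                   rate_hz: float = 300.0) -> BeatSeries:
    """Read beat times (seconds) from a CSV with column ``peak_time_s``."""
    df = pd.read_csv(path)
    if "peak_time_s" not in df.columns:
        raise ValueError("missing column 'peak_time_s'")
    return BeatSeries(df["peak_time_s"].to_numpy(dtype=float), modality,
                      rate_hz=rate_hz, unit="s")


def write_beats_csv(beats: BeatSeries, path: str | Path) -> None:
    pd.DataFrame({"peak_time_s": beats.times_s}).to_csv(path, index=False)


def read_ibi_csv(path: str | Path) -> IBIPair:
    df = pd.read_csv(path)
    for col in ("ibi_ecg_s", "ibi_sv_s"):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
    kept = (df["kept_index"].to_numpy(dtype=int) if "kept_index" in df.columns
            else np.arange(len(df)))
    return IBIPair(df["ibi_ecg_s"].to_numpy(dtype=float),
                   df["ibi_sv_s"].to_numpy(dtype=float), kept)


def write_ibi_csv(ibi: IBIPair, path: str | Path) -> None:
    pd.DataFrame({"ibi_ecg_s": ibi.ibi_ecg, "ibi_sv_s": ibi.ibi_sv,
                  "kept_index": ibi.kept_index}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def align_by_timestamps(sv: DisplacementTrace,
                        ecg: ECGRecord) -> tuple[DisplacementTrace, ECGRecord]:
    """Crop both records to their overlapping time window.

    Offsets are resolved to the nearest sample of each record; the operation
    is idempotent.  Raises if the time windows are disjoint.
    """
    start = max(sv.t0, ecg.t0)
    end = min(sv.t0 + len(sv) / sv.rate_hz, ecg.t0 + len(ecg) / ecg.rate_hz)
    if end <= start:
        raise ValueError("records do not overlap in time")

    def crop_bounds(t0: float, rate: float, n: int) -> tuple[int, int]:
        i0 = int(round((start - t0) * rate))
        i1 = int(round((end - t0) * rate))
        return max(i0, 0), min(i1, n)

    i0, i1 = crop_bounds(sv.t0, sv.rate_hz, len(sv))
    sv_out = DisplacementTrace(
        sv.dx[i0:i1], sv.dy[i0:i1], sv.rate_hz,
        t0=sv.t0 + i0 / sv.rate_hz,
        dr=None if sv.dr is None else sv.dr[i0:i1],
    )
    j0, j1 = crop_bounds(ecg.t0, ecg.rate_hz, len(ecg))
    ecg_out = ECGRecord(ecg.samples[j0:j1], ecg.rate_hz,
                        t0=ecg.t0 + j0 / ecg.rate_hz)
    return sv_out, ecg_out
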