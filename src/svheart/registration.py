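"""Sub-pixel speckle registration and the orientation-independent series Dr.

Consecutive frame pairs are registered by upsampled cross-correlation
(coarse FFT correlation peak refined by a localized upsampled DFT), giving
(dx, dy) shifts at a resolution of 1/upsampling pixels; the default
upsampling of 100 resolves 0.01 px.  The two-axis trace is then reduced to a
single series Dr by projecting onto the first principal axis of the (dx, dy)
scatter, which is invariant (up to one global sign) under any rotation of
the camera around its optical axis.
"""

from __future__ import annotations

import warnings

import numpy as np
from skimage.registration import phase_cross_correlation

from .config import Geometry
from .io import DisplacementTrace, FrameStack

__all__ = [
    "register_pair",
    "extract_displacement_trace",
    "derive_dr",
    "tilt_to_shift",
    "translation_error_sweep",
]

DEFAULT_UPSAMPLING = 100


def register_pair(ref: np.ndarray, mov: np.ndarray,
                  upsampling: int = DEFAULT_UPSAMPLING,
                  space: str = "real") -> tuple[float, float]:
    """Estimate the (dx, dy) translation mapping ``ref`` onto ``mov``.

    Convention: dx is the column shift, dy the row shift, positive when the
    pattern moves toward increasing index.  The coarse cross-correlation
    peak is exact for integer circular shifts; the upsampled DFT refinement
    resolves 1/upsampling pixels.

    ``space="fourier"`` accepts pre-computed 2-D FFTs of both frames, which
    lets a caller reuse each frame's transform across consecutive pairs.
    """
    ref = np.asarray(ref)
    mov = np.asarray(mov)
    if ref.shape != mov.shape:
        raise ValueError("frames must share one shape")
    if upsampling < 1:
        raise ValueError("upsampling must be >= 1")
    if space == "real" and (np.ptp(ref) == 0 or np.ptp(mov) == 0):
        raise ValueError("constant frame: correlation peak undefined")
    shift, _, _ = phase_cross_correlation(
        ref, mov, upsample_factor=upsampling, space=space, normalization=None)
    # skimage returns the (row, col) shift that maps mov back onto ref;
    # the displacement of the pattern from ref to mov is its negative.
    return float(-shift[1]), float(-shift[0])


def extract_displacement_trace(stack: FrameStack,
                               upsampling: int = DEFAULT_UPSAMPLING
                               ) -> DisplacementTrace:
    """Register every consecutive frame pair of a stack.

    Element k holds the shift from frame k to frame k+1 and is assigned the
    time of frame k.  Each frame's FFT is computed once and reused as it
    passes from "moving" to "reference", halving the transform cost.
    """
    frames = stack.frames
    if frames.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    n = frames.shape[0]
    dx = np.empty(n - 1)
    dy = np.empty(n - 1)
    prev_f = np.fft.fft2(np.asarray(frames[0], dtype=float))
    for k in range(n - 1):
        if np.ptp(frames[k]) == 0 or np.ptp(frames[k + 1]) == 0:
            raise ValueError("constant frame: correlation peak undefined")
        cur_f = np.fft.fft2(np.asarray(frames[k + 1], dtype=float))
        dx[k], dy[k] = register_pair(prev_f, cur_f, upsampling, space="fourier")
        prev_f = cur_f
    return DisplacementTrace(dx, dy, rate_hz=stack.rate_hz, t0=stack.t0)


def derive_dr(trace: DisplacementTrace) -> DisplacementTrace:
    """Reduce (dx, dy) to the orientation-independent series Dr.

    Dr is the projection of each raw (dx, dy) vector onto the first
    principal axis of the centered scatter.  The global sign is fixed so
    that Dr correlates non-negatively with dx (falling back to dy when dx
    carries no variance), making the result unchanged — up to one global
    sign — under any common rotation of the shift vectors.
    """
    if len(trace) < 2:
        raise ValueError("need at least 2 samples to orient the principal axis")
    xy = np.column_stack([trace.dx, trace.dy])
    centered = xy - xy.mean(axis=0)
    if np.allclose(centered, 0.0):
        warnings.warn("zero-variance displacement scatter; Dr set to zeros")
        dr = np.zeros(len(trace))
    else:
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        axis = vt[0]
        dr = xy @ axis
        c_dx = np.dot(dr - dr.mean(), centered[:, 0])
        c_dy = np.dot(dr - dr.mean(), centered[:, 1])
        if c_dx < 0 or (c_dx == 0 and c_dy < 0):
            dr = -dr
    return DisplacementTrace(trace.dx, trace.dy, trace.rate_hz,
                             t0=trace.t0, dr=dr)


def tilt_to_shift(alpha: float | np.ndarray, geom: Geometry) -> float | np.ndarray:
    """Speckle shift (pixels) produced by a surface tilt ``alpha`` (rad).

    d = K * tan(alpha) / pixel_pitch, with K the near-focused tilt-to-shift
    magnification; shared by the simulator and any calibration utility.
    """
    if np.any(np.abs(alpha) >= np.pi / 2):
        raise ValueError("|alpha| must be < pi/2")
    return geom.K * np.tan(alpha) / geom.pixel_pitch


def translation_error_sweep(base: np.ndarray,
                            shifts: np.ndarray,
                            upsampling: int = DEFAULT_UPSAMPLING) -> float:
    """Registration self-test: max abs per-axis error over known translations.

    Each (sx, sy) in ``shifts`` is applied to ``base`` by an exact spectral
    phase ramp (no noise); the shifted frame is registered against the
    original and the worst per-axis deviation from the true shift is
    returned, in pixels.
    """
    from scipy import ndimage

    base = np.asarray(base, dtype=float)
    if np.ptp(base) == 0:
        raise ValueError("constant frame: correlation peak undefined")
    base_f = np.fft.fft2(base)
    worst = 0.0
    for sx, sy in np.atleast_2d(shifts):
        mov_f = ndimage.fourier_shift(base_f, (sy, sx))
        dx, dy = register_pair(base_f, mov_f, upsampling, space="fourier")
        worst = max(worst, abs(dx - sx), abs(dy - sy))
    return worst
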