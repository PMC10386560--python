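"""Configuration dataclasses and TOML loading.

Three parameter groups drive the pipeline:

* :class:`Geometry` — the near-focused imaging geometry that converts a
  surface tilt angle into a speckle-pattern shift on the sensor.
* :class:`DetectorConfig` — band edges and adaptive-threshold constants for
  the cardiac peak detectors.
* :class:`SimConfig` — everything the synthetic-recording generator needs.

A single TOML file with sections ``[geometry]``, ``[filters]``,
``[detector]`` and ``[simulation]`` can override any default; every constant
used anywhere in the pipeline is a key here.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Optional

__all__ = ["Geometry", "DetectorConfig", "SimConfig", "load_config"]


@dataclass(frozen=True)
class Geometry:
    """Near-focused imaging geometry.

    With the camera focal plane between the measured surface and the lens, a
    surface tilt ``alpha`` translates the imaged speckle pattern by
    ``d = K * tan(alpha)`` metres on the sensor, where the magnification
    ``K = L1 * L2 / F`` is fixed by the optical distances.  Dividing by the
    sensor pixel pitch gives the shift in pixels that the registration stage
    measures.

    Parameters
    ----------
    L1 : float
        Distance from the measured surface to the camera focal plane (m).
    L2 : float
        Distance from the focal plane to the camera lens (m).
    F : float
        Focal length of the imaging lens (m).
    pixel_pitch : float
        Sensor pixel size (m/pixel).  5.86 um is the pitch of the 2.35 MP
        CMOS sensor class this models.
    K : float, optional
        Tilt-to-shift magnification (m of speckle shift per unit tan(alpha)).
        Derived as ``L1 * L2 / F`` when not given explicitly.
    """

    L1: float = 0.8
    L2: float = 0.4
    F: float = 0.05
    pixel_pitch: float = 5.86e-6
    K: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("L1", "L2", "F", "pixel_pitch"):
            if getattr(self, name) <= 0:
                raise ValueError(f"Geometry.{name} must be > 0")
        if self.K is None:
            object.__setattr__(self, "K", self.L1 * self.L2 / self.F)
        if self.K <= 0:
            raise ValueError("Geometry.K must be > 0")

    @property
    def px_per_rad(self) -> float:
        """Small-angle sensitivity: speckle shift in pixels per radian."""
        return self.K / self.pixel_pitch


@dataclass(frozen=True)
class DetectorConfig:
    """Constants for the SV principal-signal detector and its filters.

    The principal signal is the 0.5-3 Hz band-passed Hilbert envelope of the
    displacement series; peaks are accepted by adaptive thresholding over
    5 s non-overlapping windows, with a running signal-peak level updated
    exponentially (0.125/0.875) on every accepted peak.
    """

    pre_band_hz: Optional[tuple[float, float]] = (10.0, 40.0)
    env_band_hz: tuple[float, float] = (0.5, 3.0)
    window_s: float = 5.0
    thresh_frac: float = 0.25
    refractory_s: float = 0.33
    filter_order: int = 4

    def __post_init__(self) -> None:
        if self.pre_band_hz is not None:
            lo, hi = self.pre_band_hz
            if not 0 < lo < hi:
                raise ValueError("pre_band_hz must satisfy 0 < low < high")
        lo, hi = self.env_band_hz
        if not 0 < lo < hi:
            raise ValueError("env_band_hz must satisfy 0 < low < high")
        if self.window_s <= 0:
            raise ValueError("window_s must be > 0")
        if not 0 < self.thresh_frac < 1:
            raise ValueError("thresh_frac must be in (0, 1)")
        if self.refractory_s < 0:
            raise ValueError("refractory_s must be >= 0")
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic paired speckle-video / ECG recording.

    The generator emulates one study-style measurement: a laser-speckle
    pattern translating under a cardiac + respiratory surface-tilt waveform,
    imaged at ``frame_rate_hz``, plus a single-lead ECG whose R-peak times
    are exported as ground truth.

    Amplitudes: ``cardiac_tilt_amp_rad`` = 2e-6 rad and
    ``resp_tilt_amp_rad`` = 1e-5 rad give, at the default geometry,
    speckle excursions of roughly 2 and 11 pixels — cardiac deflections well
    above the 0.01 px registration resolution and a respiratory baseline an
    order of magnitude larger, as on a breathing chest.
    """

    duration_s: float = 300.0
    frame_rate_hz: float = 300.0
    ecg_rate_hz: float = 300.0
    frame_shape: tuple[int, int] = (64, 64)
    grain_px: float = 4.0
    geometry: Geometry = field(default_factory=Geometry)
    mean_hr_bpm: float = 70.0
    sdnn_s: float = 0.03
    rsa_depth: float = 0.05
    resp_rate_hz: float = 0.25
    cardiac_tilt_amp_rad: float = 2e-6
    resp_tilt_amp_rad: float = 1e-5
    shift_axis_deg: float = 30.0
    noise_sd: float = 0.02
    ecg_noise_sd: float = 0.02
    damping: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        for name in ("frame_rate_hz", "ecg_rate_hz", "resp_rate_hz", "grain_px"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 30.0 <= self.mean_hr_bpm <= 200.0:
            raise ValueError("mean_hr_bpm must lie in [30, 200]")
        if self.sdnn_s < 0 or self.rsa_depth < 0:
            raise ValueError("sdnn_s and rsa_depth must be >= 0")
        if not 0 < self.damping <= 1:
            raise ValueError("damping must be in (0, 1]")
        if self.noise_sd < 0 or self.ecg_noise_sd < 0:
            raise ValueError("noise levels must be >= 0")


def _take(section: dict, cls) -> dict:
    """Keep only keys that are fields of ``cls``; reject unknown keys."""
    names = {f.name for f in fields(cls)}
    unknown = set(section) - names
    if unknown:
        raise KeyError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return dict(section)


def load_config(path: str | Path) -> dict:
    """Read a pipeline configuration from one TOML file.

    Recognised sections: ``[geometry]``, ``[filters]`` (band edges and filter
    order), ``[detector]`` (thresholding constants) and ``[simulation]``.
    Missing sections or keys fall back to the dataclass defaults.

    Returns a dict with keys ``geometry``, ``detector``, ``simulation``.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)

    geometry = Geometry(**_take(raw.get("geometry", {}), Geometry))

    det_kwargs = _take(raw.get("filters", {}), DetectorConfig)
    det_kwargs.update(_take(raw.get("detector", {}), DetectorConfig))
    for key in ("pre_band_hz", "env_band_hz"):
        if key in det_kwargs and det_kwargs[key] is not None:
            det_kwargs[key] = tuple(det_kwargs[key])
    detector = DetectorConfig(**det_kwargs)

    sim_kwargs = _take(raw.get("simulation", {}), SimConfig)
    if "frame_shape" in sim_kwargs:
        sim_kwargs["frame_shape"] = tuple(sim_kwargs["frame_shape"])
    if "geometry" in sim_kwargs:  # inline table overrides [geometry]
        sim_kwargs["geometry"] = Geometry(**_take(sim_kwargs["geometry"], Geometry))
    else:
        sim_kwargs["geometry"] = geometry
    simulation = SimConfig(**sim_kwargs)

    return {"geometry": geometry, "detector": detector, "simulation": simulation}
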