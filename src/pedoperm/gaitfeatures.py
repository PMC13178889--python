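"""Gait, pressure and temporal parameters plus stance time series.

Covers the scalar parameters compared between groups (step length/duration,
cadence, speed, foot angle; contact area, peak pressure, maximum force;
M-curve peak timings and the four inter-peak intervals) and the
time-normalized stance series (total force in BW%, averaged pressure,
contact area, center of pressure).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from .footio import GRAVITY, LandmarkPair, ValidationError, _KPA_TO_N_PER_MM2
from .stanceprep import StancePhase, foot_angle

__all__ = [
    "GaitParams",
    "PressureParams",
    "TemporalParams",
    "TimeSeriesSet",
    "TriphasicError",
    "basic_gait_params",
    "pressure_params",
    "detect_m_peaks",
    "temporal_params",
    "time_series_set",
]


class TriphasicError(ValidationError):
    """A total-force curve lacks the M-shaped (max-min-max) structure."""


@dataclass(frozen=True)
class GaitParams:
    """Basic gait parameters from two consecutive opposite-foot steps."""

    step_length: float  # m
    step_duration: float  # s
    cadence: float  # steps/min
    speed: float  # m/s
    foot_angle: float  # deg, mean of the two feet


@dataclass(frozen=True)
class PressureParams:
    contact_area: float  # cm^2, sensors active in any frame of the stance
    peak_pressure: float  # kPa, max over sensors and frames
    max_force: float  # N, max of the total-force series


@dataclass(frozen=True)
class TemporalParams:
    """M-curve timings: absolute peak frames, interval durations, proportions.

    Intervals 1-4 partition contact time at the three peak timings;
    proportional intervals are their share of contact time (%).  Transient
    phases are the rounded midpoints between neighboring peaks (midpoint
    rounds half down, i.e. to the earlier frame).
    """

    peak1: int
    peak2: int
    peak3: int
    intervals_ms: tuple[float, float, float, float]
    proportional_intervals: tuple[float, float, float, float]
    transient1: int
    transient2: int


def basic_gait_params(
    stances: Sequence[StancePhase],
    landmarks: Sequence[LandmarkPair],
    rate: float,
    pitch: float,
) -> GaitParams:
    """Gait parameters from two consecutive stances of opposite feet.

    Step length is the progression-axis distance between the heel-contact
    positions of the two feet (operationalized as Landmark 1 of each foot);
    step duration is the onset-to-onset interval; cadence = 60 / duration;
    speed = length / duration.  Landmarks are in plate coordinates.
    """
    if len(stances) != 2 or len(landmarks) != 2:
        raise ValidationError("exactly two stances and landmark pairs required")
    s1, s2 = stances
    if s1.onset > s2.onset:
        raise ValidationError("stances must be ordered by onset")
    if s1.side is not None and s1.side == s2.side:
        raise ValidationError("consecutive steps must be of opposite feet")
    step_length = abs(landmarks[1].l1[0] - landmarks[0].l1[0]) * pitch / 1000.0
    step_duration = (s2.onset - s1.onset) / rate
    if step_duration <= 0:
        raise ValidationError("step duration must be positive")
    angles = [
        foot_angle(lm, s.side) for s, lm in zip(stances, landmarks) if s.side is not None
    ]
    return GaitParams(
        step_length=step_length,
        step_duration=step_duration,
        cadence=60.0 / step_duration,
        speed=step_length / step_duration,
        foot_angle=float(np.mean(angles)) if angles else float("nan"),
    )


def pressure_params(stance: StancePhase, pitch: Optional[float] = None) -> PressureParams:
    """Contact area, peak pressure, maximum force of one stance.

    The contact area counts sensors activated in *any* frame of the stance
    (the per-frame variant is available from :func:`time_series_set`).
    """
    pitch = pitch if pitch is not None else stance.pitch
    active_union = stance.frames.any(axis=0)
    contact_area_cm2 = float(active_union.sum()) * pitch**2 / 100.0
    force = stance.frames.sum(axis=(1, 2)) * pitch**2 * _KPA_TO_N_PER_MM2
    return PressureParams(
        contact_area=contact_area_cm2,
        peak_pressure=float(stance.frames.max()),
        max_force=float(force.max()),
    )


def _smooth3(x: np.ndarray) -> np.ndarray:
    """Moving average, window 3, reflecting ends (extremum localization only)."""
    padded = np.concatenate([x[:1], x, x[-1:]])
    return (padded[:-2] + padded[1:-1] + padded[2:]) / 3.0


def detect_m_peaks(total_force: np.ndarray, min_sep_frac: float = 0.10) -> tuple[int, int, int]:
    """Locate Peak 1, the valley (Peak 2) and Peak 3 of an M-shaped curve.

    The two highest local maxima separated by at least ``min_sep_frac`` of
    the contact time are found on a lightly smoothed copy (window 3; reported
    indices come from the raw series); Peak 2 is the raw minimum strictly
    between them, and Peaks 1/3 the raw maxima on either side of the valley.
    A series without this triphasic structure raises :class:`TriphasicError`
    so the stance can be excluded from temporal analyses.
    """
    f = np.asarray(total_force, dtype=float)
    n = f.size
    if n < 5:
        raise TriphasicError("series too short for M-peak detection")
    if np.any(f < 0):
        raise ValidationError("total force must be non-negative")
    s = _smooth3(f)
    # interior local maxima of the smoothed series (plateau-tolerant)
    cand = [
        i
        for i in range(1, n - 1)
        if s[i] >= s[i - 1] and s[i] >= s[i + 1] and (s[i] > s[i - 1] or s[i] > s[i + 1])
    ]
    min_sep = max(1, int(round(min_sep_frac * n)))
    best: tuple[float, int, int] | None = None
    for a_idx in range(len(cand)):
        for b_idx in range(a_idx + 1, len(cand)):
            a, b = cand[a_idx], cand[b_idx]
            if b - a < min_sep:
                continue
            height = min(s[a], s[b])
            if best is None or height > best[0]:
                best = (height, a, b)
    if best is None:
        raise TriphasicError("no two separated local maxima: curve is not triphasic")
    _, a, b = best
    peak2 = a + 1 + int(np.argmin(f[a + 1 : b]))
    peak1 = int(np.argmax(f[:peak2]))
    peak3 = peak2 + 1 + int(np.argmax(f[peak2 + 1 :]))
    if not (peak1 < peak2 < peak3):
        raise TriphasicError("detected extrema are not ordered")
    if f[peak2] >= min(f[peak1], f[peak3]):
        raise TriphasicError("valley is not below both peaks")
    return peak1, peak2, peak3


def temporal_params(
    peaks: tuple[int, int, int], onset: int, offset: int, rate: float
) -> TemporalParams:
    """Interval durations and proportions from peak timings.

    ``peaks`` are absolute frame indices (same clock as onset/offset).
    Interval 1 = onset->Peak1, 2 = Peak1->Peak2, 3 = Peak2->Peak3,
    4 = Peak3->offset, in ms; proportional intervals in % of contact time.
    """
    p1, p2, p3 = peaks
    if not (onset < p1 < p2 < p3 < offset):
        raise ValidationError(
            f"require onset < peak1 < peak2 < peak3 < offset, got "
            f"{onset}, {p1}, {p2}, {p3}, {offset}"
        )
    ms = 1000.0 / rate
    bounds = np.array([onset, p1, p2, p3, offset], dtype=float)
    intervals = tuple(np.diff(bounds) * ms)
    total = (offset - onset) * ms
    props = tuple(iv / total * 100.0 for iv in intervals)
    return TemporalParams(
        peak1=p1,
        peak2=p2,
        peak3=p3,
        intervals_ms=intervals,
        proportional_intervals=props,
        transient1=(p1 + p2) // 2,
        transient2=(p2 + p3) // 2,
    )


@dataclass
class TimeSeriesSet:
    """Stance time series resampled to a fixed number of points.

    total_force is in BW%; averaged_pressure is the weight-normalized mean
    over activated sensors (kPa/N); contact_area in cm^2; COP coordinates in
    sensor units on the plate (x = mediolateral column, y = progression row).
    """

    total_force: np.ndarray
    averaged_pressure: np.ndarray
    contact_area: np.ndarray
    cop_x: np.ndarray
    cop_y: np.ndarray
    n_points: int
    n_cop_filled: int = 0
    raw: dict = field(default_factory=dict, repr=False)


def _resample(y: np.ndarray, n_points: int, clip_zero: bool = False) -> np.ndarray:
    """Natural cubic spline over normalized time [0, 1], evaluated at n_points."""
    n = y.size
    if n == 1:
        return np.full(n_points, y[0])
    t = np.linspace(0.0, 1.0, n)
    out = CubicSpline(t, y, bc_type="natural")(np.linspace(0.0, 1.0, n_points))
    if clip_zero:
        out = np.clip(out, 0.0, None)
    return out


def time_series_set(stance: StancePhase, mass_kg: float, n_points: int = 50) -> TimeSeriesSet:
    """Per-frame force/pressure/area/COP series, spline-resampled.

    COP at a frame is the pressure-weighted mean of the sensor coordinates
    (plate coordinates); frames with no activation get COP filled by linear
    interpolation from neighboring frames and are counted in
    ``n_cop_filled``.
    """
    if mass_kg <= 0:
        raise ValidationError("mass must be positive")
    frames = stance.frames
    T, H, W = frames.shape
    bw_n = mass_kg * GRAVITY
    force_n = frames.sum(axis=(1, 2)) * stance.pitch**2 * _KPA_TO_N_PER_MM2
    counts = (frames > 0).sum(axis=(1, 2))
    sums = frames.sum(axis=(1, 2))
    avg_pressure = np.divide(sums, counts, out=np.zeros(T), where=counts > 0) / bw_n
    area_cm2 = counts * stance.pitch**2 / 100.0
    r0, c0 = stance.origin
    rows = np.arange(H) + r0
    cols = np.arange(W) + c0
    with np.errstate(invalid="ignore", divide="ignore"):
        cop_y = (frames.sum(axis=2) @ rows) / sums
        cop_x = (frames.sum(axis=1) @ cols) / sums
    missing = counts == 0
    n_filled = int(missing.sum())
    if n_filled:
        good = (~missing).nonzero()[0]
        idx = np.arange(T)
        cop_y[missing] = np.interp(idx[missing], good, cop_y[good])
        cop_x[missing] = np.interp(idx[missing], good, cop_x[good])
    return TimeSeriesSet(
        total_force=_resample(force_n / bw_n * 100.0, n_points, clip_zero=True),
        averaged_pressure=_resample(avg_pressure, n_points, clip_zero=True),
        contact_area=_resample(area_cm2, n_points, clip_zero=True),
        cop_x=_resample(cop_x, n_points),
        cop_y=_resample(cop_y, n_points),
        n_points=n_points,
        n_cop_filled=n_filled,
        raw={
            "total_force_n": force_n,
            "avg_pressure_norm": avg_pressure,
            "contact_area_cm2": area_cm2,
            "cop_x": cop_x,
            "cop_y": cop_y,
        },
    )
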