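"""Stance segmentation and landmark-based foot standardization.

Each footprint in a recording is segmented into a stance phase (onset =
first frame with any non-zero sensor in the footprint region, offset =
last such frame).  A stance is then mapped onto a standard foot grid by a
rigid rotation about the heel landmark L1 (aligning the L1->L2 axis with
the progression axis) and a uniform scaling that sets the L1-L2 distance
to 100 arbitrary units (A.U.), followed by bilinear interpolation of the
pressures onto the fixed grid.  Pressures (not per-sensor forces) are
interpolated; values outside the source support are 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .footio import (
    GRAVITY,
    LandmarkPair,
    PressureRecording,
    ValidationError,
    _KPA_TO_N_PER_MM2,
)

__all__ = [
    "StancePhase",
    "LandmarkPair",
    "StandardGrid",
    "StandardizedFoot",
    "segment_stances",
    "foot_angle",
    "standardize_foot",
    "weight_normalize",
]

#: L1-L2 distance on the standard grid, by definition.
STANDARD_FOOT_LENGTH_AU = 100.0


@dataclass
class StancePhase:
    """One foot-ground contact: cropped frame sub-stack plus placement.

    ``frames`` covers frames onset..offset (inclusive) cropped to the
    footprint bounding box; ``origin`` is the (row, col) of the crop's
    top-left corner in full-plate coordinates.
    """

    onset: int
    offset: int
    frames: np.ndarray
    origin: tuple[int, int] = (0, 0)
    side: Optional[str] = None
    pitch: float = 5.0
    rate: float = 100.0

    def __post_init__(self) -> None:
        if self.onset > self.offset:
            raise ValidationError("stance onset must be <= offset")
        if self.frames.ndim != 3:
            raise ValidationError("stance frames must be T x H x W")
        if not self.frames[0].any() or not self.frames[-1].any():
            raise ValidationError("stance must have activation at onset and offset")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration_s(self) -> float:
        return (self.offset - self.onset) / self.rate

    def total_force(self) -> np.ndarray:
        """Per-frame total force (N)."""
        return self.frames.sum(axis=(1, 2)) * self.pitch**2 * _KPA_TO_N_PER_MM2

    def landmarks_local(self, lm: LandmarkPair) -> LandmarkPair:
        """Landmarks shifted from plate to crop coordinates."""
        r0, c0 = self.origin
        return LandmarkPair(
            l1=(lm.l1[0] - r0, lm.l1[1] - c0), l2=(lm.l2[0] - r0, lm.l2[1] - c0)
        )


def segment_stances(rec: PressureRecording, pad: int = 2) -> list[StancePhase]:
    """Split a recording into spatially distinct stance phases.

    Footprints are separated by 8-connected component analysis of the
    time-collapsed activation map (an automatic surrogate for the manual,
    image-based region identification of midgait protocols).  Within each
    footprint region, onset/offset are the first/last frames with any
    non-zero sensor.  Returned stances are ordered by onset.  An all-zero
    recording yields an empty list.
    """
    active = rec.frames.any(axis=0)
    if not active.any():
        return []
    labels, n = ndimage.label(active, structure=np.ones((3, 3), dtype=int))
    stances = []
    for k in range(1, n + 1):
        mask = labels == k
        rows = np.any(mask, axis=1).nonzero()[0]
        cols = np.any(mask, axis=0).nonzero()[0]
        r0, r1 = max(rows[0] - pad, 0), min(rows[-1] + pad + 1, mask.shape[0])
        c0, c1 = max(cols[0] - pad, 0), min(cols[-1] + pad + 1, mask.shape[1])
        sub = np.where(mask, rec.frames, 0.0)[:, r0:r1, c0:c1]
        active_t = sub.any(axis=(1, 2)).nonzero()[0]
        onset, offset = int(active_t[0]), int(active_t[-1])
        stances.append(
            StancePhase(
                onset=onset,
                offset=offset,
                frames=sub[onset : offset + 1].copy(),
                origin=(r0, c0),
                pitch=rec.pitch,
                rate=rec.rate,
            )
        )
    stances.sort(key=lambda s: s.onset)
    return stances


def foot_angle(lm: LandmarkPair, side: str) -> float:
    """Foot angle in degrees, external rotation positive for either foot.

    The angle is between the L1->L2 line and the progression axis,
    computed as atan2(mediolateral, progression).  The column axis points
    toward the lateral side of a right foot, so the raw angle is
    sign-flipped for left feet to make outward (lateral) deviation of the
    second toe positive bilaterally.
    """
    if side not in ("left", "right"):
        raise ValidationError(f"side must be 'left' or 'right', got {side!r}")
    dr = lm.l2[0] - lm.l1[0]
    dc = lm.l2[1] - lm.l1[1]
    if dr == 0 and dc == 0:
        raise ValidationError("coincident landmarks")
    ang = math.degrees(math.atan2(dc, dr))
    return -ang if side == "left" else ang


@dataclass(frozen=True)
class StandardGrid:
    """The fixed foot coordinate grid used for group-level pooling.

    Progression coordinate (A.U.): 0 at L1, 100 at L2; rows span
    ``[-l1_margin_au, n_rows*spacing - l1_margin_au)``.  The mediolateral
    coordinate is 0 at the grid's center column.  The default 120 x 60 grid
    at 1 A.U. spacing places L1 at row 10 and leaves margin rows for toes
    extending past L2.
    """

    n_rows: int = 120
    n_cols: int = 60
    spacing: float = 1.0
    l1_margin_au: float = 10.0

    @classmethod
    def with_shape(cls, n_rows: int, n_cols: int) -> "StandardGrid":
        """A coarser/finer grid covering the same physical extent as default."""
        spacing = 120.0 / n_rows
        return cls(n_rows=n_rows, n_cols=n_cols, spacing=spacing,
                   l1_margin_au=10.0)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def coords_au(self) -> tuple[np.ndarray, np.ndarray]:
        """(progression, mediolateral) A.U. coordinates of the grid cells."""
        prog = np.arange(self.n_rows) * self.spacing - self.l1_margin_au
        ml = (np.arange(self.n_cols) - (self.n_cols - 1) / 2.0) * self.spacing
        return prog, ml

    def mesh_au(self) -> tuple[np.ndarray, np.ndarray]:
        prog, ml = self.coords_au()
        return np.meshgrid(prog, ml, indexing="ij")

    def l1_au(self) -> tuple[float, float]:
        return (0.0, 0.0)

    def l2_au(self) -> tuple[float, float]:
        return (STANDARD_FOOT_LENGTH_AU, 0.0)


@dataclass
class StandardizedFoot:
    """Pressure data resampled onto the standard foot grid.

    ``grid_values`` is (H', W') for a single timing or (T, H', W') for a
    per-frame stack, in kPa (or kPa/N once weight-normalized).  ``mm_per_au``
    records the physical size of one A.U. for this foot, so integrals can be
    compared with the sensor-grid originals.
    """

    grid_values: np.ndarray
    grid: StandardGrid
    mm_per_au: float
    weight_normalized: bool = False
    side: Optional[str] = None
    id: str = ""
    landmarks_au: tuple[tuple[float, float], tuple[float, float]] = field(
        default_factory=lambda: ((0.0, 0.0), (STANDARD_FOOT_LENGTH_AU, 0.0))
    )

    def landmark_distance_au(self) -> float:
        (r1, c1), (r2, c2) = self.landmarks_au
        return float(np.hypot(r2 - r1, c2 - c1))

    def total_force(self) -> np.ndarray:
        """Total force per frame (N), using the A.U. cell's physical area."""
        cell_mm2 = (self.grid.spacing * self.mm_per_au) ** 2
        vals = self.grid_values if self.grid_values.ndim == 3 else self.grid_values[None]
        return vals.sum(axis=(1, 2)) * cell_mm2 * _KPA_TO_N_PER_MM2


def _bilinear_sample(frames: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Sample a (T, H, W) stack at fractional (row, col) points, 0 outside.

    The interpolation weights are computed once and reused across frames.
    Returns (T, n_points).
    """
    T, H, W = frames.shape
    r0 = np.floor(rows).astype(int)
    c0 = np.floor(cols).astype(int)
    fr = rows - r0
    fc = cols - c0
    out = np.zeros((T, rows.size))
    for dr in (0, 1):
        for dc in (0, 1):
            rr = r0 + dr
            cc = c0 + dc
            w = (fr if dr else 1 - fr) * (fc if dc else 1 - fc)
            valid = (rr >= 0) & (rr < H) & (cc >= 0) & (cc < W) & (w > 0)
            if valid.any():
                out[:, valid] += w[valid] * frames[:, rr[valid], cc[valid]]
    return out


def standardize_foot(
    stance: StancePhase,
    lm: LandmarkPair,
    grid: StandardGrid | None = None,
    mirror: bool = False,
    weight_n: Optional[float] = None,
) -> StandardizedFoot:
    """Map all frames of a stance onto the standard foot grid.

    The transform rotates the sensor data about L1 so the L1->L2 line is
    parallel to the progression axis, scales uniformly so |L1L2| = 100 A.U.,
    and bilinearly resamples the pressures onto ``grid``.  ``mirror=True``
    flips the mediolateral axis (used to pool left feet with right feet).
    ``weight_n`` (body weight in N) additionally divides the pressures.

    Landmarks are given in plate coordinates and must fall inside the
    stance's cropped region.
    """
    grid = grid or StandardGrid()
    local = stance.landmarks_local(lm)
    H, W = stance.frames.shape[1:]
    for name, (r, c) in (("L1", local.l1), ("L2", local.l2)):
        if not (-1 <= r <= H and -1 <= c <= W):
            raise ValidationError(f"landmark {name} outside the stance region")
    length = local.length
    theta = math.atan2(local.l2[1] - local.l1[1], local.l2[0] - local.l1[0])
    scale = length / STANDARD_FOOT_LENGTH_AU  # sensor units per A.U.
    prog, ml = grid.mesh_au()
    if mirror:
        ml = -ml
    cos_t, sin_t = math.cos(theta), math.sin(theta)
    # inverse map: standard (prog, ml) -> sensor (row, col), rotation about L1
    rows = local.l1[0] + scale * (cos_t * prog - sin_t * ml)
    cols = local.l1[1] + scale * (sin_t * prog + cos_t * ml)
    sampled = _bilinear_sample(stance.frames, rows.ravel(), cols.ravel())
    values = sampled.reshape(stance.n_frames, *grid.shape)
    if weight_n is not None:
        if weight_n <= 0:
            raise ValidationError("body weight must be positive")
        values = values / weight_n
    return StandardizedFoot(
        grid_values=values,
        grid=grid,
        mm_per_au=stance.pitch * scale,
        weight_normalized=weight_n is not None,
        side=stance.side,
    )


def weight_normalize(
    values: np.ndarray, mass_kg: float, as_bw_percent: bool = False
) -> np.ndarray:
    """Divide pressures or forces by body weight (mass x 9.8 N).

    With ``as_bw_percent=True`` the result is scaled by 100, the BW%
    convention for total-force series (637 N at 65 kg -> 100 BW%).
    """
    if mass_kg <= 0:
        raise ValidationError("mass must be positive")
    out = np.asarray(values, dtype=float) / (mass_kg * GRAVITY)
    return out * 100.0 if as_bw_percent else out
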