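"""Data model and readers/writers for plantar-pressure recordings.

A recording is a time-ordered stack of frames from a regular grid of
capacitive pressure sensors (units kPa).  The module fixes the instrument
constants of a 5 mm pitch footplate sampling at 100 Hz with a 10 kPa
detection threshold, and defines a plain-text frame-stack format plus CSV
participant manifests.

Grid orientation convention: the row index increases along the walking
progression axis (the long side of the footplate); the column index is
mediolateral.  Indexing is 0-based throughout.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

#: Sensor spacing of the footplate grid (mm).
SENSOR_PITCH_MM = 5.0
#: Area covered by one sensor (mm^2).
SENSOR_AREA_MM2 = SENSOR_PITCH_MM**2
#: Sampling frequency (Hz).
SAMPLING_RATE_HZ = 100.0
#: Hardware detection threshold (kPa); pressures below it read as 0.
DETECTION_THRESHOLD_KPA = 10.0
#: Gravitational acceleration used for body-weight normalization (m/s^2).
GRAVITY = 9.8

_KPA_TO_N_PER_MM2 = 1e-3  # 1 kPa = 1000 Pa = 1e-3 N/mm^2


class FormatError(ValueError):
    """A file does not conform to the frame-stack or manifest format."""


class ValidationError(ValueError):
    """Input data violate a domain invariant."""


def frame_force(frame: np.ndarray, area_mm2: float = SENSOR_AREA_MM2) -> float:
    """Total vertical force of one frame in newtons.

    Each sensor reports pressure in kPa over ``area_mm2`` of contact, so the
    frame total is ``sum(p) * area * 1e-3`` N.
    """
    return float(np.sum(frame) * area_mm2 * _KPA_TO_N_PER_MM2)


@dataclass
class PressureRecording:
    """Stack of pressure frames with the physical metadata of the plate.

    Parameters
    ----------
    frames
        Array of shape (T, H, W), pressures in kPa.  Values below
        ``threshold`` are zeroed on construction, mirroring the hardware
        detection threshold, so "activated sensor" is unambiguous downstream.
    pitch
        Sensor spacing in mm (standardized data may use other units).
    rate
        Sampling frequency in Hz.
    id
        Participant/trial identifier.
    threshold
        Detection threshold in the same units as ``frames``; pass 0 to keep
        sub-threshold values (e.g. for interpolated, standardized data).
    """

    frames: np.ndarray
    pitch: float = SENSOR_PITCH_MM
    rate: float = SAMPLING_RATE_HZ
    id: str = ""
    threshold: float = DETECTION_THRESHOLD_KPA

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        if frames.ndim != 3 or min(frames.shape) < 1:
            raise ValidationError(
                f"frames must be a T x H x W stack with all dims >= 1, got shape {frames.shape}"
            )
        if self.pitch <= 0 or self.rate <= 0:
            raise ValidationError("pitch and rate must be positive")
        neg = np.argwhere(frames < 0)
        if neg.size:
            t, r, c = neg[0]
            raise ValidationError(
                f"negative pressure at frame {t}, sensor ({r}, {c})"
            )
        if self.threshold > 0:
            frames[frames < self.threshold] = 0.0
        self.frames = frames

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def sensor_area_mm2(self) -> float:
        return self.pitch**2

    def total_force(self) -> np.ndarray:
        """Per-frame total vertical force (N)."""
        return self.frames.sum(axis=(1, 2)) * self.sensor_area_mm2() * _KPA_TO_N_PER_MM2


_HEADER_FIELDS = ("pitch_mm", "rate_hz", "n_frames", "n_rows", "n_cols")


def write_recording(rec: PressureRecording, path: str | Path) -> Path:
    """Serialize a recording to the plain-text frame-stack format.

    The format is a key/value header (pitch_mm, rate_hz, n_frames, n_rows,
    n_cols, threshold_kpa, id) followed by one whitespace-separated numeric
    matrix per frame.  Writing the same recording twice yields byte-identical
    files.
    """
    path = Path(path)
    T, H, W = rec.frames.shape
    lines = [
        f"pitch_mm: {rec.pitch:.10g}",
        f"rate_hz: {rec.rate:.10g}",
        f"n_frames: {T}",
        f"n_rows: {H}",
        f"n_cols: {W}",
        f"threshold_kpa: {rec.threshold:.10g}",
        f"id: {rec.id}",
    ]
    for t in range(T):
        lines.append(f"# frame {t}")
        for row in rec.frames[t]:
            # %.17g survives the float64 round trip exactly
            lines.append(" ".join(f"{v:.17g}" for v in row))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_recording(path: str | Path) -> PressureRecording:
    """Read a frame-stack file written by :func:`write_recording`.

    Values below the declared detection threshold are zeroed; a negative
    pressure raises :class:`ValidationError` naming the frame.
    """
    path = Path(path)
    header: dict[str, str] = {}
    values: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if ":" in line and not _is_numeric_row(line):
                key, _, val = line.partition(":")
                header[key.strip()] = val.strip()
            else:
                values.extend(float(tok) for tok in line.split())
    for fld in _HEADER_FIELDS:
        if fld not in header:
            raise FormatError(f"missing header field '{fld}' in {path}")
    try:
        pitch = float(header["pitch_mm"])
        rate = float(header["rate_hz"])
        T = int(header["n_frames"])
        H = int(header["n_rows"])
        W = int(header["n_cols"])
    except ValueError as exc:
        raise FormatError(f"invalid header value in {path}: {exc}") from exc
    threshold = float(header.get("threshold_kpa", DETECTION_THRESHOLD_KPA))
    if len(values) != T * H * W:
        raise FormatError(
            f"expected {T * H * W} values ({T}x{H}x{W}), found {len(values)} in {path}"
        )
    frames = np.array(values, dtype=float).reshape(T, H, W)
    return PressureRecording(
        frames, pitch=pitch, rate=rate, id=header.get("id", ""), threshold=threshold
    )


def _is_numeric_row(line: str) -> bool:
    tok = line.split(None, 1)[0]
    try:
        float(tok)
    except ValueError:
        return False
    return True


def file_digest(path: str | Path) -> str:
    """SHA-256 hex digest of a file's bytes (for determinism checks)."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass(frozen=True)
class LandmarkPair:
    """Two manually identified anatomical landmarks in sensor coordinates.

    L1 is the most posterior point of the heel; L2 the tip of the second
    toe.  Coordinates are (row, col) in sensor units, row = progression.
    """

    l1: tuple[float, float]
    l2: tuple[float, float]

    def __post_init__(self) -> None:
        if tuple(self.l1) == tuple(self.l2):
            raise ValidationError("landmarks L1 and L2 must be distinct")

    @property
    def length(self) -> float:
        """Euclidean L1-L2 distance in sensor units."""
        return float(np.hypot(self.l2[0] - self.l1[0], self.l2[1] - self.l1[1]))


@dataclass
class ParticipantRecord:
    """One participant: demographics, recording, per-foot landmarks."""

    id: str
    sex: str
    age: float
    height_cm: float
    weight_kg: float
    bmi: Optional[float] = None
    recording: Optional[PressureRecording] = None
    recording_path: Optional[str] = None
    landmarks: dict[str, LandmarkPair] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValidationError(f"sex must be 'female' or 'male', got {self.sex!r}")
        expected = self.weight_kg / (self.height_cm / 100.0) ** 2
        if self.bmi is None:
            self.bmi = round(expected, 2)
        elif abs(self.bmi - expected) > 0.1:
            raise ValidationError(
                f"participant {self.id}: bmi {self.bmi} inconsistent with "
                f"height/weight (expected {expected:.2f})"
            )

    @property
    def body_weight_n(self) -> float:
        return self.weight_kg * GRAVITY


@dataclass
class CohortManifest:
    """A cohort: list of participants plus free-text provenance."""

    participants: list[ParticipantRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [p.id for p in self.participants]
        if len(set(ids)) != len(ids):
            raise ValidationError("participant ids must be unique")

    def by_sex(self, sex: str) -> list[ParticipantRecord]:
        return [p for p in self.participants if p.sex == sex]


_LM_COLS = [
    f"{side}_{lm}_{ax}" for side in ("left", "right") for lm in ("l1", "l2") for ax in ("row", "col")
]


def write_manifest(manifest: CohortManifest, path: str | Path) -> Path:
    """Write a cohort manifest as CSV, one row per participant."""
    rows = []
    for p in manifest.participants:
        row: dict[str, object] = {
            "id": p.id,
            "sex": p.sex,
            "age": p.age,
            "height_cm": p.height_cm,
            "weight_kg": p.weight_kg,
            "bmi": p.bmi,
            "recording": p.recording_path or "",
        }
        for side in ("left", "right"):
            lm = p.landmarks.get(side)
            for name, pt in (("l1", lm.l1 if lm else (np.nan,) * 2), ("l2", lm.l2 if lm else (np.nan,) * 2)):
                row[f"{side}_{name}_row"], row[f"{side}_{name}_col"] = pt
        rows.append(row)
    df = pd.DataFrame(rows)
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_manifest(path: str | Path, load_recordings: bool = False) -> CohortManifest:
    """Read a manifest CSV; optionally load the referenced recordings."""
    path = Path(path)
    df = pd.read_csv(path)
    required = {"id", "sex", "age", "height_cm", "weight_kg"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"manifest missing columns: {sorted(missing)}")
    participants = []
    for _, row in df.iterrows():
        landmarks = {}
        for side in ("left", "right"):
            cols = [f"{side}_{lm}_{ax}" for lm in ("l1", "l2") for ax in ("row", "col")]
            if all(c in df.columns for c in cols) and not any(pd.isna(row[c]) for c in cols):
                landmarks[side] = LandmarkPair(
                    l1=(row[cols[0]], row[cols[1]]), l2=(row[cols[2]], row[cols[3]])
                )
        rec_path = row.get("recording", "") or None
        rec = None
        if load_recordings and rec_path:
            p = Path(rec_path)
            if not p.is_absolute():
                p = path.parent / p
            rec = read_recording(p)
        participants.append(
            ParticipantRecord(
                id=str(row["id"]),
                sex=row["sex"],
                age=float(row["age"]),
                height_cm=float(row["height_cm"]),
                weight_kg=float(row["weight_kg"]),
                bmi=float(row["bmi"]) if "bmi" in df.columns and not pd.isna(row["bmi"]) else None,
                recording=rec,
                recording_path=str(rec_path) if rec_path else None,
                landmarks=landmarks,
            )
        )
    return CohortManifest(participants=participants)
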