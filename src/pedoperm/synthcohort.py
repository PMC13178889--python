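"""Synthetic two-group plantar-pressure cohorts with known ground truth.

The generator emulates a barefoot midgait trial: one valid recording of two
consecutive steps (one per foot) per participant, on a 5 mm / 100 Hz sensor
grid.  The footprint is a mixture of smooth pressure lobes (heel, lateral
midfoot, five metatarsal heads, toes) defined on the standard foot grid and
warped into sensor coordinates by the subject's foot length, foot angle and
plate position.  Per-zone amplitude envelopes shift the load from heel to
forefoot across the stance — so the center of pressure progresses forward —
while the frame-wise total force follows a triphasic (M-shaped) waveform
whose peak timings, and hence the four inter-peak intervals, are exact
ground truth.

Group structure: sample sizes, anthropometrics, gait parameters and
interval proportions default to the study conditions of a 68-female /
24-male healthy adult cohort.  Localized group effects can be injected into
preset anatomical regions (calcaneus, second metatarsal head) in
weight-normalized pressure units.

The generator is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
import yaml
from scipy.interpolate import CubicHermiteSpline

from .footio import (
    CohortManifest,
    GRAVITY,
    LandmarkPair,
    ParticipantRecord,
    PressureRecording,
    SAMPLING_RATE_HZ,
    SENSOR_PITCH_MM,
    ValidationError,
)
from .stanceprep import StandardGrid

__all__ = [
    "SynthCohortConfig",
    "RegionalEffect",
    "StanceProfile",
    "StanceTruth",
    "CohortTruth",
    "m_wave",
    "region_mask",
    "inject_regional_effect",
    "generate_stance",
    "generate_cohort",
    "simulate_group_maps",
    "effect_delta_for_d",
    "REGION_PRESETS",
]

# ---------------------------------------------------------------------------
# Footprint model: pressure lobes on the standard grid (canonical right foot,
# progression 0 = posterior heel, 100 = tip of second toe; mediolateral
# coordinate positive toward the lateral border).
# Each zone: (name, center_prog, center_ml, radius_prog, radius_ml, amplitude)

_ZONES = (
    ("heel", 14.0, 0.0, 13.0, 8.5, 1.00),
    ("midfoot", 40.0, 7.0, 16.0, 6.0, 0.35),
    ("mt1", 66.0, -11.0, 7.0, 5.5, 0.85),
    ("mt2", 69.0, -3.0, 7.0, 4.5, 1.00),
    ("mt3", 69.0, 3.0, 6.5, 4.5, 0.80),
    ("mt4", 67.5, 9.0, 6.0, 4.5, 0.55),
    ("mt5", 65.0, 14.0, 5.5, 4.5, 0.45),
    ("hallux", 86.0, -8.0, 9.0, 6.0, 0.90),
    ("toe2", 94.0, 0.0, 5.5, 3.5, 0.50),
    ("toes345", 87.0, 8.0, 6.0, 7.0, 0.35),
)

_ZONE_GROUPS = {  # which temporal envelope drives each zone
    "heel": "early",
    "midfoot": "mid",
    "mt1": "late",
    "mt2": "late",
    "mt3": "late",
    "mt4": "late",
    "mt5": "late",
    "hallux": "toeoff",
    "toe2": "toeoff",
    "toes345": "toeoff",
}

#: Anatomical region presets on the standard grid: (prog, ml, r_prog, r_ml).
REGION_PRESETS = {
    "calcaneus": (14.0, 0.0, 11.0, 8.0),
    "second_metatarsal": (69.0, -3.0, 7.0, 4.5),
}


def region_mask(region: str, grid: StandardGrid | None = None) -> np.ndarray:
    """Boolean pixel mask of a preset anatomical region on the standard grid."""
    grid = grid or StandardGrid()
    if region not in REGION_PRESETS:
        raise ValidationError(
            f"unknown region {region!r}; presets: {sorted(REGION_PRESETS)}"
        )
    cu, cv, ru, rv = REGION_PRESETS[region]
    prog, ml = grid.mesh_au()
    return ((prog - cu) / ru) ** 2 + ((ml - cv) / rv) ** 2 <= 1.0


def inject_regional_effect(
    template: np.ndarray, region: str | np.ndarray, delta: float, grid: StandardGrid | None = None
) -> np.ndarray:
    """Raise the mean pressure inside a region by exactly ``delta``.

    ``region`` is a preset name or a boolean mask on the template's grid;
    pixels outside the region are untouched.
    """
    mask = region_mask(region, grid) if isinstance(region, str) else np.asarray(region, bool)
    if mask.shape != template.shape[-2:]:
        raise ValidationError(
            f"mask shape {mask.shape} does not match template {template.shape[-2:]}"
        )
    if not np.isfinite(delta):
        raise ValidationError("effect delta must be finite")
    return template + delta * mask


@lru_cache(maxsize=8)
def _zone_shapes(grid: StandardGrid) -> tuple[list[str], np.ndarray]:
    """Super-Gaussian lobes per zone, each scaled to unit peak, on ``grid``."""
    prog, ml = grid.mesh_au()
    names, shapes = [], []
    for name, cu, cv, ru, rv, amp in _ZONES:
        d2 = ((prog - cu) / ru) ** 2 + ((ml - cv) / rv) ** 2
        shapes.append(amp * np.exp(-(d2**1.4)))
        names.append(name)
    return names, np.stack(shapes)


def _zone_envelopes(tau: np.ndarray, t1: float, t2: float, t3: float) -> dict[str, np.ndarray]:
    """Temporal activation envelopes for the four zone groups."""
    # small floors keep every zone in modest contact through the stance
    # (forefoot touches down well before mid-stance in level walking)
    return {
        "early": 0.03 + np.exp(-(((tau - 0.75 * t1) / 0.16) ** 2)),
        "mid": 0.05 + 0.5 * np.exp(-(((tau - t2) / 0.22) ** 2)),
        "late": 0.07 + np.exp(-(((tau - 0.95 * t3) / 0.20) ** 2)),
        "toeoff": 0.015 + 0.55 * np.exp(-(((tau - min(t3 + 0.06, 0.97)) / 0.14) ** 2)),
    }


def m_wave(
    tau: np.ndarray,
    t1: float,
    t2: float,
    t3: float,
    peak1: float,
    valley: float,
    peak3: float,
    boundary: float,
) -> np.ndarray:
    """Triphasic total-force waveform (arbitrary amplitude units).

    A piecewise cubic Hermite curve through (0, boundary), (t1, peak1),
    (t2, valley), (t3, peak3), (1, boundary) with zero slope at the three
    interior knots, so the curve's local extrema fall exactly at t1 < t2 < t3
    (loading peak, mid-stance valley, push-off peak).
    """
    if not (0 < t1 < t2 < t3 < 1):
        raise ValidationError(f"peak times must satisfy 0 < t1 < t2 < t3 < 1, got {(t1, t2, t3)}")
    if not (valley < peak1 and valley > boundary and valley < peak3):
        raise ValidationError("require boundary < valley < min(peak1, peak3)")
    x = np.array([0.0, t1, t2, t3, 1.0])
    y = np.array([boundary, peak1, valley, peak3, boundary])
    dydx = np.array(
        [1.2 * (peak1 - boundary) / t1, 0.0, 0.0, 0.0, -1.2 * (peak3 - boundary) / (1 - t3)]
    )
    return CubicHermiteSpline(x, y, dydx)(np.asarray(tau, dtype=float))


@dataclass(frozen=True)
class StanceProfile:
    """Per-stance generative parameters."""

    side: str = "right"
    foot_length_mm: float = 234.0  # L1-L2 distance
    foot_angle_deg: float = 4.0  # external rotation positive
    body_mass_kg: float = 58.0
    contact_time_s: float = 0.67
    interval_props: tuple[float, float, float, float] = (26.4, 24.0, 24.8, 24.9)
    peak_force_bw: float = 110.0  # BW% at the loading peak
    valley_force_bw: float = 75.0
    boundary_force_frac: float = 0.15  # of peak, at onset/offset
    zone_gains: Optional[dict[str, float]] = None
    noise_sd: float = 0.05  # per-sensor multiplicative log-normal sigma
    pitch: float = SENSOR_PITCH_MM
    rate: float = SAMPLING_RATE_HZ

    def peak_times(self) -> tuple[float, float, float]:
        # printed interval proportions can miss 100 by rounding (e.g. 100.1);
        # accept within 0.5 and renormalize so the partition is exact
        p = self.interval_props
        total = sum(p)
        if abs(total - 100.0) > 0.5:
            raise ValidationError(f"interval proportions must sum to 100, got {total}")
        return (p[0] / total, (p[0] + p[1]) / total, (p[0] + p[1] + p[2]) / total)


@dataclass
class StanceTruth:
    """Ground truth emitted alongside a generated stance."""

    onset: int
    offset: int
    peak1: int
    peak2: int
    peak3: int
    landmarks: LandmarkPair
    side: str
    interval_props: tuple[float, float, float, float]
    peak_force_bw: float

    def __post_init__(self) -> None:
        if not (self.onset < self.peak1 < self.peak2 < self.peak3 < self.offset):
            raise ValidationError("truth requires onset < peak1 < peak2 < peak3 < offset")


def _emit_stance(
    profile: StanceProfile,
    rng: np.random.Generator,
    grid_shape: tuple[int, int],
    l1_pos: tuple[float, float],
    effects: Sequence[tuple[np.ndarray, float]] = (),
    std_grid: StandardGrid | None = None,
) -> tuple[np.ndarray, StanceTruth]:
    """Render one stance onto a sensor grid of ``grid_shape``.

    ``l1_pos`` is the heel landmark's (row, col) in sensor units; ``effects``
    are (standard-grid mask, weight-normalized delta in kPa/N) pairs whose
    injected offset ramps with the force waveform (full magnitude at the
    loading peak).
    """
    std_grid = std_grid or StandardGrid()
    names, shapes = _zone_shapes(std_grid)
    t1, t2, t3 = profile.peak_times()
    n_frames = int(round(profile.contact_time_s * profile.rate)) + 1
    tau = np.arange(n_frames) / (n_frames - 1)
    env = _zone_envelopes(tau, t1, t2, t3)
    gains = profile.zone_gains or {}
    gain_vec = np.array([gains.get(nm, 1.0) for nm in names])
    env_mat = np.stack([env[_ZONE_GROUPS[nm]] for nm in names])  # (Z, T)
    weights = gain_vec[:, None] * env_mat
    weights = weights / weights.sum(axis=0, keepdims=True)  # (Z, T), sums to 1

    # warp each (static) zone shape from the standard grid to the sensor grid
    s = profile.foot_length_mm / 100.0 / profile.pitch  # sensor cells per A.U.
    theta = np.deg2rad(profile.foot_angle_deg)
    if profile.side == "left":
        theta = -theta
    H, W = grid_shape
    rr, cc = np.meshgrid(np.arange(H, dtype=float), np.arange(W, dtype=float), indexing="ij")
    dr = (rr - l1_pos[0]) / s
    dc = (cc - l1_pos[1]) / s
    u = np.cos(theta) * dr + np.sin(theta) * dc
    v = -np.sin(theta) * dr + np.cos(theta) * dc
    if profile.side == "left":
        v = -v
    gi = (u + std_grid.l1_margin_au) / std_grid.spacing
    gj = v / std_grid.spacing + (std_grid.n_cols - 1) / 2.0
    sensor_zones = np.stack([_sample_grid(sh, gi, gj) for sh in shapes])  # (Z, H, W)

    # unit total force per zone in sensor space
    cell_m2 = (profile.pitch / 1000.0) ** 2
    integrals = sensor_zones.sum(axis=(1, 2)) * cell_m2
    if np.any(integrals <= 0):
        raise ValidationError("footprint falls outside the sensor grid")
    sensor_zones /= integrals[:, None, None]

    bw_n = profile.body_mass_kg * GRAVITY
    f_bw = m_wave(
        tau, t1, t2, t3,
        profile.peak_force_bw, profile.valley_force_bw, profile.peak_force_bw * 0.98,
        profile.boundary_force_frac * profile.peak_force_bw,
    )
    force_n = f_bw / 100.0 * bw_n
    # frames in kPa: force x mixture (Pa) / 1000
    frames = np.einsum("t,zt,zhw->thw", force_n, weights, sensor_zones) / 1000.0

    if effects:
        ramp = f_bw / f_bw.max()
        for mask, delta in effects:
            sensor_mask = _sample_grid(mask.astype(float), gi, gj)
            frames += (delta * bw_n) * ramp[:, None, None] * sensor_mask[None]

    if profile.noise_sd > 0:
        sd = profile.noise_sd
        noise = np.exp(rng.normal(-0.5 * sd**2, sd, size=frames.shape))
        frames = frames * noise
    frames[frames < 0] = 0.0

    # landmarks in sensor coordinates via the forward transform
    sgn = -1.0 if profile.side == "left" else 1.0
    l2 = (
        l1_pos[0] + s * np.cos(theta) * 100.0,
        l1_pos[1] + s * np.sin(theta) * 100.0,
    )
    lm = LandmarkPair(l1=tuple(l1_pos), l2=l2)

    thresholded = np.where(frames >= 10.0, frames, 0.0)
    active_t = thresholded.any(axis=(1, 2)).nonzero()[0]
    if active_t.size == 0:
        raise ValidationError("generated stance entirely below detection threshold")
    truth = StanceTruth(
        onset=int(active_t[0]),
        offset=int(active_t[-1]),
        peak1=int(round(t1 * (n_frames - 1))),
        peak2=int(round(t2 * (n_frames - 1))),
        peak3=int(round(t3 * (n_frames - 1))),
        landmarks=lm,
        side=profile.side,
        interval_props=profile.interval_props,
        peak_force_bw=profile.peak_force_bw,
    )
    return frames, truth


def _sample_grid(arr: np.ndarray, gi: np.ndarray, gj: np.ndarray) -> np.ndarray:
    """Bilinear sample of a 2D array at fractional indices, 0 outside."""
    H, W = arr.shape
    i0 = np.floor(gi).astype(int)
    j0 = np.floor(gj).astype(int)
    fi, fj = gi - i0, gj - j0
    out = np.zeros(gi.shape)
    for di in (0, 1):
        for dj in (0, 1):
            ii, jj = i0 + di, j0 + dj
            w = (fi if di else 1 - fi) * (fj if dj else 1 - fj)
            valid = (ii >= 0) & (ii < H) & (jj >= 0) & (jj < W)
            if valid.any():
                out[valid] += (w * np.where(valid, arr[np.clip(ii, 0, H - 1), np.clip(jj, 0, W - 1)], 0.0))[valid]
    return out


def generate_stance(
    profile: StanceProfile, seed: Optional[int] = None, rng: Optional[np.random.Generator] = None
) -> tuple[PressureRecording, StanceTruth]:
    """Generate a single stance as a standalone recording plus ground truth."""
    rng = rng if rng is not None else np.random.default_rng(seed)
    s = profile.foot_length_mm / 100.0 / profile.pitch
    n_rows = int(np.ceil(s * 120)) + 10
    n_cols = int(np.ceil(s * 50)) + 10
    l1 = (s * 11 + 5, (n_cols - 1) / 2.0)
    frames, truth = _emit_stance(profile, rng, (n_rows, n_cols), l1)
    rec = PressureRecording(frames, pitch=profile.pitch, rate=profile.rate, id="stance")
    return rec, truth


@dataclass(frozen=True)
class RegionalEffect:
    """A localized group offset in weight-normalized pressure (kPa/N)."""

    region: str
    delta: float
    group: str = "female"

    def __post_init__(self) -> None:
        if self.region not in REGION_PRESETS:
            raise ValidationError(f"unknown region preset {self.region!r}")
        if not np.isfinite(self.delta):
            raise ValidationError("effect delta must be finite")
        if self.group not in ("female", "male"):
            raise ValidationError("effect group must be 'female' or 'male'")


# per-sex defaults: (age, height_cm, weight_kg) means and SDs, and gait
_DEFAULT_ANTHRO = {
    "female": {"age": (34.5, 14.9), "height": (159.4, 4.8), "weight": (54.9, 7.3)},
    "male": {"age": (33.7, 14.4), "height": (172.8, 4.9), "weight": (70.1, 9.1)},
}
_DEFAULT_GAIT = {
    "female": {"step_length": (0.702, 0.06), "step_duration": (0.49, 0.03), "foot_angle": (3.04, 4.37)},
    "male": {"step_length": (0.724, 0.063), "step_duration": (0.524, 0.048), "foot_angle": (6.35, 3.73)},
}
_DEFAULT_INTERVALS = {
    "female": {"means": (26.4, 24.0, 24.8, 24.9), "sds": (3.1, 2.9, 3.6, 2.7)},
    "male": {"means": (24.3, 20.7, 28.9, 26.1), "sds": (3.1, 4.4, 6.9, 2.2)},
}


@dataclass(frozen=True)
class SynthCohortConfig:
    """Generative specification of a synthetic two-group cohort.

    Defaults encode the study conditions: 68 females / 24 males, Table-style
    anthropometrics and gait parameters per sex, per-sex mean proportional
    intervals (which set each subject's M-curve peak timings), a 110 BW%
    loading peak, and the instrument constants (5 mm pitch, 100 Hz).
    ``regional_effects`` inject localized weight-normalized pressure offsets
    for one group.  Contact time is tied to step duration by
    ``contact_ratio`` (stance occupies ~68.5% of the stride).
    """

    n_female: int = 68
    n_male: int = 24
    anthropometrics: dict = field(default_factory=lambda: _DEFAULT_ANTHRO)
    gait: dict = field(default_factory=lambda: _DEFAULT_GAIT)
    interval_props: dict = field(default_factory=lambda: _DEFAULT_INTERVALS)
    contact_ratio: float = 1.37
    contact_jitter_sd_s: float = 0.02
    peak_force_bw: float = 110.0
    peak_force_sd: float = 5.0
    valley_force_bw: float = 75.0
    valley_force_sd: float = 5.0
    zone_gain_sd: float = 0.12
    noise_sd: float = 0.05
    regional_effects: tuple[RegionalEffect, ...] = ()
    pitch: float = SENSOR_PITCH_MM
    rate: float = SAMPLING_RATE_HZ
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_female < 2 or self.n_male < 2:
            raise ValidationError("need at least 2 participants per group")
        if self.noise_sd < 0 or self.zone_gain_sd < 0:
            raise ValidationError("noise scales must be >= 0")
        for sex in ("female", "male"):
            total = sum(self.interval_props[sex]["means"])
            # rounding slack: printed proportions may sum to e.g. 100.1
            if abs(total - 100.0) > 0.5:
                raise ValidationError(
                    f"{sex} interval proportions sum to {total}, expected 100"
                )

    def to_yaml(self) -> str:
        d = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
            if k != "regional_effects"
        }
        d["regional_effects"] = [
            {"region": e.region, "delta": e.delta, "group": e.group}
            for e in self.regional_effects
        ]
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SynthCohortConfig":
        d = yaml.safe_load(text) or {}
        effects = tuple(
            RegionalEffect(**e) for e in d.pop("regional_effects", [])
        )
        for key in ("anthropometrics", "gait", "interval_props"):
            if key in d:
                d[key] = {
                    sex: {k: tuple(v) for k, v in fields.items()}
                    for sex, fields in d[key].items()
                }
        return cls(regional_effects=effects, **d)


@dataclass
class CohortTruth:
    """Ground-truth bundle accompanying a generated cohort."""

    config: SynthCohortConfig
    stances: dict  # id -> {side: StanceTruth}
    gait: dict  # id -> {step_length_m, step_duration_s, first_side}
    effect_masks: dict  # region name -> standard-grid mask
    standard_grid: StandardGrid


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float, lo_sigma: float = 3.0) -> float:
    """Normal draw truncated at +/- 3 SD (simple rejection)."""
    while True:
        x = rng.normal(mean, sd)
        if abs(x - mean) <= lo_sigma * sd:
            return x


def _draw_intervals(rng: np.random.Generator, means, sds) -> tuple[float, float, float, float]:
    """Subject interval proportions: truncated draws renormalized to 100."""
    vals = np.array([_trunc_normal(rng, m, s) for m, s in zip(means, sds)])
    vals = np.clip(vals, 10.0, None)
    vals = vals / vals.sum() * 100.0
    return tuple(vals)


def generate_cohort(
    config: SynthCohortConfig | None = None,
) -> tuple[CohortManifest, CohortTruth]:
    """Generate a full synthetic cohort: manifest with recordings plus truth.

    Each participant gets one trial of two consecutive steps (opposite
    feet), with the second foot's heel landmark displaced along the
    progression axis by the drawn step length and in time by the drawn step
    duration.  Deterministic given ``config.seed``.
    """
    config = config or SynthCohortConfig()
    rng = np.random.default_rng(config.seed)
    std_grid = StandardGrid()
    zone_names = [z[0] for z in _ZONES]
    effect_masks = {r: region_mask(r, std_grid) for r in REGION_PRESETS}

    participants: list[ParticipantRecord] = []
    truth_stances: dict = {}
    truth_gait: dict = {}
    specs = [("female", i, f"F{i + 1:03d}") for i in range(config.n_female)] + [
        ("male", i, f"M{i + 1:03d}") for i in range(config.n_male)
    ]
    for sex, _, pid in specs:
        an = config.anthropometrics[sex]
        age = _trunc_normal(rng, *an["age"])
        height = _trunc_normal(rng, *an["height"])
        weight = _trunc_normal(rng, *an["weight"])
        gait = config.gait[sex]
        step_len = _trunc_normal(rng, *gait["step_length"])
        step_dur = _trunc_normal(rng, *gait["step_duration"])
        foot_len = max(0.147 * height * 10.0 + rng.normal(0.0, 5.0), 180.0)
        iv = config.interval_props[sex]
        props = _draw_intervals(rng, iv["means"], iv["sds"])
        contact = max(config.contact_ratio * step_dur + rng.normal(0, config.contact_jitter_sd_s), 0.4)
        peak_bw = _trunc_normal(rng, config.peak_force_bw, config.peak_force_sd)
        valley_bw = min(
            _trunc_normal(rng, config.valley_force_bw, config.valley_force_sd), 0.85 * peak_bw
        )
        gains = {nm: float(np.exp(rng.normal(0.0, config.zone_gain_sd))) for nm in zone_names}
        first_side = "left" if rng.integers(2) else "right"
        sides = (first_side, "right" if first_side == "left" else "left")
        effects = [
            (effect_masks[e.region], e.delta)
            for e in config.regional_effects
            if e.group == sex
        ]

        s = foot_len / 100.0 / config.pitch
        step_rows = step_len * 1000.0 / config.pitch
        n_rows = int(np.ceil(s * 120 + step_rows)) + 12
        n_cols = int(np.ceil(s * 50)) + 24
        onset2 = int(round(step_dur * config.rate))
        stance_frames = []
        stance_truths = {}
        lms = {}
        for k, side in enumerate(sides):
            angle = _trunc_normal(rng, *gait["foot_angle"])
            ml_off = -9.0 if side == "left" else 9.0
            l1 = (s * 11 + 5 + k * step_rows, (n_cols - 1) / 2.0 + ml_off)
            profile = StanceProfile(
                side=side,
                foot_length_mm=foot_len,
                foot_angle_deg=angle,
                body_mass_kg=weight,
                contact_time_s=contact,
                interval_props=props,
                peak_force_bw=peak_bw,
                valley_force_bw=valley_bw,
                zone_gains=gains,
                noise_sd=config.noise_sd,
                pitch=config.pitch,
                rate=config.rate,
            )
            frames, truth = _emit_stance(
                profile, rng, (n_rows, n_cols), l1, effects=effects, std_grid=std_grid
            )
            t_off = k * onset2
            truth = replace_truth_offset(truth, t_off)
            stance_frames.append((t_off, frames))
            stance_truths[side] = truth
            lms[side] = truth.landmarks

        T = max(t_off + f.shape[0] for t_off, f in stance_frames) + 2
        plate = np.zeros((T, n_rows, n_cols))
        for t_off, frames in stance_frames:
            plate[t_off : t_off + frames.shape[0]] += frames
        rec = PressureRecording(plate, pitch=config.pitch, rate=config.rate, id=pid)
        participants.append(
            ParticipantRecord(
                id=pid,
                sex=sex,
                age=age,
                height_cm=height,
                weight_kg=weight,
                recording=rec,
                landmarks=lms,
            )
        )
        truth_stances[pid] = stance_truths
        truth_gait[pid] = {
            "step_length_m": step_len,
            "step_duration_s": step_dur,
            "first_side": first_side,
            "contact_time_s": contact,
        }

    manifest = CohortManifest(
        participants=participants,
        provenance=f"synthetic cohort, seed={config.seed}",
    )
    truth = CohortTruth(
        config=config,
        stances=truth_stances,
        gait=truth_gait,
        effect_masks=effect_masks,
        standard_grid=std_grid,
    )
    return manifest, truth


def replace_truth_offset(truth: StanceTruth, t_off: int) -> StanceTruth:
    """Shift a stance truth's frame indices by a recording time offset."""
    return StanceTruth(
        onset=truth.onset + t_off,
        offset=truth.offset + t_off,
        peak1=truth.peak1 + t_off,
        peak2=truth.peak2 + t_off,
        peak3=truth.peak3 + t_off,
        landmarks=truth.landmarks,
        side=truth.side,
        interval_props=truth.interval_props,
        peak_force_bw=truth.peak_force_bw,
    )


# ---------------------------------------------------------------------------
# Reduced generator: standardized weight-normalized maps, for simulation
# studies of the inference machinery (calibration, FWER, effect recovery)
# where thousands of cohorts are needed and the sensor-grid round trip adds
# nothing to the property under study.

_TIMING_TAU = {"peak1": 0.264, "transient1": 0.384, "peak2": 0.504, "transient2": 0.628, "peak3": 0.752}


def _base_map(grid: StandardGrid, timing: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Canonical weight-normalized map (kPa/N), per-zone components, support."""
    names, shapes = _zone_shapes(grid)
    tau = _TIMING_TAU[timing]
    env = _zone_envelopes(np.array([tau]), 0.264, 0.504, 0.752)
    amps = np.array([env[_ZONE_GROUPS[nm]][0] for nm in names])
    cell_m2 = (grid.spacing * 2.35 / 1000.0) ** 2  # nominal 2.35 mm per A.U.
    unit = shapes / (shapes.sum(axis=(1, 2)) * cell_m2)[:, None, None]
    weights = amps / amps.sum()
    f_bw = m_wave(np.array([tau]), 0.264, 0.504, 0.752, 110.0, 75.0, 107.8, 16.5)[0]
    components = (f_bw / 100.0) * weights[:, None, None] * unit / 1000.0  # kPa/N per zone
    base = components.sum(axis=0)
    support = base > 0.01 * base.max()
    return base, components, support


def simulate_group_maps(
    n_subjects: int,
    rng: np.random.Generator,
    grid: StandardGrid | None = None,
    timing: str = "peak1",
    effects: Sequence[tuple[str | np.ndarray, float]] = (),
    zone_gain_sd: float = 0.0,
    pixel_noise_sd: float = 0.13,
    noise_model: str = "normal",
    effect_mode: str = "additive",
) -> np.ndarray:
    """Standardized weight-normalized pressure maps for one group.

    Between-subject variability is independent pixel-level noise with
    relative SD ``pixel_noise_sd`` (symmetric Gaussian by default, or
    log-normal with ``noise_model="lognormal"``), optionally combined with
    a correlated per-zone log-normal gain (``zone_gain_sd``).  Injected
    regional effects are additive offsets in kPa/N, or — with
    ``effect_mode="relative"`` — fractions of the local mean, which makes
    the pointwise effect size uniform across the region.  Pixels outside
    the footprint support are exactly 0.  Returns (n_subjects, H, W).
    """
    grid = grid or StandardGrid()
    base, components, support = _base_map(grid, timing)
    Z = components.shape[0]
    if zone_gain_sd > 0:
        gains = np.exp(rng.normal(-0.5 * zone_gain_sd**2, zone_gain_sd, size=(n_subjects, Z)))
        maps = np.einsum("sz,zhw->shw", gains, components)
    else:
        maps = np.broadcast_to(base, (n_subjects, *base.shape)).copy()
    if pixel_noise_sd > 0:
        if noise_model == "normal":
            maps = maps * (1.0 + rng.normal(0.0, pixel_noise_sd, size=maps.shape))
            np.clip(maps, 0.0, None, out=maps)
        elif noise_model == "lognormal":
            maps = maps * np.exp(
                rng.normal(-0.5 * pixel_noise_sd**2, pixel_noise_sd, size=maps.shape)
            )
        else:
            raise ValidationError(f"unknown noise_model {noise_model!r}")
    for region, value in effects:
        mask = region_mask(region, grid) if isinstance(region, str) else np.asarray(region, bool)
        if effect_mode == "relative":
            maps = maps + value * base * mask
        else:
            maps = maps + value * mask
    maps *= support
    return maps


def effect_fraction_for_d(
    d: float, zone_gain_sd: float = 0.0, pixel_noise_sd: float = 0.13
) -> float:
    """Relative effect fraction giving pointwise Cohen's d under the map model.

    With relative SD sigma at every footprint pixel, an offset of
    d * sigma * (local mean) yields Cohen's d at each pixel of the region
    (use with ``effect_mode="relative"``).
    """
    return d * float(np.hypot(zone_gain_sd, pixel_noise_sd))


def effect_delta_for_d(
    d: float,
    region: str,
    grid: StandardGrid | None = None,
    timing: str = "peak1",
    zone_gain_sd: float = 0.0,
    pixel_noise_sd: float = 0.13,
) -> float:
    """Weight-normalized additive delta giving ~Cohen's d in a region.

    Sized against the region's mean value b: the between-subject SD at a
    pixel with mean b is b * sqrt(sigma_zone^2 + sigma_pixel^2), so the
    realized pointwise d varies with the local mean (use
    :func:`effect_fraction_for_d` for a uniform pointwise d).
    """
    grid = grid or StandardGrid()
    base, _, _ = _base_map(grid, timing)
    mask = region_mask(region, grid)
    b = float(base[mask].mean())
    return d * b * float(np.hypot(zone_gain_sd, pixel_noise_sd))
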