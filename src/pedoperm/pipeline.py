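"""End-to-end analysis pipeline and report rendering.

Stages: obtain a cohort (generate synthetic or load a manifest) ->
segment and side-label stances -> extract gait/pressure/temporal parameters
-> scalar group statistics (+ covariate-adjusted models) -> spatial cluster
permutation tests on the standardized weight-normalized maps at the three
M-curve peaks and the two transient-phase midpoints, per foot -> temporal
cluster tests on the time-normalized series (total force, averaged
pressure, contact area, COP x/y), per foot.  Reruns with an identical
config and seed produce identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .clusterperm import PermConfig, cluster_table, cluster_test
from .cohortstats import ADJUSTMENT_PREDICTORS, adjusted_sex_effect, group_table
from .footio import ParticipantRecord, ValidationError, read_manifest
from .gaitfeatures import (
    TriphasicError,
    basic_gait_params,
    detect_m_peaks,
    pressure_params,
    temporal_params,
    time_series_set,
)
from .stanceprep import StancePhase, StandardGrid, standardize_foot, segment_stances
from .synthcohort import SynthCohortConfig, generate_cohort

log = logging.getLogger("pedoperm")

SPATIAL_TIMINGS = ("peak1", "peak2", "peak3", "transient1", "transient2")
SERIES_NAMES = ("total_force", "averaged_pressure", "contact_area", "cop_x", "cop_y")
SCALAR_PARAMS = (
    "step_length", "step_duration", "cadence", "speed", "foot_angle",
    "contact_area", "peak_pressure", "max_force",
    "interval1_ms", "interval2_ms", "interval3_ms", "interval4_ms",
    "prop_interval1", "prop_interval2", "prop_interval3", "prop_interval4",
)
ADJUSTED_PARAMS = (
    "contact_area", "max_force", "peak_pressure",
    "prop_interval1", "prop_interval2", "prop_interval3", "prop_interval4",
)


@dataclass
class PipelineConfig:
    """One input source (manifest path or synthetic config) plus analysis knobs."""

    manifest_path: Optional[str] = None
    synth: Optional[SynthCohortConfig] = None
    timings: tuple[str, ...] = SPATIAL_TIMINGS
    average3: bool = False  # average 3 neighboring frames around each timing
    n_points: int = 50
    perm: PermConfig = field(default_factory=PermConfig)
    grid: StandardGrid = field(default_factory=StandardGrid)
    mirror_left: bool = False  # pool mirrored left feet with right feet
    out_dir: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.manifest_path is None) == (self.synth is None):
            raise ValidationError("exactly one of manifest_path or synth must be set")
        if self.n_points not in (50, 100):
            raise ValidationError("n_points must be 50 or 100")
        unknown = set(self.timings) - set(SPATIAL_TIMINGS)
        if unknown:
            raise ValidationError(f"unknown timings: {sorted(unknown)}")


@dataclass
class ParticipantFeatures:
    record: ParticipantRecord
    gait: object
    per_side: dict  # side -> dict(stance, landmarks, pressure, temporal|None, series)
    m_peaks_ok: bool


@dataclass
class PipelineResult:
    config: PipelineConfig
    features: list[ParticipantFeatures]
    parameter_table: pd.DataFrame
    scalar_tests: pd.DataFrame
    regressions: dict
    spatial: dict  # (side, timing) -> ClusterResult
    temporal: dict  # (side, series) -> ClusterResult
    excluded: list[str]
    out_dir: Optional[Path] = None


def _match_side(stance: StancePhase, record: ParticipantRecord) -> Optional[str]:
    """Assign the foot side whose L1 landmark falls inside the stance crop."""
    r0, c0 = stance.origin
    H, W = stance.frames.shape[1:]
    for side, lm in record.landmarks.items():
        if r0 - 1 <= lm.l1[0] <= r0 + H and c0 - 1 <= lm.l1[1] <= c0 + W:
            return side
    return None


def extract_features(record: ParticipantRecord) -> ParticipantFeatures:
    """Segment one participant's recording and compute all per-foot features."""
    rec = record.recording
    stances = segment_stances(rec)
    for st in stances:
        st.side = _match_side(st, record)
    labelled = [s for s in stances if s.side is not None]
    if len(labelled) < 2:
        raise ValidationError(f"participant {record.id}: could not label two stances")
    labelled = labelled[:2]
    gait = basic_gait_params(
        labelled,
        [record.landmarks[s.side] for s in labelled],
        rate=rec.rate,
        pitch=rec.pitch,
    )
    per_side = {}
    ok = True
    for st in labelled:
        lm = record.landmarks[st.side]
        force = st.total_force()
        temporal = None
        try:
            peaks_rel = detect_m_peaks(force)
            temporal = temporal_params(
                tuple(p + st.onset for p in peaks_rel), st.onset, st.offset, rec.rate
            )
        except TriphasicError as exc:
            ok = False
            log.warning("participant %s %s foot: %s", record.id, st.side, exc)
        per_side[st.side] = {
            "stance": st,
            "landmarks": lm,
            "pressure": pressure_params(st),
            "temporal": temporal,
            "force": force,
        }
    return ParticipantFeatures(record=record, gait=gait, per_side=per_side, m_peaks_ok=ok)


def _mean_sides(values: list[float]) -> float:
    return float(np.mean(values)) if values else float("nan")


def parameter_row(f: ParticipantFeatures) -> dict:
    """Per-participant parameter row; per-foot values averaged across feet."""
    rec = f.record
    row = {
        "id": rec.id, "sex": rec.sex, "age": rec.age, "height_cm": rec.height_cm,
        "weight_kg": rec.weight_kg, "bmi": rec.bmi,
        "step_length": f.gait.step_length, "step_duration": f.gait.step_duration,
        "cadence": f.gait.cadence, "speed": f.gait.speed, "foot_angle": f.gait.foot_angle,
    }
    for name, get in (
        ("contact_area", lambda d: d["pressure"].contact_area),
        ("peak_pressure", lambda d: d["pressure"].peak_pressure),
        ("max_force", lambda d: d["pressure"].max_force),
    ):
        row[name] = _mean_sides([get(d) for d in f.per_side.values()])
    temporals = [d["temporal"] for d in f.per_side.values() if d["temporal"] is not None]
    for k in range(4):
        row[f"interval{k + 1}_ms"] = _mean_sides([t.intervals_ms[k] for t in temporals])
        row[f"prop_interval{k + 1}"] = _mean_sides(
            [t.proportional_intervals[k] for t in temporals]
        )
    return row


def _timing_frame(temporal, timing: str) -> int:
    return getattr(temporal, timing)


def _spatial_map(entry: dict, weight_n: float, timing: str, config: PipelineConfig) -> Optional[np.ndarray]:
    """Standardized, weight-normalized map of one foot at one timing."""
    temporal = entry["temporal"]
    if temporal is None:
        return None
    st: StancePhase = entry["stance"]
    frame_abs = _timing_frame(temporal, timing)
    idx = frame_abs - st.onset
    if config.average3:
        sel = [max(idx - 1, 0), idx, min(idx + 1, st.n_frames - 1)]
    else:
        sel = [idx]
    sub = StancePhase(
        onset=0, offset=len(sel) - 1, frames=st.frames[sel], origin=st.origin,
        side=st.side, pitch=st.pitch, rate=st.rate,
    )
    mirror = config.mirror_left and st.side == "left"
    sf = standardize_foot(sub, entry["landmarks"], grid=config.grid, mirror=mirror,
                          weight_n=weight_n)
    return sf.grid_values.mean(axis=0)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis; write outputs if ``config.out_dir`` is set."""
    if config.synth is not None:
        synth = replace(config.synth, seed=config.synth.seed + config.seed)
        manifest, _truth = generate_cohort(synth)
    else:
        manifest = read_manifest(config.manifest_path, load_recordings=True)

    features, excluded = [], []
    for p in manifest.participants:
        try:
            features.append(extract_features(p))
        except ValidationError as exc:
            excluded.append(p.id)
            log.warning("excluding participant %s: %s", p.id, exc)

    table = pd.DataFrame([parameter_row(f) for f in features])
    scalar = group_table(table, [c for c in SCALAR_PARAMS if table[c].notna().all()])
    regressions = {}
    for param in ADJUSTED_PARAMS:
        sub = table[[param, *ADJUSTMENT_PREDICTORS]].dropna()
        if len(sub) > len(ADJUSTMENT_PREDICTORS) + 2:
            regressions[param] = adjusted_sex_effect(sub, param)

    sides = ("pooled",) if config.mirror_left else ("left", "right")
    rng_spatial = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    spatial: dict = {}
    for side in sides:
        for timing in config.timings:
            groups = {"female": [], "male": []}
            for f in features:
                entries = (
                    f.per_side.values() if side == "pooled" else
                    [f.per_side[side]] if side in f.per_side else []
                )
                for entry in entries:
                    m = _spatial_map(entry, f.record.body_weight_n, timing, config)
                    if m is not None:
                        groups[f.record.sex].append(m)
            if min(len(groups["female"]), len(groups["male"])) >= 2:
                spatial[(side, timing)] = cluster_test(
                    np.stack(groups["female"]), np.stack(groups["male"]),
                    config.perm, rng=rng_spatial,
                )

    rng_temporal = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    temporal: dict = {}
    series_cache: dict = {}
    for f in features:
        for side, entry in f.per_side.items():
            series_cache[(f.record.id, side)] = time_series_set(
                entry["stance"], f.record.weight_kg, n_points=config.n_points
            )
    for side in ("left", "right"):
        for name in SERIES_NAMES:
            groups = {"female": [], "male": []}
            for f in features:
                ts = series_cache.get((f.record.id, side))
                if ts is not None:
                    groups[f.record.sex].append(getattr(ts, name))
            if min(len(groups["female"]), len(groups["male"])) >= 2:
                cov = 0.0 if name.startswith("cop") else config.perm.min_group_coverage
                temporal[(side, name)] = cluster_test(
                    np.stack(groups["female"]), np.stack(groups["male"]),
                    replace(config.perm, min_group_coverage=cov), rng=rng_temporal,
                )

    result = PipelineResult(
        config=config, features=features, parameter_table=table, scalar_tests=scalar,
        regressions=regressions, spatial=spatial, temporal=temporal, excluded=excluded,
    )
    if config.out_dir is not None:
        result.out_dir = Path(config.out_dir)
        _write_outputs(result)
    return result


def _write_outputs(result: PipelineResult) -> None:
    out = result.out_dir
    out.mkdir(parents=True, exist_ok=True)
    result.parameter_table.to_csv(out / "parameters.csv", index=False)
    result.scalar_tests.to_csv(out / "scalar_tests.csv", index=False)
    reg_rows = []
    for param, reg in result.regressions.items():
        for pred in ADJUSTMENT_PREDICTORS:
            reg_rows.append(
                {
                    "parameter": param, "predictor": pred,
                    "coef": reg.params[pred], "se": reg.bse[pred],
                    "t": reg.tvalues[pred], "p": reg.pvalues[pred],
                    "vif": reg.vif[pred],
                }
            )
    pd.DataFrame(reg_rows).to_csv(out / "regressions.csv", index=False)
    for (side, timing), res in result.spatial.items():
        cluster_table(res).to_csv(out / f"spatial_{side}_{timing}_clusters.csv", index=False)
        np.savetxt(
            out / f"spatial_{side}_{timing}_sigmask.txt",
            res.significant_mask().astype(int), fmt="%d",
        )
    for (side, name), res in result.temporal.items():
        cluster_table(res).to_csv(out / f"temporal_{side}_{name}_clusters.csv", index=False)
        np.savetxt(
            out / f"temporal_{side}_{name}_sigmask.txt",
            res.significant_mask().astype(int)[None], fmt="%d",
        )
    cfg = dataclasses.asdict(result.config)
    cfg.pop("synth", None)
    logdata = {
        "version": __version__,
        "seed": result.config.seed,
        "n_participants": len(result.features),
        "excluded": result.excluded,
        "config": {k: str(v) for k, v in cfg.items()},
    }
    (out / "run_log.json").write_text(json.dumps(logdata, indent=2))


def make_report(result: PipelineResult, out_dir: Optional[str] = None) -> Path:
    """Render group-mean maps, difference maps with significant-cluster
    outlines, and series plots with significant windows shaded.

    Group-mean maps are normalized to [0, 1] by the min/max over both sexes.
    Returns the report directory.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir) if out_dir else (result.out_dir or Path("report"))
    out.mkdir(parents=True, exist_ok=True)
    lines = [f"pedoperm report (v{__version__})", ""]
    n_sig = 0
    for (side, timing), res in sorted(result.spatial.items()):
        means = _group_means(result, side, timing)
        if means is None:
            lines.append(f"spatial {side}/{timing}: missing group maps")
            continue
        f_mean, m_mean = means
        lo = min(f_mean.min(), m_mean.min())
        hi = max(f_mean.max(), m_mean.max())
        f_norm = (f_mean - lo) / (hi - lo) if hi > lo else f_mean * 0
        m_norm = (m_mean - lo) / (hi - lo) if hi > lo else m_mean * 0
        fig, axes = plt.subplots(1, 3, figsize=(9, 4))
        for ax, img, title in zip(axes, (f_norm, m_norm), ("female", "male")):
            ax.imshow(img, origin="lower", cmap="inferno", vmin=0, vmax=1)
            ax.set_title(title)
        diff = f_mean - m_mean
        axes[2].imshow(diff, origin="lower", cmap="coolwarm")
        axes[2].set_title("female - male")
        sig = res.significant_mask()
        if sig.any():
            axes[2].contour(sig.astype(float), levels=[0.5], colors="red")
        for ax in axes:
            ax.set_xticks([]), ax.set_yticks([])
        fig.suptitle(f"{side} foot, {timing}")
        fig.savefig(out / f"map_{side}_{timing}.png", dpi=110)
        plt.close(fig)
        k = len(res.significant_clusters)
        n_sig += k
        lines.append(f"spatial {side}/{timing}: {k} significant cluster(s)")
    for (side, name), res in sorted(result.temporal.items()):
        sig = res.significant_mask()
        fig, ax = plt.subplots(figsize=(6, 3))
        for sex, color in (("female", "tab:red"), ("male", "tab:blue")):
            stack = _series_stack(result, side, name, sex)
            if stack is not None:
                mean = stack.mean(axis=0)
                sem = stack.std(axis=0, ddof=1) / np.sqrt(len(stack))
                x = np.arange(stack.shape[1])
                ax.plot(x, mean, color=color, label=sex)
                ax.fill_between(x, mean - sem, mean + sem, color=color, alpha=0.25)
        if sig.any():
            ax.fill_between(
                np.arange(sig.size), *ax.get_ylim(), where=sig, color="green", alpha=0.2
            )
        ax.set_title(f"{side} {name}")
        ax.legend()
        fig.savefig(out / f"series_{side}_{name}.png", dpi=110)
        plt.close(fig)
        k = len(res.significant_clusters)
        n_sig += k
        lines.append(f"temporal {side}/{name}: {k} significant cluster(s)")
    if n_sig == 0:
        lines.append("")
        lines.append("No significant clusters in any analysis.")
    (out / "report.txt").write_text("\n".join(lines) + "\n")
    return out


def _group_means(result: PipelineResult, side: str, timing: str):
    groups = {"female": [], "male": []}
    for f in result.features:
        entries = (
            f.per_side.values() if side == "pooled" else
            [f.per_side[side]] if side in f.per_side else []
        )
        for entry in entries:
            m = _spatial_map(entry, f.record.body_weight_n, timing, result.config)
            if m is not None:
                groups[f.record.sex].append(m)
    if not groups["female"] or not groups["male"]:
        return None
    return np.stack(groups["female"]).mean(0), np.stack(groups["male"]).mean(0)


def _series_stack(result: PipelineResult, side: str, name: str, sex: str):
    out = []
    for f in result.features:
        if f.record.sex != sex or side not in f.per_side:
            continue
        ts = time_series_set(
            f.per_side[side]["stance"], f.record.weight_kg, n_points=result.config.n_points
        )
        out.append(getattr(ts, name))
    return np.stack(out) if out else None
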