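"""Simulation studies validating the inference machinery end to end.

Each study is a deterministic function of its seed list: family-wise error
calibration under exchangeable null groups, recovery of injected regional
effects (spatial localization), direction recovery of between-group
differences in the late-stance proportional intervals, and the geometric /
conservation invariants of the standardization pipeline.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np

from .clusterperm import PermConfig, cluster_test
from .gaitfeatures import TriphasicError, detect_m_peaks, temporal_params
from .stanceprep import StandardGrid, standardize_foot, segment_stances
from .synthcohort import (
    StanceProfile,
    SynthCohortConfig,
    _DEFAULT_ANTHRO,
    _DEFAULT_GAIT,
    _DEFAULT_INTERVALS,
    _draw_intervals,
    _trunc_normal,
    effect_fraction_for_d,
    generate_cohort,
    generate_stance,
    region_mask,
    simulate_group_maps,
)

__all__ = [
    "fwer_study",
    "spatial_recovery_study",
    "temporal_direction_study",
    "pipeline_invariants",
]


def fwer_study(
    seeds: Sequence[int],
    n_per_group: int = 12,
    grid_shape: tuple[int, int] = (40, 20),
    n_perm: int = 200,
    cluster_alpha: float = 0.05,
) -> float:
    """Fraction of null datasets with any significant spatial cluster.

    Both groups are drawn from the same population (no injected effect), so
    labels are exchangeable and the fraction estimates the family-wise
    error rate of the cluster permutation test at ``cluster_alpha``.
    """
    grid = StandardGrid.with_shape(*grid_shape)
    config = PermConfig(n_perm=n_perm, cluster_alpha=cluster_alpha)
    hits = 0
    for seed in seeds:
        rng = np.random.default_rng(seed)
        a = simulate_group_maps(n_per_group, rng, grid)
        b = simulate_group_maps(n_per_group, rng, grid)
        hits += bool(cluster_test(a, b, config, rng=rng).significant_clusters)
    return hits / len(seeds)


def spatial_recovery_study(
    seeds: Sequence[int],
    effect_region: str = "calcaneus",
    probe_region: Optional[str] = None,
    d: float = 1.2,
    n_a: int = 30,
    n_b: int = 15,
    n_perm: int = 200,
    coverage: float = 0.8,
) -> dict:
    """Recovery of an injected regional effect of pointwise Cohen's d.

    Per run, group A receives a relative offset sized to ``d`` at every
    pixel of ``effect_region``; the study reports the fraction of runs in
    which the significant clusters cover at least ``coverage`` of the true
    region, and (if ``probe_region`` is given) the fraction of runs in
    which they stay clear of that other region.
    """
    grid = StandardGrid()
    true_mask = region_mask(effect_region, grid)
    probe_mask = region_mask(probe_region, grid) if probe_region else None
    frac = effect_fraction_for_d(d)
    config = PermConfig(n_perm=n_perm)
    covered = 0
    clear_of_probe = 0
    for seed in seeds:
        rng = np.random.default_rng(seed)
        a = simulate_group_maps(
            n_a, rng, grid, effects=[(effect_region, frac)], effect_mode="relative"
        )
        b = simulate_group_maps(n_b, rng, grid)
        sig = cluster_test(a, b, config, rng=rng).significant_mask()
        covered += (sig & true_mask).sum() / true_mask.sum() >= coverage
        if probe_mask is not None:
            clear_of_probe += not (sig & probe_mask).any()
    out = {"coverage_rate": covered / len(seeds)}
    if probe_mask is not None:
        out["clear_of_probe_rate"] = clear_of_probe / len(seeds)
    return out


def _cohort_proportional_intervals(
    rng: np.random.Generator, n_female: int, n_male: int
) -> tuple[np.ndarray, np.ndarray]:
    """Generate stances per subject (both feet) and recover their interval
    proportions through M-peak detection; feet averaged per subject."""
    out = {"female": [], "male": []}
    for sex, n in (("female", n_female), ("male", n_male)):
        iv = _DEFAULT_INTERVALS[sex]
        gait = _DEFAULT_GAIT[sex]
        an = _DEFAULT_ANTHRO[sex]
        for _ in range(n):
            props = _draw_intervals(rng, iv["means"], iv["sds"])
            dur = _trunc_normal(rng, *gait["step_duration"])
            contact = max(1.37 * dur + rng.normal(0, 0.02), 0.4)
            height = _trunc_normal(rng, *an["height"])
            weight = _trunc_normal(rng, *an["weight"])
            per_foot = []
            for side in ("left", "right"):
                profile = StanceProfile(
                    side=side,
                    foot_length_mm=max(1.47 * height + rng.normal(0, 5), 180.0),
                    body_mass_kg=weight,
                    contact_time_s=contact,
                    interval_props=props,
                )
                rec, truth = generate_stance(profile, rng=rng)
                force = rec.total_force()[truth.onset : truth.offset + 1]
                try:
                    peaks = detect_m_peaks(force)
                    tp = temporal_params(
                        tuple(p + truth.onset for p in peaks),
                        truth.onset, truth.offset, profile.rate,
                    )
                    per_foot.append(tp.proportional_intervals)
                except TriphasicError:
                    continue
            if per_foot:
                out[sex].append(np.mean(per_foot, axis=0))
    return np.asarray(out["female"]), np.asarray(out["male"])


def temporal_direction_study(
    seeds: Sequence[int], n_female: int = 68, n_male: int = 24
) -> dict:
    """Direction recovery of the late-stance interval differences.

    Cohorts are generated with the per-sex proportional-interval means and
    SDs; the study reports, per interval 3 and 4, the fraction of cohorts
    whose recovered group means show the male > female direction, and the
    largest deviation of any subject's proportions from summing to 100.
    """
    ok3 = ok4 = 0
    max_sum_dev = 0.0
    for seed in seeds:
        rng = np.random.default_rng(seed)
        f, m = _cohort_proportional_intervals(rng, n_female, n_male)
        ok3 += m[:, 2].mean() > f[:, 2].mean()
        ok4 += m[:, 3].mean() > f[:, 3].mean()
        sums = np.concatenate([f, m]).sum(axis=1)
        max_sum_dev = max(max_sum_dev, float(np.abs(sums - 100.0).max()))
    n = len(seeds)
    return {
        "prop_interval3_direction_rate": ok3 / n,
        "prop_interval4_direction_rate": ok4 / n,
        "max_proportion_sum_deviation": max_sum_dev,
    }


def pipeline_invariants(seed: int = 0, n_female: int = 4, n_male: int = 3) -> dict:
    """Geometric and conservation invariants on a small generated cohort.

    Checks, across every stance of every participant: the standardized
    landmark distance (must be 100 A.U.), total-force conservation under
    regridding (relative error at the force peak), and the center of
    pressure staying inside each frame's active-sensor bounding box.
    """
    config = SynthCohortConfig(n_female=n_female, n_male=n_male, seed=seed)
    manifest, _ = generate_cohort(config)
    max_lm_dev = 0.0
    max_force_err = 0.0
    cop_violations = 0
    n_frames_checked = 0
    for p in manifest.participants:
        stances = segment_stances(p.recording)
        for st in stances:
            lm = None
            for side, cand in p.landmarks.items():
                r0, c0 = st.origin
                H, W = st.frames.shape[1:]
                if r0 <= cand.l1[0] <= r0 + H and c0 <= cand.l1[1] <= c0 + W:
                    lm, st.side = cand, side
            if lm is None:
                continue
            sf = standardize_foot(st, lm)
            # landmark geometry: the inverse map evaluated at the grid cells
            # holding L1 and L2 must return the sensor landmarks
            max_lm_dev = max(max_lm_dev, abs(sf.landmark_distance_au() - 100.0))
            g = sf.grid
            theta = math.atan2(lm.l2[1] - lm.l1[1], lm.l2[0] - lm.l1[0])
            scale = st.landmarks_local(lm).length / 100.0
            for au, ref in (((0.0, 0.0), lm.l1), ((100.0, 0.0), lm.l2)):
                r = lm.l1[0] + scale * math.cos(theta) * au[0] - scale * math.sin(theta) * au[1]
                c = lm.l1[1] + scale * math.sin(theta) * au[0] + scale * math.cos(theta) * au[1]
                max_lm_dev = max(max_lm_dev, math.hypot(r - ref[0], c - ref[1]) / scale)
            force_sensor = st.total_force()
            force_std = sf.total_force()
            peak = int(np.argmax(force_sensor))
            max_force_err = max(
                max_force_err,
                abs(force_std[peak] - force_sensor[peak]) / force_sensor[peak],
            )
            # COP convexity per frame
            for t in range(st.n_frames):
                fr = st.frames[t]
                if not fr.any():
                    continue
                rows, cols = np.nonzero(fr)
                w = fr[rows, cols]
                cr = (w * rows).sum() / w.sum()
                cc = (w * cols).sum() / w.sum()
                n_frames_checked += 1
                if not (rows.min() <= cr <= rows.max() and cols.min() <= cc <= cols.max()):
                    cop_violations += 1
    return {
        "max_landmark_distance_deviation_au": max_lm_dev,
        "max_regrid_force_rel_error": max_force_err,
        "cop_bbox_violations": cop_violations,
        "n_frames_checked": n_frames_checked,
    }
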