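"""Generator: M-wave truth, regional effects, cohort structure, calibration."""

import numpy as np
import pytest

from pedoperm.footio import ValidationError
from pedoperm.gaitfeatures import detect_m_peaks, temporal_params
from pedoperm.stanceprep import StandardGrid
from pedoperm.synthcohort import (
    RegionalEffect,
    StanceProfile,
    SynthCohortConfig,
    effect_fraction_for_d,
    generate_cohort,
    generate_stance,
    inject_regional_effect,
    m_wave,
    region_mask,
    simulate_group_maps,
)
from pedoperm.clusterperm import PermConfig, pointwise_tmap


class TestMWave:
    def test_extrema_exactly_at_knots(self):
        tau = np.linspace(0, 1, 2001)
        f = m_wave(tau, 0.25, 0.5, 0.75, 110, 75, 108, 15)
        for t_knot, val in ((0.25, 110), (0.5, 75), (0.75, 108)):
            i = int(t_knot * 2000)
            assert f[i] == pytest.approx(val)
        # monotone between knots: no extremum off the knots
        d = np.diff(f)
        sign_changes = np.nonzero(np.sign(d[:-1]) * np.sign(d[1:]) < 0)[0]
        assert len(sign_changes) == 3

    def test_infeasible_timing_rejected(self):
        with pytest.raises(ValidationError):
            m_wave(np.linspace(0, 1, 10), 0.5, 0.25, 0.75, 110, 75, 108, 15)


class TestGenerateStance:
    def test_triphasic_by_construction(self, default_stance):
        rec, truth = default_stance
        force = rec.total_force()[truth.onset : truth.offset + 1]
        p1, p2, p3 = detect_m_peaks(force)  # raises if not triphasic
        assert p1 < p2 < p3

    def test_peaks_at_truth_indices(self, default_stance):
        rec, truth = default_stance
        force = rec.total_force()
        p1, p2, p3 = detect_m_peaks(force[truth.onset : truth.offset + 1])
        assert abs(p1 + truth.onset - truth.peak1) <= 1
        assert abs(p2 + truth.onset - truth.peak2) <= 1
        assert abs(p3 + truth.onset - truth.peak3) <= 1

    def test_default_female_profile_interval_recovery(self):
        """Emitted stance's proportional intervals stay within 2 points of
        the configured (26.4, 24.0, 24.8, 24.9); detected peaks add at most
        one frame of error per boundary on top."""
        for seed in range(6):
            rec, truth = generate_stance(StanceProfile(), seed=seed)
            tp_true = temporal_params(
                (truth.peak1, truth.peak2, truth.peak3), truth.onset, truth.offset, 100.0
            )
            dev = np.abs(np.subtract(tp_true.proportional_intervals, truth.interval_props))
            assert dev.max() < 2.0
            force = rec.total_force()[truth.onset : truth.offset + 1]
            peaks = detect_m_peaks(force)
            tp = temporal_params(
                tuple(p + truth.onset for p in peaks), truth.onset, truth.offset, 100.0
            )
            frame_pp = 100.0 / (truth.offset - truth.onset)
            dev_det = np.abs(np.subtract(tp.proportional_intervals, truth.interval_props))
            assert dev_det.max() < 2.0 + 2 * frame_pp

    def test_peak_force_matches_generating_waveform(self):
        """Realized peak of the weight-normalized force tracks the waveform
        oracle (110 BW% at the loading peak) within a small regrid/threshold
        loss."""
        profile = StanceProfile(peak_force_bw=110.0, noise_sd=0.0)
        rec, truth = generate_stance(profile, seed=3)
        bw_pct = rec.total_force().max() / (profile.body_mass_kg * 9.8) * 100
        assert bw_pct == pytest.approx(110.0, rel=0.05)

    def test_footprint_covers_heel_and_forefoot(self, default_stance):
        rec, truth = default_stance
        occupied = rec.frames.any(axis=0)
        rows = np.nonzero(occupied.any(axis=1))[0]
        l1_row = truth.landmarks.l1[0]
        l2_row = truth.landmarks.l2[0]
        assert rows[0] <= l1_row + 2 and rows[-1] >= l2_row - 5

    def test_infeasible_profile_rejected(self):
        with pytest.raises(ValidationError):
            generate_stance(StanceProfile(interval_props=(50.0, 30.0, 15.0, 5.0), valley_force_bw=120.0), seed=0)


class TestRegionalEffects:
    def test_zero_delta_is_identity(self):
        grid = StandardGrid()
        template = np.random.default_rng(0).random(grid.shape)
        np.testing.assert_array_equal(
            inject_regional_effect(template, "calcaneus", 0.0), template
        )

    def test_delta_raises_inside_mean_exactly(self):
        grid = StandardGrid()
        template = np.random.default_rng(1).random(grid.shape)
        mask = region_mask("calcaneus", grid)
        out = inject_regional_effect(template, "calcaneus", 0.37)
        assert out[mask].mean() - template[mask].mean() == pytest.approx(0.37)
        np.testing.assert_array_equal(out[~mask], template[~mask])

    def test_presets_disjoint(self):
        grid = StandardGrid()
        cal = region_mask("calcaneus", grid)
        mt2 = region_mask("second_metatarsal", grid)
        assert not (cal & mt2).any()
        assert cal.any() and mt2.any()

    def test_mask_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="shape"):
            inject_regional_effect(np.zeros((10, 10)), np.ones((5, 5), bool), 1.0)

    def test_unknown_region_rejected(self):
        with pytest.raises(ValidationError, match="unknown region"):
            region_mask("talus")


class TestGenerateCohort:
    def test_default_config_group_sizes(self):
        config = SynthCohortConfig()
        assert config.n_female == 68 and config.n_male == 24

    def test_same_seed_identical_cohorts(self):
        cfg = SynthCohortConfig(n_female=2, n_male=2, seed=9)
        m1, t1 = generate_cohort(cfg)
        m2, t2 = generate_cohort(cfg)
        for p1, p2 in zip(m1.participants, m2.participants):
            assert p1.weight_kg == p2.weight_kg
            np.testing.assert_array_equal(p1.recording.frames, p2.recording.frames)

    def test_two_steps_opposite_feet(self, tiny_cohort):
        manifest, truth = tiny_cohort
        for p in manifest.participants:
            sides = set(truth.stances[p.id])
            assert sides == {"left", "right"}

    def test_effects_only_injected_into_target_group(self):
        cfg = SynthCohortConfig(
            n_female=2, n_male=2, seed=4, noise_sd=0.0,
            regional_effects=(RegionalEffect("calcaneus", 0.2, "female"),),
        )
        base = SynthCohortConfig(n_female=2, n_male=2, seed=4, noise_sd=0.0)
        m_eff, _ = generate_cohort(cfg)
        m_base, _ = generate_cohort(base)
        for pe, pb in zip(m_eff.participants, m_base.participants):
            if pe.sex == "female":
                assert np.abs(pe.recording.frames - pb.recording.frames).max() > 0
            else:
                np.testing.assert_array_equal(pe.recording.frames, pb.recording.frames)

    def test_config_yaml_roundtrip(self):
        cfg = SynthCohortConfig(
            n_female=3, n_male=2, seed=5,
            regional_effects=(RegionalEffect("second_metatarsal", 0.1, "female"),),
        )
        back = SynthCohortConfig.from_yaml(cfg.to_yaml())
        assert back == cfg

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValidationError):
            SynthCohortConfig(n_female=1)
        with pytest.raises(ValidationError):
            SynthCohortConfig(noise_sd=-0.1)


class TestMapSimulator:
    def test_null_pointwise_calibration_near_one_percent(self):
        """With no effect, ~1% of testable pixels reach p < .01."""
        fracs = []
        cfg = PermConfig()
        for seed in range(4):
            rng = np.random.default_rng(100 + seed)
            a = simulate_group_maps(60, rng)
            b = simulate_group_maps(60, rng)
            sm = pointwise_tmap(a, b, cfg)
            fracs.append((sm.p_values < 0.01)[sm.testable_mask].mean())
        assert 0.004 < np.mean(fracs) < 0.022

    def test_relative_effect_realizes_requested_d(self):
        frac = effect_fraction_for_d(1.0)
        rng = np.random.default_rng(0)
        grid = StandardGrid()
        mask = region_mask("calcaneus", grid)
        a = simulate_group_maps(800, rng, effects=[("calcaneus", frac)], effect_mode="relative")
        b = simulate_group_maps(800, rng)
        sp = np.sqrt((a.var(0, ddof=1) + b.var(0, ddof=1)) / 2)
        d = (a.mean(0) - b.mean(0))[mask] / sp[mask]
        assert np.median(d) == pytest.approx(1.0, abs=0.15)

    def test_support_zero_outside_footprint(self):
        rng = np.random.default_rng(1)
        maps = simulate_group_maps(3, rng)
        assert (maps[:, 0, 0] == 0).all() and (maps >= 0).all()
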