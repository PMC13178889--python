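"""Gait parameters, M-peak detection, temporal parameters, time series."""

import numpy as np
import pytest

from pedoperm.footio import LandmarkPair, ValidationError
from pedoperm.gaitfeatures import (
    TriphasicError,
    basic_gait_params,
    detect_m_peaks,
    pressure_params,
    temporal_params,
    time_series_set,
)
from pedoperm.stanceprep import StancePhase, segment_stances


def _stance(frames, onset=0, side="right", origin=(0, 0)):
    return StancePhase(
        onset=onset, offset=onset + frames.shape[0] - 1, frames=frames,
        origin=origin, side=side,
    )


def _square(n_frames, value=100.0, size=4):
    frames = np.zeros((n_frames, 10, 10))
    frames[:, 2 : 2 + size, 2 : 2 + size] = value
    return frames


class TestBasicGaitParams:
    def _pair(self, dt_frames=50, drow=140):
        s1 = _stance(_square(10), onset=0, side="left")
        s2 = _stance(_square(10), onset=dt_frames, side="right", origin=(drow, 0))
        lm1 = LandmarkPair(l1=(3.0, 4.0), l2=(43.0, 4.0))
        lm2 = LandmarkPair(l1=(3.0 + drow, 4.0), l2=(43.0 + drow, 4.0))
        return [s1, s2], [lm1, lm2]

    def test_cadence_is_60_over_step_duration(self):
        stances, lms = self._pair(dt_frames=50)
        g = basic_gait_params(stances, lms, rate=100.0, pitch=5.0)
        assert g.step_duration == pytest.approx(0.5)
        assert g.cadence == pytest.approx(120.0)

    def test_speed_is_length_over_duration(self):
        stances, lms = self._pair(dt_frames=50, drow=140)  # 140 x 5mm = 0.7 m
        g = basic_gait_params(stances, lms, rate=100.0, pitch=5.0)
        assert g.step_length == pytest.approx(0.7)
        assert g.speed == pytest.approx(1.4)

    def test_same_side_steps_rejected(self):
        stances, lms = self._pair()
        stances[1].side = "left"
        with pytest.raises(ValidationError, match="opposite"):
            basic_gait_params(stances, lms, rate=100.0, pitch=5.0)

    def test_cohort_truth_recovered(self, tiny_cohort):
        """Step length/duration recovered within one pitch / one frame."""
        manifest, truth = tiny_cohort
        for p in manifest.participants:
            stances = segment_stances(p.recording)
            for st in stances:
                for side, t in truth.stances[p.id].items():
                    if t.onset == st.onset:
                        st.side = side
            stances = [s for s in stances if s.side]
            lms = [p.landmarks[s.side] for s in stances]
            g = basic_gait_params(stances, lms, p.recording.rate, p.recording.pitch)
            want = truth.gait[p.id]
            assert abs(g.step_length - want["step_length_m"]) <= 0.005
            assert abs(g.step_duration - want["step_duration_s"]) <= 0.01


class TestPressureParams:
    def test_uniform_pressure_closed_form(self):
        # 16 sensors at 200 kPa: area 16 x 0.25 cm^2, force 200*16*25e-3 N
        pp = pressure_params(_stance(_square(5, value=200.0, size=4)), pitch=5.0)
        assert pp.contact_area == pytest.approx(4.0)
        assert pp.peak_pressure == pytest.approx(200.0)
        assert pp.max_force == pytest.approx(200 * 16 * 25e-3)

    def test_400_sensors_give_100_cm2(self):
        frames = np.zeros((2, 25, 25))
        frames[:, :20, :20] = 50.0
        assert pressure_params(_stance(frames), pitch=5.0).contact_area == pytest.approx(100.0)

    def test_max_force_matches_series_oracle(self, default_stance):
        rec, truth = default_stance
        st, = segment_stances(rec)
        pp = pressure_params(st)
        assert pp.max_force == pytest.approx(st.total_force().max(), rel=1e-9)

    def test_contact_area_counts_any_frame_union(self):
        frames = np.zeros((2, 6, 6))
        frames[0, 0, 0] = 50.0
        frames[1, 5, 5] = 50.0
        assert pressure_params(_stance(frames), pitch=5.0).contact_area == pytest.approx(0.5)


class TestDetectMPeaks:
    def test_constructed_extrema_recovered(self):
        f = np.concatenate([
            np.linspace(5, 100, 11),        # rise to peak at 10
            np.linspace(100, 60, 16)[1:],   # fall to valley at 25
            np.linspace(60, 95, 16)[1:],    # rise to peak at 40
            np.linspace(95, 5, 12)[1:],     # fall-off
        ])
        assert detect_m_peaks(f) == (10, 25, 40)

    def test_monotone_series_flagged_invalid(self):
        with pytest.raises(TriphasicError):
            detect_m_peaks(np.linspace(0, 100, 30))

    def test_single_peak_flagged_invalid(self):
        f = np.concatenate([np.linspace(0, 100, 15), np.linspace(100, 0, 15)[1:]])
        with pytest.raises(TriphasicError):
            detect_m_peaks(f)

    def test_generated_stance_peaks_within_one_frame_of_truth(self, tiny_cohort):
        manifest, truth = tiny_cohort
        for p in manifest.participants:
            for st in segment_stances(p.recording):
                t = next(
                    t for t in truth.stances[p.id].values() if t.onset == st.onset
                )
                p1, p2, p3 = detect_m_peaks(st.total_force())
                assert abs(p1 + st.onset - t.peak1) <= 1
                assert abs(p2 + st.onset - t.peak2) <= 1
                assert abs(p3 + st.onset - t.peak3) <= 1


class TestTemporalParams:
    def test_intervals_by_subtraction(self):
        # 1000 Hz so frame index = ms
        tp = temporal_params((175, 335, 500), onset=0, offset=660, rate=1000.0)
        assert tp.intervals_ms == pytest.approx((175.0, 160.0, 165.0, 160.0))

    def test_proportions_sum_to_100_and_rate_conversion(self):
        tp = temporal_params((18, 34, 50), onset=0, offset=66, rate=100.0)
        assert sum(tp.proportional_intervals) == pytest.approx(100.0, abs=1e-9)
        # at 100 Hz an interval in ms is the frame difference x 10
        assert tp.intervals_ms[1] == pytest.approx((34 - 18) * 10.0)
        assert sum(tp.intervals_ms) == pytest.approx(660.0)

    def test_transients_round_half_down(self):
        tp = temporal_params((10, 21, 30), onset=0, offset=40, rate=100.0)
        assert tp.transient1 == 15  # midpoint 15.5 -> earlier frame
        assert tp.transient2 == 25

    def test_ordering_violation_rejected(self):
        with pytest.raises(ValidationError):
            temporal_params((30, 20, 40), onset=0, offset=50, rate=100.0)


class TestTimeSeriesSet:
    def test_cop_at_midpoint_of_two_equal_sensors(self):
        frames = np.zeros((6, 8, 8))
        frames[:, 2, 2] = 100.0
        frames[:, 6, 4] = 100.0
        ts = time_series_set(_stance(frames), mass_kg=60.0)
        assert ts.raw["cop_y"][0] == pytest.approx(4.0)
        assert ts.raw["cop_x"][0] == pytest.approx(3.0)

    def test_constant_series_resampled_constant(self):
        ts = time_series_set(_stance(_square(12, value=80.0)), mass_kg=60.0, n_points=50)
        assert ts.total_force.shape == (50,)
        np.testing.assert_allclose(ts.total_force, ts.total_force[0], rtol=1e-9)
        np.testing.assert_allclose(ts.contact_area, 4.0)

    def test_cop_within_active_bounding_box(self, default_stance):
        rec, truth = default_stance
        st, = segment_stances(rec)
        ts = time_series_set(st, mass_kg=58.0)
        for t in range(st.n_frames):
            fr = st.frames[t]
            if not fr.any():
                continue
            rows, cols = np.nonzero(fr)
            r0, c0 = st.origin
            assert rows.min() + r0 <= ts.raw["cop_y"][t] <= rows.max() + r0
            assert cols.min() + c0 <= ts.raw["cop_x"][t] <= cols.max() + c0

    def test_force_pressure_area_identity(self, default_stance):
        """avg pressure x active count x sensor area = total force, per frame."""
        rec, truth = default_stance
        st, = segment_stances(rec)
        mass = 58.0
        ts = time_series_set(st, mass_kg=mass)
        counts = (st.frames > 0).sum(axis=(1, 2))
        force = ts.raw["avg_pressure_norm"] * (mass * 9.8) * counts * 25e-3
        np.testing.assert_allclose(force, ts.raw["total_force_n"], rtol=1e-6)

    def test_series_nonnegative_and_length(self, default_stance):
        rec, truth = default_stance
        st, = segment_stances(rec)
        for n in (50, 100):
            ts = time_series_set(st, mass_kg=58.0, n_points=n)
            for name in ("total_force", "averaged_pressure", "contact_area"):
                series = getattr(ts, name)
                assert series.shape == (n,)
                assert (series >= 0).all()
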