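"""The synthetic sprint generator: geometry, truth consistency, recovery."""

import numpy as np
import pytest

import sprintgnss as sg
from sprintgnss.detection import Leg
from sprintgnss.simulate import NoiseConfig, TrackGeometry, make_track_path


class TestTrackPath:
    def test_starts_at_origin_heading_east(self):
        path = make_track_path(TrackGeometry())
        e, n = path(np.array([0.0, 0.01]))
        assert e[0] == 0.0 and n[0] == 0.0
        tangent = np.array([e[1] - e[0], n[1] - n[0]]) / 0.01
        assert tangent[0] == pytest.approx(1.0, abs=1e-3)
        assert tangent[1] == pytest.approx(0.0, abs=1e-3)

    def test_arclength_parameterization(self):
        path = make_track_path(TrackGeometry())
        s = np.linspace(0, 399.9, 5000)
        e, n = path(s)
        speed = np.hypot(np.diff(e), np.diff(n)) / np.diff(s)
        assert np.allclose(speed, 1.0, atol=1e-6)

    def test_total_length_is_400(self):
        geom = TrackGeometry()
        path = make_track_path(geom)
        s = np.linspace(0, geom.lap_length, 400_000)
        e, n = path(s)
        length = np.sum(np.hypot(np.diff(e), np.diff(n)))
        assert length == pytest.approx(400.0, abs=1e-3)

    def test_closes_the_lap(self):
        geom = TrackGeometry()
        path = make_track_path(geom)
        e, n = path(np.array([geom.lap_length]))
        assert abs(e[0]) < 1e-9 and abs(n[0]) < 1e-9

    def test_bad_geometry_rejected(self):
        with pytest.raises(sg.ConfigError):
            make_track_path(TrackGeometry(straight_len=120.0))


class TestTruthConsistency:
    def test_velocity_identity_and_totals(self, clean_sim):
        truth = clean_sim.truth
        assert np.allclose(truth.v_true, truth.sf_true * truth.sl_true)
        assert np.all(np.diff(truth.ic_times) > 0)
        assert truth.total_steps == len(truth.ic_times)
        assert np.allclose(truth.sf_true[1:], 1.0 / np.diff(truth.ic_times))

    def test_sl_sum_matches_final_distance(self):
        from sprintgnss.simulate import step_schedules
        cfg = sg.preset("subjectB_like", seed=0)
        st, sl = step_schedules(cfg)
        assert np.sum(sl) == pytest.approx(400.0, abs=1e-6)
        assert np.sum(st) == pytest.approx(73.07, abs=1e-6)

    def test_midstance_between_ics(self, clean_sim):
        truth = clean_sim.truth
        assert np.all(truth.midstance_times > truth.ic_times)
        assert np.all(truth.midstance_times[:-1] < truth.ic_times[1:])

    def test_legs_alternate(self, clean_sim):
        legs = clean_sim.truth.legs
        assert all(a is not b for a, b in zip(legs, legs[1:]))


class TestPresets:
    def test_subject_scenarios(self):
        a = sg.preset("subjectA_like")
        assert a.n_steps == 200
        assert a.gait.peak_sl == pytest.approx(2.10)
        assert a.gait.peak_sf == pytest.approx(4.00)
        assert len(a.float_spans) > 0
        b = sg.preset("subjectB_like")
        assert b.n_steps == 242
        assert b.gait.peak_sl == pytest.approx(1.86)
        assert b.gait.peak_sf == pytest.approx(3.57)
        assert b.float_spans == ()

    def test_clean_preset_is_noise_free(self):
        c = sg.preset("clean_unit_test")
        assert c.noise.fix_sd_h == c.noise.fix_sd_v == 0
        assert c.noise.float_sd_h == c.noise.float_sd_v == 0

    def test_unknown_preset(self):
        with pytest.raises(sg.ConfigError):
            sg.preset("subjectC_like")


class TestSimulatedSignals:
    def test_clean_minima_at_truth_times(self, clean_sim):
        """Unfiltered clean signal: u minima at mid-stance (1 sample), v_u
        minima at IC (2 samples after smoothing by differentiation)."""
        e, n, u = clean_sim.clean_enu
        truth = clean_sim.truth
        t = np.array([s.t for s in clean_sim.traj.samples])
        rate = 100.0
        for tms in truth.midstance_times[1:-1]:
            k = np.argmin(np.abs(t - tms))
            w = slice(k - 8, k + 9)
            assert abs(t[w][np.argmin(u[w])] - tms) <= 1.01 / rate
        v = sg.differentiate(u, rate)
        for tic in truth.ic_times[1:-1]:
            k = np.argmin(np.abs(t - tic))
            w = slice(k - 8, k + 9)
            assert abs(t[w][np.argmin(v[w])] - tic) <= 2.01 / rate

    def test_gnss_roundtrip_within_noise(self):
        cfg = sg.SimConfig(n_steps=30, seed=8,
                           noise=NoiseConfig(fix_sd_h=0.01, fix_sd_v=0.02,
                                             float_sd_h=0.1, float_sd_v=0.2))
        res = sg.simulate_sprint(cfg)
        tr = sg.to_local_enu(res.traj)
        e, n, u = res.clean_enu
        assert np.std(tr.e - e) < 4 * 0.01
        assert np.std(tr.u - u) < 4 * 0.02

    def test_float_spans_set_status(self):
        cfg = sg.SimConfig(n_steps=30, seed=1, float_spans=((2.0, 3.0),))
        res = sg.simulate_sprint(cfg)
        status = np.array([s.status.value for s in res.traj.samples])
        t = np.array([s.t for s in res.traj.samples])
        inside = (t >= 2.0) & (t < 3.0)
        assert np.all(status[inside] == "FLOAT")
        assert np.all(status[~inside] == "FIX")

    def test_float_span_outside_duration_rejected(self):
        cfg = sg.SimConfig(n_steps=10, seed=1, float_spans=((0.0, 9999.0),))
        with pytest.raises(sg.ConfigError):
            sg.simulate_sprint(cfg)

    def test_determinism(self):
        a = sg.simulate_sprint(sg.SimConfig(n_steps=10, seed=42))
        b = sg.simulate_sprint(sg.SimConfig(n_steps=10, seed=42))
        assert np.array_equal([s.lat for s in a.traj.samples],
                              [s.lat for s in b.traj.samples])
        assert np.array_equal(a.imu_left.az, b.imu_left.az)

    def test_impacts_only_on_matching_leg(self, clean_sim):
        truth = clean_sim.truth
        left = clean_sim.imu_left
        for tic, leg in zip(truth.ic_times, truth.legs):
            k = np.searchsorted(left.t, tic + 0.003)
            peaked = left.az[k] > 3 * 9.80665
            assert peaked == (leg is Leg.LEFT)


class TestEndToEndRecovery:
    def test_clean_per_step_recovery(self, clean_sim, clean_kin):
        """Headline property: after the standard first-five-step exclusion,
        per-step SF within 0.05 Hz and SL within 0.02 m of truth."""
        truth = clean_sim.truth
        recs = sg.exclude_initial_steps(
            sg.build_step_records(sg.method2_events(clean_kin), clean_kin), 5)
        for r in recs:
            k = int(np.argmin(np.abs(truth.ic_times - r.t_end)))
            assert abs(r.sf - truth.sf_true[k]) < 0.05
            assert abs(r.sl - truth.sl_true[k]) < 0.02

    def test_subjectA_like_full_run(self):
        res = sg.simulate_sprint(sg.preset("subjectA_like", seed=0))
        kin = sg.build_kinematics(sg.to_local_enu(res.traj))
        truth = res.truth
        events = sg.method2_events(kin)
        pairs, _, unmatched_ref = sg.match_events(events, truth.ic_events())
        assert unmatched_ref <= 2  # virtually every true step is captured
        summ = sg.sprint_summary(
            kin, sg.build_step_records(events, kin), 400.0)
        pm = sg.percent_match(summ.total_time, truth.total_time)
        assert pm >= 99.8
        assert 0.4 <= summ.float_fraction <= 0.6
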