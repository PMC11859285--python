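"""Event detection and per-step parameter computation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sprintgnss as sg
from sprintgnss.detection import Leg, Method, Quality, Section
from conftest import make_kin


def brute_force_minima(x, distance, prominence):
    """Oracle: scan every sample; keep prominent local minima, deepest-first
    greedy thinning within ``distance`` samples (ties to the earlier)."""
    from scipy.signal import peak_prominences
    cand = [k for k in range(1, len(x) - 1)
            if x[k] < x[k - 1] and x[k] <= x[k + 1]]
    proms = peak_prominences(-np.asarray(x, float), cand)[0] if cand else []
    cand = [k for k, p in zip(cand, proms) if p >= prominence]
    kept = []
    for k in sorted(cand, key=lambda k: (x[k], k)):
        if all(abs(k - j) >= distance for j in kept):
            kept.append(k)
    return sorted(kept)


class TestDetectMinima:
    def test_sine_minima_spacing(self):
        rate, f = 100.0, 4.0
        t = np.arange(0, 3, 1 / rate)
        idx = sg.detect_minima(np.sin(2 * np.pi * f * t), rate, 0.15, 0.1)
        times = t[idx]
        # sine minima at (3/4 + k)/4 s, spaced 0.25 s
        assert np.allclose(np.diff(times), 0.25, atol=1e-6)
        k0 = round((times[0] - 3 / 16) * 4)
        assert times[0] == pytest.approx(3 / 16 + k0 / 4, abs=1.1 / rate)

    def test_monotone_series_has_no_events(self):
        assert len(sg.detect_minima(np.linspace(0, 1, 200), 100, 0.1, 0.01)) == 0

    def test_close_dips_keep_the_deeper(self):
        rate = 100.0
        x = np.zeros(300)
        x[100:105] -= 1.0 * np.sin(np.linspace(0, np.pi, 5))   # deep dip
        x[106:111] -= 0.3 * np.sin(np.linspace(0, np.pi, 5))   # shallow, 0.05 s later
        idx = sg.detect_minima(x, rate, 0.15, 0.05)
        assert brute_force_minima(x, 15, 0.05) == list(idx)
        assert len(idx) == 1 and x[idx[0]] == x.min()

    def test_flat_minimum_first_sample(self):
        x = np.concatenate([np.linspace(1, 0, 50), np.zeros(5),
                            np.linspace(0, 1, 50)])
        idx = sg.detect_minima(x, 100, 0.1, 0.1)
        assert list(idx) == [49]  # first sample of the flat run

    @settings(deadline=None, max_examples=40)
    @given(seed=st.integers(0, 10_000))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = np.convolve(rng.standard_normal(400), np.ones(9) / 9, "same")
        got = list(sg.detect_minima(x, 100.0, 0.12, 0.2))
        assert got == brute_force_minima(x, 12, 0.2)


class TestMethodEvents:
    def test_clean_counts_and_timing(self, clean_sim, clean_kin):
        truth = clean_sim.truth
        m1 = sg.method1_events(clean_kin)
        m2 = sg.method2_events(clean_kin)
        assert len(m1) == len(m2) == truth.total_steps
        assert np.max(np.abs([e.t for e in m1] - truth.midstance_times)) < 0.030
        assert np.max(np.abs([e.t for e in m2] - truth.ic_times)) < 0.020

    def test_stationary_trajectory_no_events(self, flat_kin):
        assert sg.method1_events(flat_kin) == []
        assert sg.method2_events(flat_kin) == []

    def test_pure_sine_velocity_minima_lag_quarter_period(self):
        rate, f = 100.0, 3.0
        t = np.arange(0, 10, 1 / rate)
        kin = make_kin(t, 0.05 * np.sin(2 * np.pi * f * t))
        t1 = np.array([e.t for e in sg.method1_events(kin)])
        t2 = np.array([e.t for e in sg.method2_events(kin)])
        # d/dt of a sine: the velocity minimum sits a quarter period away
        # from the position minimum (and both trains share the full period)
        quarter = 1 / (4 * f)
        nearest = np.array([np.min(np.abs(t1 - tv)) for tv in t2[1:-1]])
        assert np.allclose(nearest, quarter, atol=1.5 / rate)
        assert np.allclose(np.diff(t2), 1 / f, atol=1.5 / rate)

    def test_float_quality_flagging(self):
        rate = 100.0
        t = np.arange(0, 10, 1 / rate)
        status = np.full(len(t), "FIX", dtype=object)
        status[300:350] = "FLOAT"  # inside the second event's interval
        kin = make_kin(t, 0.05 * np.sin(2 * np.pi * 3.0 * t), status=status)
        events = sg.method1_events(kin)
        flagged = [e for e in events if e.quality is Quality.FLOAT_TOUCHED]
        assert len(flagged) >= 1
        assert all(e.sample_index >= 300 for e in flagged)

    def test_detection_invariant_to_offsets_and_rotation(self, clean_sim, clean_kin):
        tr = sg.to_local_enu(clean_sim.traj)
        th = 0.7
        e_r = tr.e * np.cos(th) - tr.n * np.sin(th) + 250.0
        n_r = tr.e * np.sin(th) + tr.n * np.cos(th) - 90.0
        rotated = sg.LocalTrack(t=tr.t, e=e_r, n=n_r, u=tr.u + 3.0,
                                status=tr.status, origin=tr.origin,
                                nominal_rate=tr.nominal_rate)
        kin_r = sg.build_kinematics(rotated)
        for fn in (sg.method1_events, sg.method2_events):
            a = [e.sample_index for e in fn(clean_kin)]
            b = [e.sample_index for e in fn(kin_r)]
            assert a == b


class TestStepRecords:
    def test_paper_scale_worked_example(self):
        # events 0.25 s apart with 2.10 m displacement: SF 4.00 Hz, v 8.40 m/s
        t = np.arange(0, 21, 0.01)
        u = 0.05 * np.sin(2 * np.pi * 4.0 * t)  # minima every 0.25 s
        e = 8.4 * t
        kin = make_kin(t, u, e=e)
        events = sg.method1_events(kin)
        rec = sg.build_step_records(events, kin)[5]
        assert rec.step_time == pytest.approx(0.25, abs=1e-3)
        assert rec.sf == pytest.approx(4.00, abs=0.02)
        assert rec.sl == pytest.approx(2.10, abs=0.02)
        assert rec.velocity == pytest.approx(8.40, abs=0.05)

    def test_zero_displacement(self):
        t = np.arange(0, 10, 0.01)
        kin = make_kin(t, 0.05 * np.sin(2 * np.pi * 2.0 * t))
        rec = sg.build_step_records(sg.method1_events(kin), kin)[0]
        assert rec.sf == pytest.approx(2.0, abs=0.01)
        assert rec.sl == pytest.approx(0.0, abs=1e-9)
        assert rec.velocity == pytest.approx(0.0, abs=1e-9)

    def test_velocity_identity_exact(self, clean_kin):
        recs = sg.build_step_records(sg.method2_events(clean_kin), clean_kin)
        for r in recs:
            assert r.velocity == r.sf * r.sl
            assert r.sf == 1.0 / r.step_time
            assert r.t_end > r.t_start

    def test_sl_sum_close_to_cumdist_increment(self, clean_kin):
        recs = sg.build_step_records(sg.method2_events(clean_kin), clean_kin)
        total_sl = sum(r.sl for r in recs)
        d = np.interp([recs[0].t_start, recs[-1].t_end], clean_kin.t,
                      clean_kin.cum_dist)
        assert total_sl == pytest.approx(d[1] - d[0], rel=0.01)

    def test_fewer_than_two_events_error(self, clean_kin):
        with pytest.raises(sg.DataError):
            sg.build_step_records([], clean_kin)


class TestLegsAndSections:
    def test_leg_alternation(self):
        events = [sg.StepEvent(t=float(k), sample_index=k,
                               method=Method.VELOCITY_MIN) for k in range(4)]
        labelled = sg.assign_legs(events, Leg.RIGHT)
        assert [e.leg for e in labelled] == [Leg.RIGHT, Leg.LEFT, Leg.RIGHT, Leg.LEFT]
        assert [e.leg for e in sg.assign_legs(events[:1], Leg.LEFT)] == [Leg.LEFT]

    def test_legs_match_simulator_truth(self, clean_sim, clean_kin):
        truth = clean_sim.truth
        events = sg.assign_legs(sg.method2_events(clean_kin), truth.legs[0])
        assert [e.leg for e in events] == truth.legs

    @pytest.mark.parametrize("d,expected", [
        (150, Section.STRAIGHT), (250, Section.CURVE), (200, Section.TRANSITION),
        (5, Section.CURVE), (115, Section.CURVE), (125, Section.STRAIGHT),
        (0, Section.TRANSITION), (400, Section.STRAIGHT), (4.9, Section.TRANSITION),
    ])
    def test_section_ranges(self, d, expected):
        assert sg.classify_section(d) is expected


class TestExclusionAndSummary:
    def test_exclude_first_five(self, clean_kin):
        recs = sg.build_step_records(sg.method2_events(clean_kin), clean_kin)
        kept = sg.exclude_initial_steps(recs, 5)
        assert len(kept) == len(recs) - 5
        assert kept[0].step_index == 6  # indices preserved

    def test_exclude_zero_is_identity(self, clean_kin):
        recs = sg.build_step_records(sg.method2_events(clean_kin), clean_kin)
        assert sg.exclude_initial_steps(recs, 0) == recs

    def test_exclude_more_than_available(self, clean_kin):
        recs = sg.build_step_records(sg.method2_events(clean_kin), clean_kin)[:3]
        assert sg.exclude_initial_steps(recs, 5) == []

    def test_summary_counts_footstrikes(self, clean_sim, clean_kin):
        truth = clean_sim.truth
        recs = sg.build_step_records(sg.method2_events(clean_kin), clean_kin)
        summ = sg.sprint_summary(clean_kin, recs,
                                 target_distance=truth.cum_dist_true[-1] - 0.5)
        assert summ.total_steps == truth.total_steps

    def test_summary_unreachable_distance(self, clean_kin):
        recs = sg.build_step_records(sg.method2_events(clean_kin), clean_kin)
        with pytest.raises(sg.DataError):
            sg.sprint_summary(clean_kin, recs, target_distance=1000.0)


class TestAsymmetryMechanism:
    """Left-right asymmetry corrupts Method 1's step segmentation, not Method 2's."""

    @staticmethod
    def median_step_time_error(method_fn, seed, asym):
        cfg = sg.SimConfig(n_steps=60, seed=seed, asym=asym)
        res = sg.simulate_sprint(cfg)
        kin = sg.build_kinematics(sg.to_local_enu(res.traj))
        truth = res.truth
        recs = sg.exclude_initial_steps(
            sg.build_step_records(method_fn(kin), kin), 5)
        errs = []
        for r in recs:
            k = int(np.argmin(np.abs(truth.ic_times - r.t_end)))
            if k >= 1 and abs(truth.ic_times[k] - r.t_end) < 0.1:
                true_dt = truth.ic_times[k] - truth.ic_times[k - 1]
                errs.append(abs(r.step_time - true_dt))
        return float(np.median(errs))

    def test_method2_beats_method1_under_asymmetry(self):
        seeds = range(20)
        m1 = np.median([self.median_step_time_error(sg.method1_events, s, 0.10)
                        for s in seeds])
        m2 = np.median([self.median_step_time_error(sg.method2_events, s, 0.10)
                        for s in seeds])
        assert m2 <= m1
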