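"""Event engine: determinism, conservation laws, queue-theory oracles."""

import numpy as np
import pandas as pd
import pytest

import sonoflow as sf
from conftest import single_server_profile
from sonoflow.distributions import (
    RandomStream,
    deterministic,
    exponential,
    sample,
    upper_bound,
)
from sonoflow.profile import ExamType, HospitalProfile, PatientClassConfig, RoomConfig


class TestSingleRuns:
    def test_idle_server_gives_zero_wait(self):
        prof = single_server_profile(
            None, deterministic(15.0), arrival_model="scheduled_interval", interval=1000.0
        )
        cal = sf.CalendarConfig(days_per_replication=1, warmup_minutes=0.0)
        res = sf.run_replication(prof, "points", cal, seed=0, collect_events=True)
        ev = res.events
        assert len(ev) == 1
        assert ev.room_entry_time.iloc[0] == ev.arrival_time.iloc[0]
        assert res.overall_mean_wait == 0.0
        assert ev.completion_time.iloc[0] == pytest.approx(15.0)

    def test_identical_seed_identical_result(self, profile, short_calendar):
        a = sf.run_replication(profile, "points", short_calendar, seed=3, collect_events=True)
        b = sf.run_replication(profile, "points", short_calendar, seed=3, collect_events=True)
        assert a.class_counts == b.class_counts
        assert a.room_utilization == b.room_utilization
        pd.testing.assert_frame_equal(a.events, b.events)

    def test_random_policy_reproducible(self, profile, short_calendar):
        a = sf.run_replication(profile, "random", short_calendar, seed=3)
        b = sf.run_replication(profile, "random", short_calendar, seed=3)
        assert a.room_utilization == b.room_utilization

    def test_infeasible_profile_raises(self):
        exam = ExamType("prostate", "fixed20", deterministic(10.0), "male_tech_only")
        cls = PatientClassConfig(
            "outpatient", 1.0, "scheduled_interval", (("prostate", 1.0),),
            interval_minutes=100.0,
        )
        prof = HospitalProfile((cls,), (exam,), (RoomConfig(5, "female"),))
        cal = sf.CalendarConfig(days_per_replication=1, warmup_minutes=0.0)
        with pytest.raises(ValueError, match="no eligible room"):
            sf.run_replication(prof, "points", cal, seed=0)


class TestInvariants:
    def test_all_measured_patients_complete(self, one_replication):
        """Conservation: every arrival in the measured window is examined
        (overtime exams run to completion)."""
        assert one_replication.completed_in_window_arrivals == one_replication.total_examined
        assert one_replication.total_examined == sum(one_replication.class_counts.values())

    def test_timestamps_monotone(self, one_replication):
        ev = one_replication.events
        assert (ev.room_entry_time >= ev.arrival_time - 1e-9).all()
        assert (ev.first_image_time >= ev.room_entry_time).all()
        assert (ev.completion_time >= ev.first_image_time).all()

    def test_sex_constraint_never_violated(self, one_replication, profile):
        ev = one_replication.events
        male_rooms = {r.room_id for r in profile.rooms if r.tech_sex == "male"}
        for exam_name in ("prostate", "scrotum"):
            sub = ev[ev.exam == exam_name]
            assert set(sub.room_id) <= male_rooms
            assert (sub.sex == "male").all()
        dvt = ev[ev.exam == "dvt"]
        male_dvt = dvt[dvt.sex == "male"]
        female_dvt = dvt[dvt.sex == "female"]
        assert set(male_dvt.room_id) <= male_rooms
        assert set(female_dvt.room_id) <= ({r.room_id for r in profile.rooms} - male_rooms)

    def test_points_counters_conserve_assigned_points(self, one_replication):
        """Sum of room point counters equals the points of patients assigned
        after the warm-up clear."""
        ev = one_replication.events
        measured = ev[ev.measured]
        assert sum(one_replication.room_points.values()) == measured.base_points.sum()

    def test_utilizations_in_unit_interval(self, one_replication):
        assert all(0.0 <= u <= 1.0 for u in one_replication.room_utilization.values())

    def test_fifo_within_each_room(self, one_replication):
        ev = one_replication.events.sort_values("arrival_time", kind="stable")
        for _, grp in ev.groupby("room_id"):
            entries = grp.room_entry_time.to_numpy()
            assert (np.diff(entries) >= -1e-9).all()

    def test_minutes_policy_bounded_counter_gap(self):
        """Greedy least-minutes dispatch keeps the spread of room minute
        counters below one maximal service duration."""
        exam = ExamType("scan", "fixed20", sf.triangular(10, 15, 20))
        cls = PatientClassConfig(
            "outpatient", 1.0, "scheduled_interval", (("scan", 1.0),), interval_minutes=4.0,
        )
        rooms = tuple(RoomConfig(i, "female") for i in range(5, 11))
        prof = HospitalProfile((cls,), (exam,), rooms, setup_spec=sf.triangular(1, 5, 9))
        cal = sf.CalendarConfig(days_per_replication=2, warmup_minutes=0.0)
        res = sf.run_replication(prof, "minutes", cal, seed=8)
        counters = list(res.room_minutes.values())
        max_service = upper_bound(exam.service_spec) + upper_bound(prof.setup_spec)
        assert max(counters) - min(counters) <= max_service + 1e-9


class TestLindleyOracle:
    def test_matches_independent_single_queue_recursion(self):
        """Engine waits on a single-room instance equal the Lindley
        recursion applied to the identical draw sequence."""
        seed = 17
        prof = single_server_profile(
            None, exponential(12.0), setup_spec=sf.triangular(1, 5, 9),
            arrival_model="scheduled_interval", interval=10.0,
        )
        cal = sf.CalendarConfig(effective_day_minutes=200.0, days_per_replication=1,
                                warmup_minutes=0.0)
        res = sf.run_replication(prof, "points", cal, seed=seed, collect_events=True)
        ev = res.events.sort_values("pid")
        n = len(ev)
        # reproduce the engine's per-patient draws from the same substreams
        setup_stream = RandomStream(seed, "setup")
        scan_stream = RandomStream(seed, "service/scan")
        setups = [sample(prof.setup_spec, setup_stream) for _ in range(n)]
        scans = [sample(prof.exams[0].service_spec, scan_stream) for _ in range(n)]
        arrivals = ev.arrival_time.to_numpy()
        prev_completion = 0.0
        expected_waits = []
        for i in range(n):
            start = max(arrivals[i], prev_completion)
            expected_waits.append(start - arrivals[i])
            prev_completion = start + setups[i] + scans[i]
        got = (ev.room_entry_time - ev.arrival_time).to_numpy()
        assert np.allclose(got, expected_waits)


class TestExperiments:
    def test_requires_two_replications(self, profile, short_calendar):
        with pytest.raises(ValueError):
            sf.run_experiment(profile, "points", short_calendar, 1, 0)

    def test_experiment_deterministic(self, profile, short_calendar):
        a = sf.run_experiment(profile, "points", short_calendar, 3, 5)
        b = sf.run_experiment(profile, "points", short_calendar, 3, 5)
        pd.testing.assert_frame_equal(a.per_rep, b.per_rep)

    def test_half_width_scales_like_inverse_sqrt_n(self):
        """Quadrupling the replication count roughly halves the half-width
        of a count measure."""
        prof = single_server_profile(exponential(10.0), deterministic(5.0))
        cal = sf.CalendarConfig(effective_day_minutes=400.0, days_per_replication=1,
                                warmup_minutes=0.0)
        h30 = sf.run_experiment(prof, "points", cal, 30, 2).stat("total_examined").half_width
        h120 = sf.run_experiment(prof, "points", cal, 120, 2).stat("total_examined").half_width
        assert 1.4 < h30 / h120 < 2.9


class TestWarmupScan:
    def test_empty_arrivals_constant_zero(self):
        prof = single_server_profile(exponential(1e9), deterministic(5.0))
        frame = sf.warmup_scan(prof, "points", sf.CalendarConfig(), 500.0, seed=0,
                               horizon=3000.0)
        assert (frame.room5 == 0.0).all()

    def test_mm1_running_utilization_converges_to_rho(self):
        """Single-room queue with offered load rho=2/3: the running
        utilization settles near 2/3."""
        prof = single_server_profile(exponential(30.0), exponential(20.0))
        frames = [
            sf.warmup_scan(prof, "points", sf.CalendarConfig(), 1000.0, seed=s,
                           horizon=20000.0)
            for s in range(8)
        ]
        tail = np.mean([f.room5.iloc[-1] for f in frames])
        assert abs(tail - 2.0 / 3.0) < 0.05

    def test_default_profile_flat_after_warmup(self, profile):
        """The Welch-averaged running utilization (mean over rooms and a
        handful of seeded runs) has no trend left over the last 20% of an
        extended run: the warm-up length is adequate."""
        frames = [
            sf.warmup_scan(profile, "points", sf.CalendarConfig(), 100.0, seed=s,
                           horizon=7200.0)
            for s in range(5)
        ]
        rooms = [c for c in frames[0].columns if c.startswith("room")]
        series = sum(f[rooms].mean(axis=1) for f in frames) / len(frames)
        last = series[frames[0].time >= 0.8 * 7200.0]
        assert abs(last.iloc[-1] - last.iloc[0]) < 0.01
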