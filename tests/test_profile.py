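"""Hospital profile: class mix, arrival generators, slot rules, weighted
points, serialization."""

import numpy as np
import pytest

import sonoflow as sf
from sonoflow.distributions import RandomStream, deterministic, exponential, mean_of
from sonoflow.profile import (
    MEASURED_WEEK_MINUTES,
    WEEKLY_TARGETS,
    profile_to_dict,
    case_hospital_profile,
    round_half_up,
)


class TestDefaultProfile:
    def test_class_shares(self, profile):
        """Normalized class shares reproduce the published mix within 1e-4
        and sum to one."""
        shares = {c.name: c.share for c in profile.classes}
        printed = {"outpatient": 0.7246, "inpatient": 0.1998, "emergency": 0.0757}
        for name, p in printed.items():
            assert shares[name] == pytest.approx(p, abs=1e-4)
        assert sum(shares.values()) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("cname,target", sorted(WEEKLY_TARGETS.items()))
    def test_arrival_rates_match_weekly_targets(self, profile, cname, target):
        """Expected arrivals per 5 measured days equal the weekly volumes
        the arrival stand-ins are calibrated to."""
        c = profile.patient_class(cname)
        expected = MEASURED_WEEK_MINUTES / mean_of(c.interarrival_spec)
        assert expected == pytest.approx(target, rel=1e-9)

    def test_room_layout(self, profile):
        assert len(profile.rooms) == 6
        sexes = {r.room_id: r.tech_sex for r in profile.rooms}
        assert all(sexes[i] == "female" for i in (5, 7, 9))
        assert all(sexes[i] == "male" for i in (6, 8, 10))

    def test_stand_in_service_means_sit_in_documented_bands(self, profile):
        for exam in profile.exams:
            if exam.name == "prostate":  # the published mixture, exempt
                continue
            m = exam.mean_service_minutes
            if exam.slot_rule == "fixed40":
                assert 30 <= m <= 45
            elif exam.slot_rule == "fixed20":
                assert 15 <= m <= 25

    def test_exam_mix_probabilities_sum_to_one(self, profile):
        for c in profile.classes:
            assert sum(p for _, p in c.exam_mix) == pytest.approx(1.0, abs=1e-9)

    def test_exam_mix_draw_frequencies(self, profile):
        """Exam draws over many patients reproduce the configured mix
        within 3 binomial SDs."""
        c = profile.patient_class("outpatient")
        names = [n for n, _ in c.exam_mix]
        probs = np.array([p for _, p in c.exam_mix])
        rng = RandomStream(21, "exam_mix").rng
        n = 100_000
        idx = rng.choice(len(names), size=n, p=probs)
        freq = np.bincount(idx, minlength=len(names)) / n
        sd = np.sqrt(probs * (1 - probs) / n)
        assert np.all(np.abs(freq - probs) < 3 * sd + 1e-12)

    def test_round_trips_through_yaml(self, profile, tmp_path):
        path = tmp_path / "profile.yaml"
        sf.save_profile(profile, path)
        assert profile_to_dict(sf.load_profile(path)) == profile_to_dict(profile)

    def test_shipped_reference_profile_matches_default(self, profile):
        assert profile_to_dict(case_hospital_profile()) == profile_to_dict(profile)


class TestScheduledArrivals:
    def test_single_per_epoch(self):
        times = sf.gen_scheduled_arrivals(18, 1, 447.36)
        assert len(times) == 25
        assert times[0] == 0.0 and times[-1] == 432.0
        assert np.allclose(np.diff(times), 18.0)

    def test_batches_share_timestamps(self):
        times = sf.gen_scheduled_arrivals(18, 3, 447.36)
        assert len(times) == 75
        assert np.array_equal(times[:3], [0.0, 0.0, 0.0])

    def test_empty_horizon(self):
        assert sf.gen_scheduled_arrivals(10, 1, 0).size == 0

    def test_bad_interval(self):
        with pytest.raises(ValueError):
            sf.gen_scheduled_arrivals(0, 1, 100)

    def test_deterministic_and_seed_free(self):
        a = sf.gen_scheduled_arrivals(7, 2, 300)
        b = sf.gen_scheduled_arrivals(7, 2, 300)
        assert np.array_equal(a, b)


class TestRenewalArrivals:
    def test_poisson_count_mean(self):
        """Exponential inter-arrivals give counts with mean horizon/mean-gap
        (checked over seeded runs within 3 SDs of the Poisson count law)."""
        m, horizon, n_runs = 12.0, 600.0, 1000
        counts = [
            sf.gen_renewal_arrivals(exponential(m), horizon, RandomStream(i, "arr")).size
            for i in range(n_runs)
        ]
        lam = horizon / m
        se = np.sqrt(lam / n_runs)
        assert abs(np.mean(counts) - lam) < 3 * se

    def test_deterministic_gaps(self):
        times = sf.gen_renewal_arrivals(deterministic(10.0), 45.0, RandomStream(0, "arr"))
        assert np.allclose(times, [10.0, 20.0, 30.0, 40.0])

    def test_zero_horizon_empty(self):
        assert sf.gen_renewal_arrivals(exponential(5), 0, RandomStream(0, "arr")).size == 0

    def test_reproducible_per_stream(self):
        a = sf.gen_renewal_arrivals(exponential(5), 500, RandomStream(4, "arr"))
        b = sf.gen_renewal_arrivals(exponential(5), 500, RandomStream(4, "arr"))
        assert np.array_equal(a, b)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            sf.gen_renewal_arrivals(deterministic(0.0), 100, RandomStream(0, "arr"))


class TestSlotAllocation:
    def test_fixed_rules(self, profile):
        stream = RandomStream(0, "slot")
        assert sf.allocate_slots(profile.exam("liver"), stream) == (40, 2)
        assert sf.allocate_slots(profile.exam("abdomen"), stream) == (20, 1)

    def test_dvt_split_frequency(self, profile):
        stream = RandomStream(13, "slot")
        draws = [sf.allocate_slots(profile.exam("dvt"), stream) for _ in range(10_000)]
        frac40 = np.mean([s == 40 for s, _ in draws])
        assert abs(frac40 - 0.30) < 0.015
        assert all(pts == (2 if s == 40 else 1) for s, pts in draws)


class TestWeightedPoints:
    @pytest.mark.parametrize(
        "mean,expected",
        [(16.35, 1.1), (20.0, 1.3), (40.0, 2.3)],
    )
    def test_examples(self, mean, expected):
        assert sf.weighted_points(mean) == pytest.approx(expected)

    def test_setup_share_rounds_half_up(self):
        # 5/20 = 0.25 -> 0.3 at one decimal
        assert round_half_up(0.25) == 0.3

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            sf.weighted_points(0.0)
        with pytest.raises(ValueError):
            sf.weighted_points(10.0, setup_minutes=-1)
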