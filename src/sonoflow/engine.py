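"""Event-driven patient-flow simulator.

One replication advances a continuous, compressed clock through a next-event
loop: patient arrivals (scheduled or renewal), room assignment at the
registration counter, per-room FIFO queues, a setup phase (registration
paperwork, positioning, first image) followed by the scanning phase, then
departure.  The working day is compressed to 447.36 effective minutes and a
5-day measured week follows a 5600-min warm-up, so a full replication spans
7836.8 min; statistics are cleared at the warm-up point and collected only
for patients arriving in the measured window.  Exams still in progress when
the horizon ends run to completion (and count), but busy time is credited
only up to the horizon.

Determinism: a replication is a pure function of (profile, policy, calendar,
seed).  Every stochastic process draws from its own seeded substream, so two
policies run with the same seed share identical arrival and service
realizations (common random numbers).
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import repstats
from .assignment import POLICIES, RoomState, assign_room, update_criterion
from .distributions import RandomStream, mean_of, sample
from .profile import (
    EFFECTIVE_DAY_MINUTES,
    HospitalProfile,
    allocate_slots,
    gen_renewal_arrivals,
    gen_scheduled_arrivals,
    round_half_up,
)

__all__ = [
    "CalendarConfig",
    "Patient",
    "ReplicationResult",
    "ExperimentSummary",
    "run_replication",
    "run_experiment",
    "warmup_scan",
]


@dataclass(frozen=True)
class CalendarConfig:
    """Compressed simulation calendar (all values in minutes)."""

    effective_day_minutes: float = EFFECTIVE_DAY_MINUTES
    days_per_replication: int = 5
    warmup_minutes: float = 5600.0

    def __post_init__(self) -> None:
        if self.effective_day_minutes <= 0 or self.days_per_replication <= 0:
            raise ValueError("calendar: day length and day count must be positive")
        if self.warmup_minutes < 0:
            raise ValueError("calendar: warm-up must be non-negative")

    @property
    def measured_minutes(self) -> float:
        return self.effective_day_minutes * self.days_per_replication

    @property
    def replication_minutes(self) -> float:
        return self.warmup_minutes + self.measured_minutes


class Patient:
    """One examination request and its timestamps along the path
    arrival -> room entry -> first image -> completion."""

    __slots__ = (
        "pid",
        "patient_class",
        "sex",
        "exam_name",
        "sex_constraint",
        "slot_minutes",
        "base_points",
        "setup_minutes",
        "scan_minutes",
        "arrival_time",
        "room_id",
        "room_entry_time",
        "first_image_time",
        "completion_time",
    )

    def __init__(self, pid, patient_class, sex, exam_name, sex_constraint,
                 slot_minutes, base_points, setup_minutes, scan_minutes, arrival_time):
        self.pid = pid
        self.patient_class = patient_class
        self.sex = sex
        self.exam_name = exam_name
        self.sex_constraint = sex_constraint
        self.slot_minutes = slot_minutes
        self.base_points = base_points
        self.setup_minutes = setup_minutes
        self.scan_minutes = scan_minutes
        self.arrival_time = arrival_time
        self.room_id = None
        self.room_entry_time = None
        self.first_image_time = None
        self.completion_time = None

    @property
    def waiting_time(self) -> float:
        return self.room_entry_time - self.arrival_time


@dataclass
class ReplicationResult:
    """Measured-window statistics of one replication."""

    class_counts: dict
    class_mean_waits: dict
    overall_mean_wait: float
    total_examined: int
    completed_in_window_arrivals: int
    room_utilization: dict
    room_points: dict
    room_minutes: dict
    room_weighted_points: dict
    workload_mean: float
    workload_sd: float
    events: pd.DataFrame | None = None


def _streams(profile: HospitalProfile, seed: int) -> dict:
    st = {
        "exam": RandomStream(seed, "exam_mix"),
        "sex": RandomStream(seed, "sex"),
        "dvt_slot": RandomStream(seed, "dvt_slot"),
        "setup": RandomStream(seed, "setup"),
        "policy": RandomStream(seed, "policy_random"),
    }
    for c in profile.classes:
        st[f"arrivals/{c.name}"] = RandomStream(seed, f"arrivals/{c.name}")
    for e in profile.exams:
        st[f"service/{e.name}"] = RandomStream(seed, f"service/{e.name}")
    return st


def _exam_weighted_points(profile: HospitalProfile) -> dict:
    setup_mean = mean_of(profile.setup_spec)
    wp = {}
    for e in profile.exams:
        scan_part = round_half_up(e.mean_service_minutes / 20.0)
        setup_part = round_half_up(setup_mean / 20.0) if setup_mean > 0 else 0.0
        wp[e.name] = scan_part + setup_part
    return wp


class _Simulation:
    """One seeded run of the next-event loop (internal)."""

    def __init__(self, profile, policy, calendar, seed, collect_events, horizon=None):
        if policy not in POLICIES:
            raise ValueError(f"policy: unknown policy {policy!r}")
        self.profile = profile
        self.policy = policy
        self.calendar = calendar
        self.seed = int(seed)
        self.collect_events = collect_events
        self.streams = _streams(profile, self.seed)
        self.weighted = _exam_weighted_points(profile)
        self.exam_names = [e.name for e in profile.exams]
        self.rooms = [RoomState(r.room_id, r.tech_sex) for r in profile.rooms]
        self.horizon_end = float(horizon if horizon is not None else calendar.replication_minutes)
        self.warmup = float(calendar.warmup_minutes) if horizon is None else 0.0
        self.patients: list[Patient] = []
        self._heap: list = []
        self._seq = 0
        self._probe_rows: list = []

    # event priorities: completions fire before arrivals at equal times so a
    # freed room is visible to a simultaneously registering patient
    _COMPLETE, _ARRIVAL, _RESET, _PROBE = 0, 1, -1, 2

    def _push(self, time, prio, kind, payload):
        self._seq += 1
        heapq.heappush(self._heap, (time, prio, self._seq, kind, payload))

    def _generate_arrivals(self):
        rows = []
        for c in self.profile.classes:
            if c.arrival_model == "scheduled_interval":
                if c.interval_minutes is None:
                    raise ValueError(f"class {c.name}: scheduled_interval needs interval_minutes")
                times = gen_scheduled_arrivals(c.interval_minutes, c.batch_size, self.horizon_end)
            else:
                if c.interarrival_spec is None:
                    raise ValueError(f"class {c.name}: renewal_process needs interarrival_spec")
                times = gen_renewal_arrivals(
                    c.interarrival_spec, self.horizon_end, self.streams[f"arrivals/{c.name}"]
                )
            for t in times:
                rows.append((float(t), c))
        rows.sort(key=lambda r: r[0])
        return rows

    def _make_patient(self, pid, t, cconf) -> Patient:
        names = [n for n, _ in cconf.exam_mix]
        probs = [p for _, p in cconf.exam_mix]
        exam_name = names[int(self.streams["exam"].rng.choice(len(names), p=probs))]
        exam = self.profile.exam(exam_name)
        if exam.sex_constraint == "male_tech_only":
            sex = "male"
        elif exam.name == "dvt" or exam.sex_constraint == "same_sex_tech":
            sex = "male" if self.streams["sex"].rng.uniform() < cconf.dvt_male_probability else "female"
        else:
            sex = "male" if self.streams["sex"].rng.uniform() < cconf.male_probability else "female"
        slot, pts = allocate_slots(exam, self.streams["dvt_slot"])
        setup = sample(self.profile.setup_spec, self.streams["setup"])
        scan = sample(exam.service_spec, self.streams[f"service/{exam.name}"])
        return Patient(pid, cconf.name, sex, exam.name, exam.sex_constraint,
                       slot, pts, setup, scan, t)

    def _start_service(self, room: RoomState, now: float):
        patient: Patient = room.queue.pop(0)
        patient.room_entry_time = now
        patient.first_image_time = now + patient.setup_minutes
        patient.completion_time = patient.first_image_time + patient.scan_minutes
        room.in_service = patient
        self._push(patient.completion_time, self._COMPLETE, "complete", room)

    def _credit_busy(self, room: RoomState, start: float, end: float):
        lo = max(start, self.warmup)
        hi = min(end, self.horizon_end)
        if hi > lo:
            room.busy_minutes += hi - lo

    def run(self, probe_interval=None):
        arrivals = self._generate_arrivals()
        for t, cconf in arrivals:
            self._push(t, self._ARRIVAL, "arrival", cconf)
        if self.warmup > 0:
            self._push(self.warmup, self._RESET, "reset", None)
        if probe_interval:
            t = probe_interval
            while t <= self.horizon_end + 1e-9:
                self._push(t, self._PROBE, "probe", None)
                t += probe_interval
        pid = 0
        while self._heap:
            now, _, _, kind, payload = heapq.heappop(self._heap)
            if kind == "arrival":
                pid += 1
                p = self._make_patient(pid, now, payload)
                room = assign_room(p.patient_class, p.sex, self.profile.exam(p.exam_name),
                                   self.rooms, self.policy, self.streams["policy"])
                p.room_id = room.room_id
                update_criterion(room, p.base_points, p.setup_minutes + p.scan_minutes,
                                 self.weighted[p.exam_name])
                self.patients.append(p)
                room.queue.append(p)
                if room.in_service is None:
                    self._start_service(room, now)
            elif kind == "complete":
                room: RoomState = payload
                done: Patient = room.in_service
                self._credit_busy(room, done.room_entry_time, done.completion_time)
                room.in_service = None
                if room.queue:
                    self._start_service(room, now)
            elif kind == "reset":
                for room in self.rooms:
                    room.reset_counters()
            elif kind == "probe":
                self._probe_rows.append(self._probe(now))
        return self._collect()

    def _probe(self, now: float) -> dict:
        row = {"time": now}
        for room in self.rooms:
            busy = room.busy_minutes
            if room.in_service is not None:
                busy += max(0.0, now - max(room.in_service.room_entry_time, self.warmup))
            row[f"room{room.room_id}"] = busy / now if now > 0 else 0.0
        return row

    def probe_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self._probe_rows)

    def _collect(self) -> ReplicationResult:
        measured = [p for p in self.patients
                    if self.warmup <= p.arrival_time < self.horizon_end]
        class_names = [c.name for c in self.profile.classes]
        counts = {n: 0 for n in class_names}
        waits: dict = {n: [] for n in class_names}
        for p in measured:
            counts[p.patient_class] += 1
            waits[p.patient_class].append(p.waiting_time)
        mean_waits = {n: (float(np.mean(w)) if w else math.nan) for n, w in waits.items()}
        all_waits = [p.waiting_time for p in measured]
        denom = self.horizon_end - self.warmup
        util = {r.room_id: r.busy_minutes / denom for r in self.rooms}
        completed = sum(1 for p in measured if p.completion_time is not None)
        upct = np.asarray([u * 100.0 for u in util.values()])
        wl_mean = float(upct.mean())
        wl_sd = float(upct.std(ddof=1)) if upct.size > 1 else 0.0
        events = None
        if self.collect_events:
            events = pd.DataFrame(
                {
                    "pid": [p.pid for p in self.patients],
                    "patient_class": [p.patient_class for p in self.patients],
                    "sex": [p.sex for p in self.patients],
                    "exam": [p.exam_name for p in self.patients],
                    "slot_minutes": [p.slot_minutes for p in self.patients],
                    "base_points": [p.base_points for p in self.patients],
                    "arrival_time": [p.arrival_time for p in self.patients],
                    "room_id": [p.room_id for p in self.patients],
                    "room_entry_time": [p.room_entry_time for p in self.patients],
                    "first_image_time": [p.first_image_time for p in self.patients],
                    "completion_time": [p.completion_time for p in self.patients],
                    "measured": [
                        self.warmup <= p.arrival_time < self.horizon_end for p in self.patients
                    ],
                }
            )
        return ReplicationResult(
            class_counts=counts,
            class_mean_waits=mean_waits,
            overall_mean_wait=float(np.mean(all_waits)) if all_waits else math.nan,
            total_examined=len(measured),
            completed_in_window_arrivals=completed,
            room_utilization=util,
            room_points={r.room_id: r.points for r in self.rooms},
            room_minutes={r.room_id: r.minutes for r in self.rooms},
            room_weighted_points={r.room_id: r.weighted_points for r in self.rooms},
            workload_mean=wl_mean,
            workload_sd=wl_sd,
            events=events,
        )


def run_replication(
    profile: HospitalProfile,
    policy: str,
    calendar: CalendarConfig,
    seed: int,
    collect_events: bool = False,
) -> ReplicationResult:
    """Run one seeded replication; identical seeds give identical results."""
    sim = _Simulation(profile, policy, calendar, seed, collect_events)
    return sim.run()


@dataclass
class ExperimentSummary:
    """Across-replication summary of one experiment (profile x policy)."""

    policy: str
    n_reps: int
    per_rep: pd.DataFrame  # one row per replication, one column per measure
    stats: dict  # measure name -> ReplicationStats

    def stat(self, name: str) -> repstats.ReplicationStats:
        return self.stats[name]


def _rep_seed(base_seed: int, rep: int) -> int:
    return (int(base_seed) * 100_003 + rep) % (2**31 - 1)


def run_experiment(
    profile: HospitalProfile,
    policy: str,
    calendar: CalendarConfig,
    n_reps: int,
    base_seed: int,
) -> ExperimentSummary:
    """Run ``n_reps`` independent replications and summarise each measure by
    its mean, SD and 95% half-width."""
    if n_reps < 2:
        raise ValueError("n_reps: need at least two replications (SD undefined)")
    rows = []
    for r in range(n_reps):
        res = run_replication(profile, policy, calendar, _rep_seed(base_seed, r))
        row = {"rep": r, "total_examined": res.total_examined,
               "wait_overall": res.overall_mean_wait,
               "workload_mean": res.workload_mean, "workload_sd": res.workload_sd}
        for cname, cnt in res.class_counts.items():
            row[f"count_{cname}"] = cnt
            row[f"wait_{cname}"] = res.class_mean_waits[cname]
        for rid, u in res.room_utilization.items():
            row[f"util_room{rid}"] = u * 100.0
        rows.append(row)
    per_rep = pd.DataFrame(rows).set_index("rep")
    stats = {
        col: repstats.summarize(per_rep[col].dropna().to_numpy())
        for col in per_rep.columns
        if per_rep[col].dropna().size >= 2
    }
    return ExperimentSummary(policy=policy, n_reps=n_reps, per_rep=per_rep, stats=stats)


def warmup_scan(
    profile: HospitalProfile,
    policy: str,
    calendar: CalendarConfig,
    probe_interval: float,
    seed: int,
    horizon: float = 7200.0,
) -> pd.DataFrame:
    """Running room utilization sampled every ``probe_interval`` minutes over
    an extended horizon (no warm-up clearing), for warm-up-length diagnosis."""
    if probe_interval <= 0:
        raise ValueError("probe_interval: must be positive")
    sim = _Simulation(profile, policy, calendar, seed, collect_events=False, horizon=horizon)
    sim.run(probe_interval=probe_interval)
    return sim.probe_frame()
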