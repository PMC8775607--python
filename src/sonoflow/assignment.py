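"""Examination-room dispatch: eligibility rules and balance criteria.

At registration every patient is routed to exactly one of the six rooms by a
fixed decision tree:

1. sex-constrained exams first -- a male patient needing a prostate, scrotal
   or DVT exam may only go to the male-technologist rooms (6, 8, 10); a
   female DVT patient only to the female-technologist rooms (5, 7, 9);
2. an inpatient goes straight to room 5 when nobody is waiting there,
   otherwise to the least-loaded room overall;
3. an emergency patient likewise gets priority access to room 6;
4. everyone else goes to the least-loaded room overall.

"Least loaded" is measured by the active policy's balance counter:

``points``
    cumulative base examination points (1 per 20-min slot, 2 per 40-min) --
    the department's current practice;
``minutes``
    cumulative committed examination time (setup + scanning minutes);
``random``
    a uniform draw over the eligible rooms;
``weighted_points``
    cumulative weighted points (per-exam mean scanning time and the setup
    time each scored against a 20-min baseline).

Ties break to the lowest room id.  All three counters are maintained on
every run regardless of the active policy so reports can show them side by
side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .distributions import RandomStream
from .profile import ExamType

__all__ = ["POLICIES", "RoomState", "eligible_rooms", "assign_room", "update_criterion"]

POLICIES = ("points", "minutes", "random", "weighted_points")

MALE_ONLY_EXAMS = ("prostate", "scrotum")


@dataclass
class RoomState:
    """Mutable per-room state: FIFO queue, busy bookkeeping, balance counters."""

    room_id: int
    tech_sex: str
    queue: list = field(default_factory=list)
    in_service: object = None
    busy_minutes: float = 0.0
    points: float = 0.0
    minutes: float = 0.0
    weighted_points: float = 0.0

    def queue_length(self) -> int:
        """Waiting patients, excluding any patient currently in service."""
        return len(self.queue)

    def criterion(self, policy: str) -> float:
        if policy == "points":
            return self.points
        if policy == "minutes":
            return self.minutes
        if policy == "weighted_points":
            return self.weighted_points
        raise ValueError(f"policy: no balance counter for {policy!r}")

    def reset_counters(self) -> None:
        self.points = 0.0
        self.minutes = 0.0
        self.weighted_points = 0.0


def eligible_rooms(sex: str, exam: ExamType, rooms: list) -> list:
    """Rooms allowed for a patient of ``sex`` needing ``exam``.

    Raises ``ValueError`` for the impossible female prostate/scrotum case.
    """
    if exam.sex_constraint == "male_tech_only":
        if sex != "male":
            raise ValueError(
                f"patient: {exam.name} exams are male-patient-only, got sex={sex!r}"
            )
        return [r for r in rooms if r.tech_sex == "male"]
    if exam.sex_constraint == "same_sex_tech":
        return [r for r in rooms if r.tech_sex == sex]
    return list(rooms)


def _min_criterion(candidates: list, policy: str, stream: RandomStream | None):
    if policy == "random":
        if stream is None:
            raise ValueError("policy=random requires a random stream")
        return candidates[int(stream.rng.integers(len(candidates)))]
    best = min(candidates, key=lambda r: (r.criterion(policy), r.room_id))
    return best


def assign_room(
    patient_class: str,
    sex: str,
    exam: ExamType,
    rooms: list,
    policy: str,
    stream: RandomStream | None = None,
):
    """Pick the room for one registering patient; returns the RoomState.

    Follows the dispatch tree described in the module docstring; the
    priority-room branches (inpatient -> 5, emergency -> 6) trigger only
    when the priority room's queue is empty (a busy room with an empty
    queue still receives the patient).
    """
    if policy not in POLICIES:
        raise ValueError(f"policy: unknown policy {policy!r}")
    candidates = eligible_rooms(sex, exam, rooms)
    if not candidates:
        raise ValueError(
            f"patient: no eligible room for sex={sex!r}, exam={exam.name!r}"
        )
    # branch 1: sex-constrained exams bypass the priority rooms
    if exam.sex_constraint != "none":
        return _min_criterion(candidates, policy, stream)
    by_id = {r.room_id: r for r in candidates}
    if patient_class == "inpatient" and 5 in by_id and by_id[5].queue_length() == 0:
        return by_id[5]
    if patient_class == "emergency" and 6 in by_id and by_id[6].queue_length() == 0:
        return by_id[6]
    return _min_criterion(candidates, policy, stream)


def update_criterion(
    room: RoomState,
    base_points: int,
    committed_minutes: float,
    exam_weighted_points: float,
) -> None:
    """Charge an assigned patient's load to the room's three balance counters.

    ``committed_minutes`` is the patient's examination duration (setup +
    scanning) as committed at assignment time, so the dispatcher always sees
    the load it has already placed.
    """
    room.points += base_points
    room.minutes += committed_minutes
    room.weighted_points += exam_weighted_points
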