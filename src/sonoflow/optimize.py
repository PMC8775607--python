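"""Constrained search over outpatient appointment settings.

A transparent exhaustive grid search stands in for a black-box simulation
optimizer: each candidate (appointment interval, batch size, policy) is
evaluated by a full replication experiment; a candidate is feasible when
every room's mean utilization clears the lower bound (and an optional upper
bound) and the mean number of patients examined exceeds a volume threshold.
The objective is the class-weighted mean waiting time
``sum_c N_c * W_c / sum_c N_c``.  All candidates share the same replication
seeds (common random numbers), so differences between candidates reflect the
settings, not sampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass

from .engine import CalendarConfig, ExperimentSummary, run_experiment
from .profile import MEASURED_WEEK_MINUTES, HospitalProfile

__all__ = [
    "Candidate",
    "Constraints",
    "CandidateReport",
    "OptimizationResult",
    "objective",
    "evaluate_candidate",
    "search",
]


@dataclass(frozen=True)
class Candidate:
    interval_minutes: int
    batch_size: int = 1
    policy: str = "points"

    def __post_init__(self) -> None:
        if self.interval_minutes < 1:
            raise ValueError("interval_minutes: must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size: must be >= 1")


@dataclass(frozen=True)
class Constraints:
    """Feasibility bounds.

    ``min_total_examined`` refers to a 5-day (2236.8-min) measured week and
    is scaled linearly when the experiment measures a different horizon, so
    reduced-scale runs stay meaningful.
    """

    min_room_utilization: float = 0.70
    max_room_utilization: float | None = None  # e.g. 0.75 to cap workloads
    min_total_examined: float = 485.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_room_utilization <= 1.0):
            raise ValueError("min_room_utilization: must be in [0, 1]")
        if self.max_room_utilization is not None and not (
            self.min_room_utilization < self.max_room_utilization <= 1.0
        ):
            raise ValueError("max_room_utilization: must exceed the minimum and be <= 1")

    def scaled_min_total(self, measured_minutes: float) -> float:
        return self.min_total_examined * measured_minutes / MEASURED_WEEK_MINUTES


@dataclass
class CandidateReport:
    candidate: Candidate
    objective: float
    min_utilization: float
    max_utilization: float
    mean_total_examined: float
    feasible: bool
    violated: tuple = ()
    n_reps: int = 0


@dataclass
class OptimizationResult:
    reports: list
    feasible: list  # feasible reports sorted ascending by objective
    best: CandidateReport | None


def objective(summary: ExperimentSummary) -> float:
    """Class-weighted mean waiting time (minutes)."""
    num = 0.0
    den = 0.0
    for col in summary.per_rep.columns:
        if not col.startswith("count_"):
            continue
        cname = col[len("count_"):]
        n_c = summary.stat(col).mean
        if n_c == 0:
            continue
        w_col = f"wait_{cname}"
        if w_col not in summary.stats:
            continue
        num += n_c * summary.stat(w_col).mean
        den += n_c
    if den == 0:
        raise ValueError("objective: no patients in the experiment")
    return num / den


def evaluate_candidate(
    candidate: Candidate,
    profile: HospitalProfile,
    calendar: CalendarConfig,
    constraints: Constraints,
    n_reps: int,
    base_seed: int,
) -> CandidateReport:
    """Run the candidate's experiment and report objective + feasibility."""
    prof = profile.with_outpatient_schedule(candidate.interval_minutes, candidate.batch_size)
    summary = run_experiment(prof, candidate.policy, calendar, n_reps, base_seed)
    utils = [
        summary.stat(c).mean / 100.0
        for c in summary.per_rep.columns
        if c.startswith("util_room")
    ]
    total = summary.stat("total_examined").mean
    threshold = constraints.scaled_min_total(calendar.measured_minutes)
    violated = []
    if min(utils) < constraints.min_room_utilization:
        violated.append("min_room_utilization")
    if (
        constraints.max_room_utilization is not None
        and max(utils) > constraints.max_room_utilization
    ):
        violated.append("max_room_utilization")
    if not total > threshold:
        violated.append("min_total_examined")
    return CandidateReport(
        candidate=candidate,
        objective=objective(summary),
        min_utilization=min(utils),
        max_utilization=max(utils),
        mean_total_examined=total,
        feasible=not violated,
        violated=tuple(violated),
        n_reps=n_reps,
    )


def search(
    candidates: list,
    profile: HospitalProfile,
    calendar: CalendarConfig,
    constraints: Constraints,
    n_reps: int,
    base_seed: int,
) -> OptimizationResult:
    """Exhaustively evaluate all candidates; the best is the feasible one
    with the smallest objective (an empty feasible set is reported, not an
    error)."""
    if not candidates:
        raise ValueError("candidates: need at least one candidate")
    reports = [
        evaluate_candidate(c, profile, calendar, constraints, n_reps, base_seed)
        for c in candidates
    ]
    feasible = sorted((r for r in reports if r.feasible), key=lambda r: r.objective)
    return OptimizationResult(
        reports=reports, feasible=feasible, best=feasible[0] if feasible else None
    )
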