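"""Scenario runners and table-style reports.

The study design compares the department's current practice with targeted
changes:

* ``as_is`` -- current arrivals (renewal stand-in), points-balanced dispatch;
* ``s1`` -- Scenario 1: search the outpatient appointment interval (1..30
  min, batch 1) under the feasibility constraints, points dispatch;
* ``s2_stage1`` -- Scenario 2, stage 1: compare dispatch policies
  points / minutes / random under AS-IS arrivals;
* ``s2_stage2`` -- Scenario 2, stage 2: compare points / minutes /
  weighted-points;
* ``s3`` -- Scenario 3: joint search over interval and batch size with
  weighted-points dispatch.

Each run emits ``summary.csv`` (one column pair per model: mean and 95%
half-width; rows are total examined, mean wait, the six room utilizations,
mean workload and across-room workload SD), ``events.csv`` (per-patient
timestamps of a reference replication), ``candidates.csv`` for the search
scenarios, and a ``run_metadata.json`` with seeds and settings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .engine import CalendarConfig, ExperimentSummary, run_experiment, run_replication
from .optimize import Candidate, Constraints, OptimizationResult, search
from .profile import HospitalProfile, default_profile, profile_to_dict

__all__ = ["ScenarioConfig", "summary_table", "run_scenario", "SCENARIOS"]

SCENARIOS = ("as_is", "s1", "s2_stage1", "s2_stage2", "s3")

_ROW_ORDER = ["total_examined", "wait_overall"]


@dataclass
class ScenarioConfig:
    scenario: str
    profile: HospitalProfile = field(default_factory=default_profile)
    calendar: CalendarConfig = field(default_factory=CalendarConfig)
    n_reps: int = 110
    base_seed: int = 20220115
    out_dir: str | Path = "sonoflow_out"
    intervals: tuple = tuple(range(1, 31))  # s1/s3 candidate grid
    batches: tuple = (1,)
    constraints: Constraints = field(default_factory=Constraints)

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario: unknown scenario id {self.scenario!r}")


def summary_table(summaries: dict[str, ExperimentSummary]) -> pd.DataFrame:
    """Comparison table: one (mean, 95% half-width) column pair per model."""
    first = next(iter(summaries.values()))
    util_rows = sorted(c for c in first.per_rep.columns if c.startswith("util_room"))
    rows = _ROW_ORDER + util_rows + ["workload_mean", "workload_sd"]
    labels = {
        "total_examined": "Average total number of examined patients",
        "wait_overall": "Patient's average waiting time (min)",
        "workload_mean": "Mean workload across rooms (%)",
        "workload_sd": "SD of workload across rooms (%)",
    }
    for r in util_rows:
        labels[r] = f"Workload, room {r.removeprefix('util_room')} (%)"
    data = {}
    for name, s in summaries.items():
        data[(name, "mean")] = [round(s.stat(r).mean, 2) for r in rows]
        data[(name, "half_width")] = [round(s.stat(r).half_width, 2) for r in rows]
    return pd.DataFrame(data, index=[labels[r] for r in rows])


def _candidate_frame(result: OptimizationResult) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "interval_minutes": [r.candidate.interval_minutes for r in result.reports],
            "batch_size": [r.candidate.batch_size for r in result.reports],
            "policy": [r.candidate.policy for r in result.reports],
            "objective_minutes": [round(r.objective, 3) for r in result.reports],
            "min_room_utilization": [round(r.min_utilization, 4) for r in result.reports],
            "max_room_utilization": [round(r.max_utilization, 4) for r in result.reports],
            "mean_total_examined": [round(r.mean_total_examined, 2) for r in result.reports],
            "feasible": [r.feasible for r in result.reports],
            "violated": ["|".join(r.violated) for r in result.reports],
        }
    )


def run_scenario(config: ScenarioConfig) -> dict:
    """Execute one scenario and write its report files; returns the paths
    plus in-memory results."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prof, cal = config.profile, config.calendar
    summaries: dict[str, ExperimentSummary] = {}
    opt_result: OptimizationResult | None = None
    event_profile, event_policy = prof, "points"

    if config.scenario == "as_is":
        summaries["as_is_points"] = run_experiment(prof, "points", cal, config.n_reps, config.base_seed)
    elif config.scenario == "s2_stage1":
        for pol in ("points", "minutes", "random"):
            summaries[pol] = run_experiment(prof, pol, cal, config.n_reps, config.base_seed)
    elif config.scenario == "s2_stage2":
        for pol in ("points", "minutes", "weighted_points"):
            summaries[pol] = run_experiment(prof, pol, cal, config.n_reps, config.base_seed)
    elif config.scenario in ("s1", "s3"):
        policy = "points" if config.scenario == "s1" else "weighted_points"
        batches = (1,) if config.scenario == "s1" else config.batches
        cands = [
            Candidate(i, b, policy) for i in config.intervals for b in batches
        ]
        opt_result = search(cands, prof, cal, config.constraints, config.n_reps, config.base_seed)
        summaries["as_is_points"] = run_experiment(prof, "points", cal, config.n_reps, config.base_seed)
        if opt_result.best is not None:
            c = opt_result.best.candidate
            best_prof = prof.with_outpatient_schedule(c.interval_minutes, c.batch_size)
            summaries[f"best_{c.interval_minutes}min_x{c.batch_size}"] = run_experiment(
                best_prof, c.policy, cal, config.n_reps, config.base_seed
            )
            event_profile, event_policy = best_prof, c.policy

    table = summary_table(summaries)
    table.to_csv(out / "summary.csv")
    # per-patient event log of a reference replication (first seed)
    ref = run_replication(event_profile, event_policy, cal, config.base_seed, collect_events=True)
    ref.events.to_csv(out / "events.csv", index=False)
    paths = {"summary": out / "summary.csv", "events": out / "events.csv"}
    if opt_result is not None:
        _candidate_frame(opt_result).to_csv(out / "candidates.csv", index=False)
        paths["candidates"] = out / "candidates.csv"
    meta = {
        "scenario": config.scenario,
        "n_reps": config.n_reps,
        "base_seed": config.base_seed,
        "calendar": {
            "effective_day_minutes": cal.effective_day_minutes,
            "days_per_replication": cal.days_per_replication,
            "warmup_minutes": cal.warmup_minutes,
        },
        "profile": profile_to_dict(prof),
    }
    with open(out / "run_metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    paths["metadata"] = out / "run_metadata.json"
    return {"paths": paths, "summaries": summaries, "optimization": opt_result, "table": table}
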