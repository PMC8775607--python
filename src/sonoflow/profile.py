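"""Synthetic hospital profile: patient mixes, exam catalogue, arrival streams.

The default profile emulates a six-room hospital ultrasound department:

* three patient classes -- outpatients (72.46%), inpatients (19.98%) and
  emergency patients (7.57%) of the weekly volume;
* an exam catalogue with 20-min and 40-min appointment slots (liver takes two
  consecutive 20-min slots; deep-vein-thrombosis exams take one slot 70% of
  the time and two slots 30% of the time);
* sex constraints: prostate and scrotum exams are male-patient-only and must
  be performed by a male technologist; DVT exams need a technologist of the
  patient's sex;
* six examination rooms numbered 5..10, female technologists in the odd
  rooms (5, 7, 9) and male technologists in the even rooms (6, 8, 10).

Arrival processes are calibrated so that a 5-day measured week (5 x 447.36
effective minutes) sees on average 355.3 outpatients, 93.0 inpatients and
37.9 emergency patients.  The per-body-part scanning-time laws of the case
department are not public; except for the prostate mixture (which is), the
catalogue ships documented synthetic stand-ins whose means lie in
[15, 25] min for single-slot exams and [30, 45] min for double-slot exams.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Any

import numpy as np
import yaml

from .distributions import (
    DistributionSpec,
    RandomStream,
    exponential,
    lower_bound,
    mean_of,
    mixture,
    spec_from_dict,
    spec_to_dict,
    triangular,
    weibull_scaled,
    beta_scaled,
)

__all__ = [
    "ExamType",
    "PatientClassConfig",
    "RoomConfig",
    "HospitalProfile",
    "PROSTATE_MIXTURE",
    "default_profile",
    "gen_scheduled_arrivals",
    "gen_renewal_arrivals",
    "allocate_slots",
    "weighted_points",
    "round_half_up",
    "profile_to_dict",
    "profile_from_dict",
    "save_profile",
    "load_profile",
    "case_hospital_profile",
]

# Effective minutes of examination work per day (480 x 93.2%) and the
# measured horizon of one replication week.
EFFECTIVE_DAY_MINUTES = 447.36
MEASURED_WEEK_MINUTES = 5 * EFFECTIVE_DAY_MINUTES  # 2236.8

#: Weekly arrival targets per patient class (patients per 5 measured days).
WEEKLY_TARGETS = {"outpatient": 355.3, "inpatient": 93.0, "emergency": 37.9}

#: Patient-class shares of total volume (printed percentages sum to 100.01%
#: from table rounding; stored normalized so they sum to exactly 1).
_RAW_SHARES = {"outpatient": 0.7246, "inpatient": 0.1998, "emergency": 0.0757}
CLASS_SHARES = {k: v / sum(_RAW_SHARES.values()) for k, v in _RAW_SHARES.items()}

#: The one scanning-time law that is public: outpatient prostate exams,
#: a three-part offset Beta/Weibull mixture (minutes).
PROSTATE_MIXTURE = mixture(
    [
        (0.485, beta_scaled(3.0, 7.0, 1.9, 1.16)),
        (0.424, weibull_scaled(10.0, 3.46, 1.23)),
        (0.091, weibull_scaled(20.0, 6.99, 1.29)),
    ]
)


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal round-half-up (0.25 -> 0.3 at one decimal)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def weighted_points(
    mean_exam_minutes: float, setup_minutes: float = 5.0, base: float = 20.0
) -> float:
    """Weighted examination points for one exam type.

    The exam's mean scanning time and the setup time are each divided by the
    20-min baseline slot and rounded half-up to one decimal, then summed
    (e.g. a 16.35-min scan -> 0.8, a 5-min setup -> 0.3, total 1.1 points).
    """
    if mean_exam_minutes <= 0 or setup_minutes <= 0 or base <= 0:
        raise ValueError("weighted_points: all arguments must be positive")
    return round_half_up(mean_exam_minutes / base) + round_half_up(setup_minutes / base)


@dataclass(frozen=True)
class ExamType:
    """One body-part examination: slot rule, scanning-time law, sex rule."""

    name: str
    slot_rule: str  # fixed20 | fixed40 | dvt_split
    service_spec: DistributionSpec
    sex_constraint: str = "none"  # none | male_tech_only | same_sex_tech

    def __post_init__(self) -> None:
        if self.slot_rule not in ("fixed20", "fixed40", "dvt_split"):
            raise ValueError(f"slot_rule: unknown rule {self.slot_rule!r}")
        if self.sex_constraint not in ("none", "male_tech_only", "same_sex_tech"):
            raise ValueError(f"sex_constraint: unknown value {self.sex_constraint!r}")

    @property
    def mean_service_minutes(self) -> float:
        return mean_of(self.service_spec)

    def weighted_points(self, setup_minutes: float = 5.0) -> float:
        return weighted_points(self.mean_service_minutes, setup_minutes)


@dataclass(frozen=True)
class PatientClassConfig:
    """Arrival process and case mix for one patient class."""

    name: str  # outpatient | inpatient | emergency
    share: float
    arrival_model: str  # scheduled_interval | renewal_process
    exam_mix: tuple  # ((exam name, probability), ...)
    interval_minutes: float | None = None
    batch_size: int = 1
    interarrival_spec: DistributionSpec | None = None
    male_probability: float = 0.5
    dvt_male_probability: float = 3.0 / 7.0  # male:female 3:4 among DVT patients

    def __post_init__(self) -> None:
        if self.arrival_model not in ("scheduled_interval", "renewal_process"):
            raise ValueError(f"arrival_model: unknown model {self.arrival_model!r}")
        if self.batch_size < 1:
            raise ValueError("batch_size: must be >= 1")
        tot = sum(p for _, p in self.exam_mix)
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"exam_mix: probabilities must sum to 1, got {tot}")


@dataclass(frozen=True)
class RoomConfig:
    room_id: int
    tech_sex: str  # male | female

    def __post_init__(self) -> None:
        if self.tech_sex not in ("male", "female"):
            raise ValueError(f"tech_sex: unknown value {self.tech_sex!r}")


@dataclass(frozen=True)
class HospitalProfile:
    classes: tuple  # PatientClassConfig, ...
    exams: tuple  # ExamType, ...
    rooms: tuple  # RoomConfig, ...
    setup_spec: DistributionSpec = triangular(1.0, 5.0, 9.0)

    def exam(self, name: str) -> ExamType:
        for e in self.exams:
            if e.name == name:
                return e
        raise KeyError(name)

    def patient_class(self, name: str) -> PatientClassConfig:
        for c in self.classes:
            if c.name == name:
                return c
        raise KeyError(name)

    def with_outpatient_schedule(self, interval: float, batch: int) -> "HospitalProfile":
        """Return a copy whose outpatients arrive on a fixed appointment grid."""
        new_classes = tuple(
            replace(
                c,
                arrival_model="scheduled_interval",
                interval_minutes=float(interval),
                batch_size=int(batch),
                interarrival_spec=None,
            )
            if c.name == "outpatient"
            else c
            for c in self.classes
        )
        return replace(self, classes=new_classes)


def _default_exam_catalogue() -> tuple:
    # Stand-in triangular laws for the unpublished per-body-part scanning
    # times; the prostate mixture is the published one.  Single-slot means
    # sit at 15-16.35 min and the double-slot (liver) mean at 30 min.
    tri15 = triangular(7.0, 15.0, 23.0)
    return (
        ExamType("liver", "fixed40", triangular(22.0, 30.0, 38.0)),
        ExamType(
            "dvt",
            "dvt_split",
            mixture([(0.7, triangular(8.0, 15.0, 22.0)), (0.3, triangular(22.0, 30.0, 38.0))]),
            sex_constraint="same_sex_tech",
        ),
        ExamType("prostate", "fixed20", PROSTATE_MIXTURE, sex_constraint="male_tech_only"),
        ExamType("scrotum", "fixed20", tri15, sex_constraint="male_tech_only"),
        ExamType("abdomen", "fixed20", tri15),
        ExamType("shoulder", "fixed20", triangular(8.35, 16.35, 24.35)),
        ExamType("other", "fixed20", triangular(7.0, 15.0, 23.0)),
    )


#: Outpatient body-part mix (stand-in; abdomen dominates as in the case
#: department, where abdomen alone was ~135 of 355 weekly outpatients).
_OUTPATIENT_EXAM_MIX = (
    ("abdomen", 0.38),
    ("liver", 0.12),
    ("dvt", 0.08),
    ("prostate", 0.03),
    ("scrotum", 0.02),
    ("shoulder", 0.07),
    ("other", 0.30),
)


def default_profile() -> HospitalProfile:
    """Build the synthetic case-hospital profile.

    Unscheduled arrivals use exponential inter-arrival stand-ins calibrated
    so the expected count per 5-day measured week equals the weekly targets
    (355.3 / 93.0 / 37.9); inpatient and emergency exam mixes reuse the
    outpatient mix.
    """
    classes = []
    for name in ("outpatient", "inpatient", "emergency"):
        mean_gap = MEASURED_WEEK_MINUTES / WEEKLY_TARGETS[name]
        classes.append(
            PatientClassConfig(
                name=name,
                share=CLASS_SHARES[name],
                arrival_model="renewal_process",
                exam_mix=_OUTPATIENT_EXAM_MIX,
                interarrival_spec=exponential(mean_gap),
            )
        )
    rooms = tuple(
        RoomConfig(i, "female" if i % 2 == 1 else "male") for i in range(5, 11)
    )
    return HospitalProfile(
        classes=tuple(classes),
        exams=_default_exam_catalogue(),
        rooms=rooms,
        setup_spec=triangular(1.0, 5.0, 9.0),
    )


# -- arrival generation ----------------------------------------------------


def gen_scheduled_arrivals(interval: float, batch: int, horizon: float) -> np.ndarray:
    """Appointment-grid arrivals: ``batch`` patients at 0, interval, 2*interval,
    ... strictly below ``horizon``.  Deterministic."""
    if interval <= 0:
        raise ValueError("interval: must be positive")
    if batch < 1:
        raise ValueError("batch: must be >= 1")
    if horizon <= 0:
        return np.empty(0)
    epochs = np.arange(0.0, horizon, float(interval))
    return np.repeat(epochs, int(batch))


def gen_renewal_arrivals(
    spec: DistributionSpec, horizon: float, stream: RandomStream
) -> np.ndarray:
    """Renewal-process arrivals: cumulative sums of inter-arrival draws from
    ``spec``, truncated at ``horizon``; reproducible per stream."""
    if lower_bound(spec) < 0 or mean_of(spec) <= 0:
        raise ValueError("spec: inter-arrival law must have positive support and mean")
    if horizon <= 0:
        return np.empty(0)
    mean_gap = mean_of(spec)
    times = []
    t = 0.0
    # draw in blocks sized from the expected count to limit Python looping
    block = max(16, int(horizon / mean_gap * 1.25) + 8)
    while t < horizon:
        draws = _draw_block(spec, stream, block)
        cum = t + np.cumsum(draws)
        keep = cum[cum < horizon]
        times.extend(keep.tolist())
        if cum.size and cum[-1] >= horizon:
            break
        t = cum[-1] if cum.size else horizon
    return np.asarray(times)


def _draw_block(spec: DistributionSpec, stream: RandomStream, n: int) -> np.ndarray:
    from .distributions import sample_many

    return sample_many(spec, stream, n)


def allocate_slots(exam: ExamType, stream: RandomStream) -> tuple[int, int]:
    """Appointment slot minutes and base examination points for one patient.

    Liver exams book two consecutive 20-min slots (40 min, 2 points); DVT
    exams book one slot with probability 0.7, two with 0.3; every other exam
    books a single 20-min slot (1 point).
    """
    if exam.slot_rule == "fixed40":
        return 40, 2
    if exam.slot_rule == "fixed20":
        return 20, 1
    if exam.slot_rule == "dvt_split":
        if stream.rng.uniform() < 0.7:
            return 20, 1
        return 40, 2
    raise ValueError(f"slot_rule: unknown rule {exam.slot_rule!r}")


# -- serialization ---------------------------------------------------------


def profile_to_dict(profile: HospitalProfile) -> dict[str, Any]:
    return {
        "setup_spec": spec_to_dict(profile.setup_spec),
        "rooms": [
            {"room_id": r.room_id, "tech_sex": r.tech_sex} for r in profile.rooms
        ],
        "exams": [
            {
                "name": e.name,
                "slot_rule": e.slot_rule,
                "sex_constraint": e.sex_constraint,
                "service_spec": spec_to_dict(e.service_spec),
            }
            for e in profile.exams
        ],
        "classes": [
            {
                "name": c.name,
                "share": c.share,
                "arrival_model": c.arrival_model,
                "interval_minutes": c.interval_minutes,
                "batch_size": c.batch_size,
                "interarrival_spec": (
                    spec_to_dict(c.interarrival_spec) if c.interarrival_spec else None
                ),
                "male_probability": c.male_probability,
                "dvt_male_probability": c.dvt_male_probability,
                "exam_mix": [[n, p] for n, p in c.exam_mix],
            }
            for c in profile.classes
        ],
    }


def profile_from_dict(d: dict[str, Any]) -> HospitalProfile:
    return HospitalProfile(
        classes=tuple(
            PatientClassConfig(
                name=c["name"],
                share=float(c["share"]),
                arrival_model=c["arrival_model"],
                exam_mix=tuple((n, float(p)) for n, p in c["exam_mix"]),
                interval_minutes=(
                    float(c["interval_minutes"]) if c["interval_minutes"] is not None else None
                ),
                batch_size=int(c["batch_size"]),
                interarrival_spec=(
                    spec_from_dict(c["interarrival_spec"])
                    if c["interarrival_spec"]
                    else None
                ),
                male_probability=float(c["male_probability"]),
                dvt_male_probability=float(c["dvt_male_probability"]),
            )
            for c in d["classes"]
        ),
        exams=tuple(
            ExamType(
                name=e["name"],
                slot_rule=e["slot_rule"],
                service_spec=spec_from_dict(e["service_spec"]),
                sex_constraint=e["sex_constraint"],
            )
            for e in d["exams"]
        ),
        rooms=tuple(RoomConfig(int(r["room_id"]), r["tech_sex"]) for r in d["rooms"]),
        setup_spec=spec_from_dict(d["setup_spec"]),
    )


def save_profile(profile: HospitalProfile, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(profile_to_dict(profile), fh, sort_keys=False)


def load_profile(path) -> HospitalProfile:
    with open(path) as fh:
        return profile_from_dict(yaml.safe_load(fh))


def case_hospital_profile() -> HospitalProfile:
    """The reference profile shipped with the package (YAML copy of
    :func:`default_profile`)."""
    from importlib.resources import files

    text = files("sonoflow.data").joinpath("case_hospital.yaml").read_text()
    return profile_from_dict(yaml.safe_load(text))
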