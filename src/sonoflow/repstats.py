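"""Replication-sizing and summary statistics.

Across-replication measures are summarised by their mean, sample SD and the
95% Student-t half-width ``h = t_{n-1,1-a/2} * s / sqrt(n)``.  The number of
replications needed to shrink an initial half-width ``h0`` (observed over
``n0`` pilot replications) down to a target ``h`` follows the standard
sequential-sizing approximation ``n ~ n0 * h0^2 / h^2``.  The precision
criterion used throughout is the coefficient of variation ``cv = h / mean``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ReplicationStats",
    "summarize",
    "confidence_interval",
    "half_width",
    "required_replications",
    "cv",
    "workload_sd",
    "validate_against_reference",
]


@dataclass(frozen=True)
class ReplicationStats:
    """Mean, spread and 95%-CI geometry of one measure across replications."""

    mean: float
    sd: float
    n: int
    alpha: float = 0.05

    @property
    def t_quantile(self) -> float:
        return float(stats.t.ppf(1.0 - self.alpha / 2.0, self.n - 1))

    @property
    def half_width(self) -> float:
        return half_width(self.sd, self.n, self.alpha)

    @property
    def ci(self) -> tuple[float, float]:
        h = self.half_width
        return (self.mean - h, self.mean + h)

    @property
    def cv(self) -> float:
        return cv(self.half_width, self.mean)

    def contains(self, reference: float) -> bool:
        lo, hi = self.ci
        return lo <= reference <= hi


def summarize(values: Sequence[float], alpha: float = 0.05) -> ReplicationStats:
    """Across-replication summary of one performance measure."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("values: need at least two replications (SD undefined)")
    return ReplicationStats(float(arr.mean()), float(arr.std(ddof=1)), int(arr.size), alpha)


def confidence_interval(
    mean: float, sd: float, n: int, alpha: float = 0.05
) -> tuple[float, float]:
    """Student-t confidence interval ``mean -/+ t_{n-1,1-a/2} * sd / sqrt(n)``."""
    h = half_width(sd, n, alpha)
    return (mean - h, mean + h)


def half_width(sd: float, n: int, alpha: float = 0.05) -> float:
    if n < 2:
        raise ValueError("n: need at least two replications")
    if sd < 0:
        raise ValueError("sd: must be non-negative")
    t = float(stats.t.ppf(1.0 - alpha / 2.0, n - 1))
    return t * sd / math.sqrt(n)


def required_replications(n0: int, h0: float, h_target: float) -> int:
    """Replications needed to shrink half-width ``h0`` to ``h_target``:
    ``ceil(n0 * h0^2 / h_target^2)``."""
    if n0 <= 0 or h0 <= 0:
        raise ValueError("n0 and h0 must be positive")
    if h_target <= 0:
        raise ValueError("h_target: must be positive")
    return math.ceil(n0 * (h0 / h_target) ** 2)


def cv(half_width_value: float, mean: float) -> float:
    """Coefficient of variation of a CI: half-width over mean."""
    if mean <= 0:
        raise ValueError("mean: must be positive")
    if half_width_value < 0:
        raise ValueError("half_width: must be non-negative")
    return half_width_value / mean


def workload_sd(utilizations: Sequence[float]) -> tuple[float, float]:
    """Mean and sample SD (n-1) of the six per-room workloads, on the
    percentage scale, rounded to 2 decimals."""
    arr = np.asarray(utilizations, dtype=float)
    if arr.size != 6:
        raise ValueError(f"utilizations: expected six rooms, got {arr.size}")
    return (round(float(arr.mean()), 2), round(float(arr.std(ddof=1)), 2))


def validate_against_reference(
    summary_stats: dict[str, ReplicationStats], reference: dict[str, float]
) -> dict[str, bool | None]:
    """Check each reference value against the simulated 95% CI.

    Returns per-measure True/False; a reference measure absent from the
    summary is reported as ``None`` (not evaluated), never a silent pass.
    """
    out: dict[str, bool | None] = {}
    for name, ref in reference.items():
        st = summary_stats.get(name)
        out[name] = None if st is None else bool(st.contains(ref))
    return out
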