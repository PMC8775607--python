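"""Declarative random-variate specifications and seeded sampling.

Service times, setup phases and inter-arrival gaps in the simulator are all
described by :class:`DistributionSpec` objects -- small declarative records
that can be validated, serialized into the run configuration, sampled from a
reproducible stream, and queried for their analytic mean and CDF.

Supported laws (parameter conventions follow the common simulation-software
usage):

``triangular``
    ``(minimum, mode, maximum)`` minutes.
``beta_scaled``
    ``offset + scale * Beta(shape1, shape2)`` -- a Beta variate on [0, 1]
    shifted and stretched onto ``[offset, offset + scale]``.
``weibull_scaled``
    ``offset + Weibull(scale, shape)`` with mean
    ``offset + scale * Gamma(1 + 1/shape)``.
``exponential``
    parameterized by its mean.
``deterministic``
    a constant.
``empirical``
    a continuous piecewise-linear CDF given as ``(value, cum_prob)``
    breakpoints (the way continuous empirical distributions are specified in
    simulation packages); a jump in cumulative probability at a single value
    is an atom.
``mixture``
    a finite mixture of component specs with positive weights summing to 1.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "DistributionSpec",
    "RandomStream",
    "SpecValidationError",
    "triangular",
    "beta_scaled",
    "weibull_scaled",
    "exponential",
    "deterministic",
    "empirical",
    "mixture",
    "sample",
    "sample_many",
    "mean_of",
    "cdf",
    "lower_bound",
    "upper_bound",
    "ks_check",
    "spec_to_dict",
    "spec_from_dict",
]

_KINDS = {
    "triangular",
    "beta_scaled",
    "weibull_scaled",
    "exponential",
    "deterministic",
    "empirical",
    "mixture",
}


class SpecValidationError(ValueError):
    """A distribution spec violates its invariants; the message names the field."""


@dataclass(frozen=True)
class DistributionSpec:
    kind: str
    params: tuple = ()
    components: tuple = ()  # mixture only: ((weight, DistributionSpec), ...)
    breakpoints: tuple = ()  # empirical only: ((value, cum_prob), ...)

    def __post_init__(self) -> None:
        _validate(self)


def _validate(spec: DistributionSpec) -> None:
    if spec.kind not in _KINDS:
        raise SpecValidationError(f"kind: unknown distribution kind {spec.kind!r}")
    p = spec.params
    if spec.kind == "triangular":
        if len(p) != 3:
            raise SpecValidationError("params: triangular needs (min, mode, max)")
        a, m, b = p
        if not (a <= m <= b):
            raise SpecValidationError(
                f"params: triangular requires min <= mode <= max, got {p}"
            )
    elif spec.kind == "beta_scaled":
        if len(p) != 4:
            raise SpecValidationError(
                "params: beta_scaled needs (offset, scale, shape1, shape2)"
            )
        if p[1] <= 0 or p[2] <= 0 or p[3] <= 0:
            raise SpecValidationError(
                "params: beta_scaled scale and shapes must be positive"
            )
    elif spec.kind == "weibull_scaled":
        if len(p) != 3:
            raise SpecValidationError(
                "params: weibull_scaled needs (offset, scale, shape)"
            )
        if p[1] <= 0 or p[2] <= 0:
            raise SpecValidationError(
                "params: weibull_scaled scale and shape must be positive"
            )
    elif spec.kind == "exponential":
        if len(p) != 1 or p[0] <= 0:
            raise SpecValidationError("params: exponential needs a positive mean")
    elif spec.kind == "deterministic":
        if len(p) != 1:
            raise SpecValidationError("params: deterministic needs (value,)")
    elif spec.kind == "empirical":
        bp = spec.breakpoints
        if len(bp) < 2:
            raise SpecValidationError("breakpoints: need at least two (value, cdf) pairs")
        vals = [v for v, _ in bp]
        cps = [c for _, c in bp]
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise SpecValidationError("breakpoints: values must be strictly increasing")
        if any(b <= a for a, b in zip(cps, cps[1:])):
            raise SpecValidationError(
                "breakpoints: cumulative probabilities must be strictly increasing"
            )
        if cps[0] < 0 or abs(cps[-1] - 1.0) > 1e-9:
            raise SpecValidationError("breakpoints: cumulative probability must end at 1")
    elif spec.kind == "mixture":
        comps = spec.components
        if not comps:
            raise SpecValidationError("components: mixture needs at least one component")
        wsum = 0.0
        for w, c in comps:
            if w <= 0:
                raise SpecValidationError("components: mixture weights must be positive")
            if not isinstance(c, DistributionSpec):
                raise SpecValidationError("components: entries must be (weight, spec)")
            wsum += w
        if abs(wsum - 1.0) > 1e-9:
            raise SpecValidationError(
                f"components: mixture weights must sum to 1, got {wsum}"
            )


# -- constructors ----------------------------------------------------------


def triangular(minimum: float, mode: float, maximum: float) -> DistributionSpec:
    return DistributionSpec("triangular", (minimum, mode, maximum))


def beta_scaled(offset: float, scale: float, shape1: float, shape2: float) -> DistributionSpec:
    return DistributionSpec("beta_scaled", (offset, scale, shape1, shape2))


def weibull_scaled(offset: float, scale: float, shape: float) -> DistributionSpec:
    return DistributionSpec("weibull_scaled", (offset, scale, shape))


def exponential(mean: float) -> DistributionSpec:
    return DistributionSpec("exponential", (mean,))


def deterministic(value: float) -> DistributionSpec:
    return DistributionSpec("deterministic", (value,))


def empirical(breakpoints: Sequence[tuple[float, float]]) -> DistributionSpec:
    return DistributionSpec("empirical", breakpoints=tuple(tuple(b) for b in breakpoints))


def mixture(components: Sequence[tuple[float, DistributionSpec]]) -> DistributionSpec:
    return DistributionSpec("mixture", components=tuple((w, c) for w, c in components))


# -- random streams --------------------------------------------------------


@dataclass
class RandomStream:
    """One independent, reproducible substream of pseudo-random numbers.

    A stream is identified by a ``(seed, stream_id)`` pair; the same pair
    always reproduces the same draw sequence, and distinct ``stream_id``
    labels give statistically independent streams (one per stochastic
    process: arrivals per patient class, exam-type draw, service times,
    setup, slot draws, the random policy).  Independent substreams let
    policy comparisons share common random numbers.
    """

    seed: int
    stream_id: str
    _rng: np.random.Generator = field(init=False, repr=False)

    def __post_init__(self) -> None:
        label = zlib.crc32(self.stream_id.encode("utf-8"))
        self._rng = np.random.default_rng(np.random.SeedSequence([int(self.seed), label]))

    @property
    def rng(self) -> np.random.Generator:
        return self._rng


# -- sampling --------------------------------------------------------------


def sample(spec: DistributionSpec, stream: RandomStream) -> float:
    """Draw one variate from ``spec`` using ``stream``."""
    return float(_sample_n(spec, stream.rng, 1)[0])


def sample_many(spec: DistributionSpec, stream: RandomStream, n: int) -> np.ndarray:
    """Draw ``n`` variates (vectorized where the law permits)."""
    return _sample_n(spec, stream.rng, int(n))


def _sample_n(spec: DistributionSpec, rng: np.random.Generator, n: int) -> np.ndarray:
    p = spec.params
    if spec.kind == "deterministic":
        return np.full(n, float(p[0]))
    if spec.kind == "triangular":
        a, m, b = p
        if a == b:  # degenerate
            return np.full(n, float(a))
        return rng.triangular(a, m, b, size=n)
    if spec.kind == "exponential":
        return rng.exponential(p[0], size=n)
    if spec.kind == "beta_scaled":
        off, sc, a1, a2 = p
        return off + sc * rng.beta(a1, a2, size=n)
    if spec.kind == "weibull_scaled":
        off, sc, sh = p
        return off + sc * rng.weibull(sh, size=n)
    if spec.kind == "empirical":
        return _empirical_ppf(spec.breakpoints, rng.uniform(size=n))
    if spec.kind == "mixture":
        ws = np.array([w for w, _ in spec.components])
        idx = rng.choice(len(ws), size=n, p=ws)
        out = np.empty(n)
        for i, (_, comp) in enumerate(spec.components):
            mask = idx == i
            k = int(mask.sum())
            if k:
                out[mask] = _sample_n(comp, rng, k)
        return out
    raise AssertionError(spec.kind)


def _empirical_ppf(bp: tuple, u: np.ndarray) -> np.ndarray:
    vals = np.array([v for v, _ in bp])
    cps = np.array([c for _, c in bp])
    # inverse of the piecewise-linear CDF; u below the first breakpoint's
    # cumulative probability maps to the first value (an atom there)
    return np.interp(u, cps, vals)


# -- analytic mean / CDF / support -----------------------------------------


def mean_of(spec: DistributionSpec) -> float:
    """Closed-form mean of a spec (mixtures by weight-sum, empirical by
    the trapezoid mean of its piecewise-linear CDF)."""
    p = spec.params
    if spec.kind == "deterministic":
        return float(p[0])
    if spec.kind == "triangular":
        return (p[0] + p[1] + p[2]) / 3.0
    if spec.kind == "exponential":
        return float(p[0])
    if spec.kind == "beta_scaled":
        off, sc, a1, a2 = p
        return off + sc * a1 / (a1 + a2)
    if spec.kind == "weibull_scaled":
        off, sc, sh = p
        return off + sc * math.gamma(1.0 + 1.0 / sh)
    if spec.kind == "empirical":
        bp = spec.breakpoints
        m = bp[0][0] * bp[0][1]  # possible atom at the first value
        for (v0, c0), (v1, c1) in zip(bp, bp[1:]):
            m += (c1 - c0) * 0.5 * (v0 + v1)
        return m
    if spec.kind == "mixture":
        return sum(w * mean_of(c) for w, c in spec.components)
    raise AssertionError(spec.kind)


def cdf(spec: DistributionSpec, x) -> np.ndarray:
    """Exact CDF of a spec evaluated at ``x`` (scalar or array)."""
    x = np.asarray(x, dtype=float)
    p = spec.params
    if spec.kind == "deterministic":
        return (x >= p[0]).astype(float)
    if spec.kind == "triangular":
        a, m, b = p
        if a == b:
            return (x >= a).astype(float)
        return stats.triang.cdf(x, c=(m - a) / (b - a), loc=a, scale=b - a)
    if spec.kind == "exponential":
        return stats.expon.cdf(x, scale=p[0])
    if spec.kind == "beta_scaled":
        off, sc, a1, a2 = p
        return stats.beta.cdf(x, a1, a2, loc=off, scale=sc)
    if spec.kind == "weibull_scaled":
        off, sc, sh = p
        return stats.weibull_min.cdf(x, sh, loc=off, scale=sc)
    if spec.kind == "empirical":
        vals = np.array([v for v, _ in spec.breakpoints])
        cps = np.array([c for _, c in spec.breakpoints])
        out = np.interp(x, vals, cps, left=0.0, right=1.0)
        out = np.where(x < vals[0], 0.0, out)
        return out
    if spec.kind == "mixture":
        out = np.zeros_like(x, dtype=float)
        for w, c in spec.components:
            out = out + w * cdf(c, x)
        return out
    raise AssertionError(spec.kind)


def lower_bound(spec: DistributionSpec) -> float:
    """Analytic lower support bound (offsets respected)."""
    p = spec.params
    if spec.kind == "deterministic":
        return float(p[0])
    if spec.kind == "triangular":
        return float(p[0])
    if spec.kind == "exponential":
        return 0.0
    if spec.kind in ("beta_scaled", "weibull_scaled"):
        return float(p[0])
    if spec.kind == "empirical":
        return float(spec.breakpoints[0][0])
    if spec.kind == "mixture":
        return min(lower_bound(c) for _, c in spec.components)
    raise AssertionError(spec.kind)


def upper_bound(spec: DistributionSpec) -> float:
    """Analytic upper support bound; ``inf`` for unbounded laws."""
    p = spec.params
    if spec.kind == "deterministic":
        return float(p[0])
    if spec.kind == "triangular":
        return float(p[2])
    if spec.kind == "exponential":
        return math.inf
    if spec.kind == "beta_scaled":
        return float(p[0] + p[1])
    if spec.kind == "weibull_scaled":
        return math.inf
    if spec.kind == "empirical":
        return float(spec.breakpoints[-1][0])
    if spec.kind == "mixture":
        return max(upper_bound(c) for _, c in spec.components)
    raise AssertionError(spec.kind)


# -- goodness of fit -------------------------------------------------------


def ks_check(samples: Sequence[float], spec: DistributionSpec, alpha: float = 0.05):
    """One-sample Kolmogorov-Smirnov check of ``samples`` against ``spec``.

    Returns ``(statistic, passed)`` where ``passed`` is True when the
    statistic falls below the two-sided critical value at level ``alpha``.
    Mixture and empirical CDFs are evaluated exactly.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("samples: need at least one observation")
    if samples.size < 20:
        raise ValueError("samples: need at least 20 observations for the K-S check")
    stat = float(stats.kstest(samples, lambda x: cdf(spec, x)).statistic)
    crit = float(stats.kstwo.ppf(1.0 - alpha, samples.size))
    return stat, stat < crit


# -- serialization ---------------------------------------------------------


def spec_to_dict(spec: DistributionSpec) -> dict[str, Any]:
    d: dict[str, Any] = {"kind": spec.kind}
    if spec.kind == "mixture":
        d["components"] = [
            {"weight": float(w), **spec_to_dict(c)} for w, c in spec.components
        ]
    elif spec.kind == "empirical":
        d["breakpoints"] = [[float(v), float(c)] for v, c in spec.breakpoints]
    else:
        d["params"] = [float(v) for v in spec.params]
    return d


def spec_from_dict(d: dict[str, Any]) -> DistributionSpec:
    kind = d["kind"]
    if kind == "mixture":
        comps = [
            (float(c["weight"]), spec_from_dict({k: v for k, v in c.items() if k != "weight"}))
            for c in d["components"]
        ]
        return mixture(comps)
    if kind == "empirical":
        return empirical([(float(v), float(c)) for v, c in d["breakpoints"]])
    return DistributionSpec(kind, tuple(float(v) for v in d.get("params", ())))
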