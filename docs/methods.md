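# Methods

## Model and assumptions

sonoflow models an ultrasound department as a network of six single-server
FIFO queues fed by one shared registration counter. Simulation time is a
continuous, compressed clock: each working day contributes 447.36 effective
minutes (8 scheduled hours × 93.2%, the fraction of the day actually spent
on the modelled exam mix), and days are concatenated with no overnight or
lunch boundary — day boundaries exist only for reporting. A replication
spans a 5600-minute warm-up followed by a 5-day measured week
(5 × 447.36 = 2236.8 min), 7836.8 min in total.

Assumptions baked into the engine:

* Rooms and machines are identical; the same scanning-time law applies to a
  body part in every room.
* A patient is assigned to exactly one room at registration and never
  jockeys between queues afterwards.
* Registration time equals arrival time (no front-desk delay); waiting time
  is the span from registration to room entry.
* Service is a setup phase (TRIA(1, 5, 9) minutes: positioning through
  first image) followed by the scanning phase; both are drawn at assignment
  and committed, so the dispatcher always sees the load it has placed.
* Exams in progress when the horizon ends run to completion and are
  counted, but busy time is credited only up to the horizon.
* No no-shows, no unpunctuality, no technologist-proficiency differences,
  no heterogeneous equipment.

## Dispatch policies

The registration counter walks a fixed decision tree: sex-constrained exams
first (male prostate/scrotum/DVT → rooms 6/8/10; female DVT → 5/7/9), then
the inpatient branch (room 5 if its queue is empty, i.e. nobody *waiting*,
even if the room is busy), then the emergency branch (room 6 likewise),
then the general branch. Whenever a branch says "least-loaded room", the
active policy supplies the measure:

| policy | balance counter |
| --- | --- |
| `points` | base examination points: 1 per 20-min slot, 2 per 40-min slot |
| `minutes` | committed examination minutes (setup + scanning of every patient already assigned) |
| `weighted_points` | per-exam weighted points: round-half-up(mean scan / 20, 1 dp) + round-half-up(setup mean / 20, 1 dp) |
| `random` | uniform draw over the eligible set (branch structure preserved) |

Ties break to the lowest room id — deterministic and testable. The
`minutes` counter deliberately uses the patient's actual committed
examination duration rather than the booked slot length: slot minutes are
identically 20 × base points, so a slot-minute counter would reproduce the
`points` policy exactly and the two could never be distinguished; a
cumulative-examination-time criterion is only meaningful on real durations.
All three counters are maintained on every run, whatever the active policy,
so reports can show them side by side. Counters, like all statistics, are
cleared at the warm-up point; after that they accumulate continuously
across the measured week (no daily reset).

## Synthetic hospital profile

The default profile is a stand-in for a real department whose raw data are
not public. What is fixed by published figures:

* class shares 72.46 / 19.98 / 7.57% (stored normalized — the printed
  percentages sum to 100.01%);
* weekly volumes 355.3 outpatients, 93.0 inpatients, 37.9 emergency
  patients per 5 measured days;
* the DVT 70/30 one-slot/two-slot split, the liver double slot, the
  3:4 male:female ratio among DVT outpatients;
* the prostate scanning-time mixture
  0.485·(3 + 7·Beta(1.9, 1.16)) + 0.424·(10 + Weibull(3.46, 1.23)) +
  0.091·(20 + Weibull(6.99, 1.29)) (offset-Beta/Weibull convention:
  Beta on [0, 1] scaled as offset + scale·X; Weibull read as (scale,
  shape) with mean scale·Γ(1 + 1/shape));
* the TRIA(1, 5, 9) setup phase.

Everything else is a documented choice, made once:

* **Arrival processes.** All three classes default to exponential
  inter-arrival stand-ins with means 2236.8/355.3 = 6.30, 24.05 and
  59.02 min, so the expected count per measured week equals each target
  exactly. Scenario runs switch outpatients to a deterministic appointment
  grid (`batch` patients every `interval` minutes, simultaneous timestamps,
  registered in generation order). Empirical piecewise-linear CDFs are
  supported for users with their own inter-arrival data.
* **Exam catalogue and mix.** abdomen 38%, other 30%, liver 12%, DVT 8%,
  shoulder 7%, prostate 3%, scrotum 2%; the inpatient and emergency mixes
  reuse the outpatient mix (their true mixes are unpublished but
  configurable). Stand-in scanning laws are triangular with means 15 min
  for generic single-slot exams, 16.35 for shoulder (a published mean),
  30 for liver, and a 0.7/0.3 triangular mixture (means 15/30) for DVT.
  Single-slot means are constrained to [15, 25] min and double-slot means
  to [30, 45].
* **Resulting operating point.** With those bands the six rooms run at
  ≈ 79% mean utilization. A department at ≈ 69% would need generic scan
  means near 14 min, below the single-slot band floor, so the profile sits
  at the loaded end; all policy comparisons and the interval search are
  qualitative at this operating point.

What passing tests on this profile do **not** show: agreement with any real
department's absolute waiting times, utilizations or workload SDs. They
show the calibrated volumes, the analytic distribution properties, the
queueing dynamics (validated against M/M/1), and the *orderings* between
policies, which are driven by counter granularity rather than by the
specific stand-in laws.

## Replication statistics

Across-replication measures use Student-t half-widths
`h = t_{n−1,1−α/2}·s/√n` (α = 0.05 throughout) and the precision criterion
`cv = h/x̄`. The sequential-sizing rule `n ≈ n₀·h₀²/h²` is rounded up
(`ceil`); with a 30-replication pilot at half-width 6.1 around mean 351.7
and a 1%-CV target it yields 91. The across-room workload SD uses the
sample (n−1) denominator — pinned by exact reproduction of the reference
columns (69.21/1.40 and 0.06) — and is reported on the percentage scale to
two decimals.

## Randomness and common random numbers

Every stochastic process draws from its own substream, keyed by
`(seed, stream_id)` through `numpy` `SeedSequence` (the label is hashed
with CRC-32): per-class arrivals, the exam-type draw, the sex draw, the DVT
slot draw, setup, per-exam scanning, and the random policy. A replication
is therefore a pure function of (profile, policy, calendar, seed), and two
policies or two interval candidates run with the same base seed see
identical arrival and service realizations — paired comparisons isolate the
policy effect. Replication `r` of an experiment uses seed
`(base·100003 + r) mod (2³¹ − 1)`.

## Constrained interval search

Scenario searches enumerate an integer grid (intervals 1–30 min; batch
sizes where applicable) rather than using a metaheuristic: the decision
space is tiny and exhaustive evaluation is reproducible. Feasibility
requires every room's mean utilization ≥ 70% (an optional 75% cap is
available but off by default, since the binding constraint is stated as a
floor) and mean patients examined above a volume threshold of 485 per
measured week, scaled linearly when a shorter horizon is simulated so
reduced-scale runs remain meaningful. An empty feasible set is a reported
outcome, not an error.

## Numerical choices and edge cases

* Warm-up clearing excludes patients in flight at the reset from waiting
  statistics, but their residual service still counts toward busy time.
* At equal event times, completions fire before arrivals so a freed room is
  visible to a simultaneously registering patient; simultaneous batch
  arrivals register in generation order.
* Weighted points use decimal round-half-up at one decimal (0.25 → 0.3),
  which is how a 5-min setup scores 0.3 rather than 0.2.
* The one-sample K-S self-check compares against the exact CDF (mixtures
  and empirical CDFs evaluated in closed form) and the two-sided
  finite-sample critical value.
* Degenerate inputs: zero-length horizons yield empty arrival lists;
  `sd = 0` gives a degenerate CI; a profile in which some patient has no
  eligible room raises an error naming the patient's sex and exam.

## Problem sizes used by the shipped checks

The test suite and the acceptance script run the full replication design
(110 replications of 7836.8 min; 200 replications for the M/M/1
comparison); unit and property tests use a reduced calendar (one measured
day, 400-min warm-up) where only mechanics, not steady-state magnitudes,
are under test.

## Known limitations

* The stand-in scanning laws make absolute performance figures synthetic;
  only calibrated volumes and qualitative comparisons transfer.
* No no-show/unpunctuality modelling, no Saturday policies, no breast
  ultrasound, no technologist rostering beyond the fixed 1:1 sex-to-room
  mapping, no heterogeneous equipment.
* The warm-up diagnostic is a Welch-style running-mean scan; it supports,
  but does not automatically select, the warm-up length.
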