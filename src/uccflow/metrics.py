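"""Outcome measures per replication and their cross-replication summaries.

Four measures per staffed role: time-averaged queue length (patients),
utilization (busy server-time over staffed server-time), idle time
(unoccupied server-minutes), and — for the triage stage — the patient
waiting time, defined as the interval from arrival (readiness for
triage) to the start of the triage consultation. Crowding is the
fraction of the window with more than a threshold number of patients
(default 5) waiting for triage.

Across replications, measures are summarised as the mean with a normal
95% CI, except utilization which is reported as median and IQR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .engine import ROLES, ResourceTrace, RunResult

__all__ = [
    "RunMetrics",
    "AggregateEntry",
    "AggregateMetrics",
    "triage_waits",
    "time_average_queue",
    "busy_fraction",
    "idle_time",
    "crowding_fraction",
    "time_average_virtual_wait",
    "event_record_queue_mean",
    "queue_at_arrivals",
    "aggregate",
    "aggregate_runs",
    "compute_run_metrics",
    "percent_reduction",
    "CROWDING_THRESHOLD",
]

#: Crowding definition: strictly more than this many patients waiting.
CROWDING_THRESHOLD = 5


def triage_waits(run: RunResult, *, censor: str = "completed") -> list[float]:
    """Per-patient triage waiting times, minutes.

    The wait is the interval from arrival (readiness for triage) to the
    start of the triage consultation, i.e. the consultation itself is
    excluded. ``censor`` picks which patients contribute:

    - ``"completed"`` (default): patients whose triage consultation
      ended within the window — the population a per-resource activity
      monitor reports, and the one results tables summarise;
    - ``"started"``: patients whose triage started within the window;
    - ``"include"``: as ``"started"``, plus patients still waiting at
      close contributing their censored wait ``horizon - arrival_time``
      (sensitivity alternative).
    """
    if censor not in ("completed", "started", "include"):
        raise ValueError(f"unknown censoring mode: {censor}")
    if censor == "completed":
        return [
            r.triage_start - r.arrival_time
            for r in run.records
            if r.triage_end is not None
        ]
    waits = [
        r.triage_start - r.arrival_time
        for r in run.records
        if r.triage_start is not None
    ]
    if censor == "include":
        horizon = run.config.horizon
        waits += [
            horizon - r.arrival_time
            for r in run.records
            if r.triage_start is None
        ]
    return waits


def time_average_queue(trace: ResourceTrace, horizon: float) -> float:
    """(1/horizon) x integral of the queue-length step function."""
    if not horizon > 0:
        raise ValueError("horizon must be positive")
    return trace.queue_integral() / horizon


def busy_fraction(trace: ResourceTrace, horizon: float) -> float:
    """Utilization: busy server-minutes over capacity x horizon."""
    if not horizon > 0:
        raise ValueError("horizon must be positive")
    return trace.busy_integral() / (trace.capacity * horizon)


def idle_time(trace: ResourceTrace, horizon: float) -> float:
    """Unoccupied server-minutes: capacity x horizon minus busy integral."""
    if not horizon > 0:
        raise ValueError("horizon must be positive")
    return trace.capacity * horizon - trace.busy_integral()


def crowding_fraction(
    trace: ResourceTrace, threshold: float = CROWDING_THRESHOLD, horizon: float | None = None
) -> float:
    """Fraction of the window with strictly more than ``threshold`` waiting."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    h = trace.horizon if horizon is None else horizon
    return trace.time_queue_above(threshold) / h


def time_average_virtual_wait(trace: ResourceTrace, service_mean: float, horizon: float) -> float:
    """Time average of the expected wait a hypothetical arrival would face.

    An arrival finding ``n`` patients at a ``c``-server FIFO stage with
    exponential service of the given mean waits, in expectation,
    ``max(n - c + 1, 0) * mean / c``. Since arrivals are Poisson, the
    time average of this transform equals the arrival-averaged expected
    wait (PASTA), giving a simulation-side quantity with an exact
    analytic counterpart.
    """
    if not horizon > 0:
        raise ValueError("horizon must be positive")
    return trace.virtual_wait_integral(service_mean) / horizon


def event_record_queue_mean(trace: ResourceTrace) -> float:
    """Unweighted mean of the queue column over state-change records.

    The trace holds one record per queue/server state change at the
    role (a seize attempt or a service completion). Averaging the queue
    column without time weights oversamples busy periods relative to
    the time average; it is, however, exactly how a per-event resource
    monitor log summarises to, and is kept as the results-table
    estimator alongside the primary time-averaged measure.
    """
    if len(trace.queue) <= 1:
        return 0.0
    return float(np.mean(trace.queue[1:]))  # row 0 is the initial state


def queue_at_arrivals(run: RunResult, role: str = "triage") -> list[int]:
    """Queue length seen by each arriving patient (sampling alternative).

    Counts, for each arrival, how many earlier patients are waiting at
    that role at the arrival instant, read off the queue step function
    just before the arrival's own queue entry.
    """
    trace = run.traces[role]
    out = []
    for r in run.records:
        # right-open steps: value just before t is at searchsorted(side="left")-1
        i = int(np.searchsorted(trace.times, r.arrival_time, side="left")) - 1
        out.append(int(trace.queue[max(i, 0)]))
    return out


@dataclass
class RunMetrics:
    """Outcome measures of one replication."""

    queue_len: dict[str, float]        # time-averaged number waiting, per role
    queue_sampled: dict[str, float]    # event-record queue mean, per role
    utilization: dict[str, float]      # busy fraction in [0, 1], per role
    idle_minutes: dict[str, float]     # unoccupied server-minutes, per role
    wait_triage: float                 # mean triage wait (NaN if nobody triaged)
    n_waits: int                       # patients contributing to wait_triage
    crowding: float                    # fraction of window with triage queue > threshold
    virtual_wait_triage: float         # time-averaged virtual wait at triage
    n_arrivals: int
    n_discharged: int


def compute_run_metrics(
    run: RunResult,
    *,
    crowding_threshold: float = CROWDING_THRESHOLD,
    wait_censor: str = "completed",
) -> RunMetrics:
    """All outcome measures of a completed replication."""
    h = run.config.horizon
    waits = triage_waits(run, censor=wait_censor)
    return RunMetrics(
        queue_len={r: time_average_queue(run.traces[r], h) for r in ROLES},
        queue_sampled={r: event_record_queue_mean(run.traces[r]) for r in ROLES},
        utilization={r: busy_fraction(run.traces[r], h) for r in ROLES},
        idle_minutes={r: idle_time(run.traces[r], h) for r in ROLES},
        wait_triage=float(np.mean(waits)) if waits else math.nan,
        n_waits=len(waits),
        crowding=crowding_fraction(run.traces["triage"], crowding_threshold, h),
        virtual_wait_triage=time_average_virtual_wait(
            run.traces["triage"], run.config.eff_mean_triage, h
        ),
        n_arrivals=run.n_arrivals,
        n_discharged=run.n_discharged,
    )


@dataclass
class AggregateEntry:
    """One measure summarised across replications."""

    kind: str            # "mean-ci" or "median-iqr"
    point: float         # mean or median
    lo: float            # CI lower or first quartile (NaN if undefined)
    hi: float            # CI upper or third quartile
    n: int
    ci_defined: bool = True

    def astuple(self) -> tuple[float, float, float]:
        return (self.point, self.lo, self.hi)


def aggregate(values, kind: str) -> AggregateEntry:
    """Summarise per-replication values.

    ``kind="mean-ci"``: mean with normal-approximation 95% CI,
    mean +/- 1.96 * sd / sqrt(n); with a single value the CI is flagged
    undefined and set to NaN. ``kind="median-iqr"``: median with 25th
    and 75th percentiles (linear interpolation).
    """
    x = np.asarray([v for v in values if not math.isnan(v)], dtype=float)
    if x.size == 0:
        raise ValueError("cannot aggregate an empty collection")
    n = int(x.size)
    if kind == "mean-ci":
        m = float(np.mean(x))
        if n < 2:
            return AggregateEntry("mean-ci", m, math.nan, math.nan, n, ci_defined=False)
        half = 1.96 * float(np.std(x, ddof=1)) / math.sqrt(n)
        return AggregateEntry("mean-ci", m, m - half, m + half, n)
    if kind == "median-iqr":
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        return AggregateEntry("median-iqr", float(med), float(q1), float(q3), n)
    raise ValueError(f"unknown aggregation kind: {kind}")


@dataclass
class AggregateMetrics:
    """Cross-replication summary of every measure of one scenario."""

    scenario: str
    n_reps: int
    entries: dict[str, AggregateEntry] = field(default_factory=dict)

    def __getitem__(self, key: str) -> AggregateEntry:
        return self.entries[key]


def aggregate_runs(scenario: str, per_rep: list[RunMetrics]) -> AggregateMetrics:
    """Summarise a scenario's replications the way results tables report them:
    mean with 95% CI for queues, idle time and waiting time; median with
    IQR for utilization (reported in percent)."""
    agg = AggregateMetrics(scenario=scenario, n_reps=len(per_rep))
    for role in ROLES:
        agg.entries[f"queue_{role}"] = aggregate(
            [m.queue_len[role] for m in per_rep], "mean-ci"
        )
        agg.entries[f"queue_sampled_{role}"] = aggregate(
            [m.queue_sampled[role] for m in per_rep], "mean-ci"
        )
        agg.entries[f"idle_{role}"] = aggregate(
            [m.idle_minutes[role] for m in per_rep], "mean-ci"
        )
        agg.entries[f"util_{role}"] = aggregate(
            [100.0 * m.utilization[role] for m in per_rep], "median-iqr"
        )
    agg.entries["wait_triage"] = aggregate([m.wait_triage for m in per_rep], "mean-ci")
    agg.entries["crowding_triage"] = aggregate([m.crowding for m in per_rep], "mean-ci")
    agg.entries["vwait_triage"] = aggregate(
        [m.virtual_wait_triage for m in per_rep], "mean-ci"
    )
    return agg


def percent_reduction(baseline_value: float, scenario_value: float) -> float:
    """Reduction of a measure relative to baseline, in percent."""
    if not baseline_value > 0:
        raise ValueError("baseline value must be positive")
    return 100.0 * (baseline_value - scenario_value) / baseline_value
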