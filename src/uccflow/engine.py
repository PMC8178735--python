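"""Event-driven simulation of one urgent-care-center opening period.

The patient trajectory: Poisson arrivals join a FIFO queue for a triage
nurse; after triage they queue for a doctor; after the consultation they
go to the examination/treatment room with probability ``p_exam`` or to
discharge administration otherwise; after examination/treatment they
return to a doctor with probability ``p_return`` or go to discharge.
All service durations are exponential. The clock halts at the horizon:
no new activity starts after it and in-flight services are truncated at
the horizon in all resource traces.

Randomness is split into six named streams per replication (arrivals,
one per service role, routing), each seeded deterministically from
``(base_seed, rep_index, purpose)``. Because triage timestamps consume
only the arrival and triage streams, every triage-stage statistic is
bit-identical under changes to the downstream parameters (doctor/exam/
admin means, consultation saving, routing probabilities) — the property
that makes triage metrics well-defined even though the routing
probabilities of the real center are uncertain.
"""

from __future__ import annotations

import heapq
import itertools
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .config import ScenarioConfig, validate_config

__all__ = [
    "ROLES",
    "STREAM_PURPOSES",
    "PatientRecord",
    "ResourceTrace",
    "RunResult",
    "make_streams",
    "sample_duration",
    "route",
    "simulate_run",
    "event_log_frame",
]

#: Staffed roles, in trajectory order.
ROLES = ("triage", "doctor", "exam", "admin")

#: Independent random-number streams consumed by one replication.
STREAM_PURPOSES = ("arrival", "triage", "doctor", "exam", "admin", "routing")

# event-type priorities at equal clock time: completions before arrivals,
# then insertion order — keeps replay deterministic even on float ties
_PRIO_COMPLETION = 0
_PRIO_ARRIVAL = 1


@dataclass
class PatientRecord:
    """Timestamps and routing outcomes of one simulated visit.

    Times are minutes from opening. A ``None`` end-timestamp means the
    activity was still in progress (or never started) when the center's
    observation window closed. Doctor and exam visits are lists of
    ``[queue_entry, start, end]`` triples since the trajectory can loop.
    """

    patient_id: int
    arrival_time: float
    triage_start: float | None = None
    triage_end: float | None = None
    doctor_visits: list[list[float | None]] = field(default_factory=list)
    exam_visits: list[list[float | None]] = field(default_factory=list)
    discharge_start: float | None = None
    discharge_end: float | None = None
    disposition: str = "in_system_at_close"


@dataclass
class ResourceTrace:
    """Right-open step functions of one role's busy and queue counts.

    ``busy[i]`` and ``queue[i]`` hold on ``[times[i], times[i+1])``; the
    final value holds to the horizon. All breakpoints lie in
    ``[0, horizon]``, so integrals over the window need no clipping.
    """

    role: str
    capacity: int
    times: np.ndarray
    busy: np.ndarray
    queue: np.ndarray
    horizon: float

    def _integral(self, values: np.ndarray) -> float:
        edges = np.append(self.times, self.horizon)
        return float(np.sum(np.diff(edges) * values))

    def busy_integral(self) -> float:
        """Total busy server-minutes over [0, horizon]."""
        return self._integral(self.busy)

    def queue_integral(self) -> float:
        """Patient-minutes spent waiting over [0, horizon]."""
        return self._integral(self.queue)

    def time_queue_above(self, threshold: float) -> float:
        """Minutes with strictly more than ``threshold`` patients waiting."""
        return self._integral((self.queue > threshold).astype(float))

    def head_count_integral(self) -> float:
        """Integral of (busy + queue), i.e. patients at the role."""
        return self._integral(self.busy + self.queue)

    def virtual_wait_integral(self, service_mean: float) -> float:
        """Integral of the expected virtual waiting time transform.

        For a FIFO multi-server stage with exponential service, an
        arrival finding ``n`` patients present waits ``max(n-c+1, 0)``
        service completions, each Exp(mean/c) in expectation.
        """
        n = self.busy + self.queue
        w = np.maximum(n - self.capacity + 1, 0) * (service_mean / self.capacity)
        return self._integral(w)


@dataclass
class RunResult:
    """Everything one replication produced."""

    config: ScenarioConfig
    rep_index: int
    base_seed: int
    records: list[PatientRecord]
    traces: dict[str, ResourceTrace]
    event_log: list[tuple[int, str, float, str]] | None = None

    @property
    def n_arrivals(self) -> int:
        return len(self.records)

    @property
    def n_discharged(self) -> int:
        return sum(1 for r in self.records if r.disposition == "discharged")


def make_streams(base_seed: int, rep_index: int) -> dict[str, np.random.Generator]:
    """Six independent PCG64 generators for one replication.

    Seeded from ``SeedSequence([base_seed, rep_index, purpose_index])``
    so that any purpose's stream is unaffected by how much the others
    consume.
    """
    return {
        purpose: np.random.Generator(
            np.random.PCG64(np.random.SeedSequence([base_seed, rep_index, k]))
        )
        for k, purpose in enumerate(STREAM_PURPOSES)
    }


def sample_duration(mean: float, stream: np.random.Generator) -> float:
    """One exponentially distributed duration with the given mean (minutes)."""
    if not mean > 0:
        raise ValueError(f"service mean must be positive, got {mean}")
    return float(stream.exponential(mean))


def route(u: float, p: float) -> bool:
    """Branch decision: take the branch iff ``u < p``."""
    if not 0.0 <= u < 1.0:
        raise ValueError(f"uniform draw out of [0, 1): {u}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability out of range: {p}")
    return u < p


class _Role:
    """Mutable per-role state during a run: servers, FIFO queue, trace."""

    __slots__ = ("name", "capacity", "mean", "rng", "busy", "fifo",
                 "times", "busys", "queues")

    def __init__(self, name: str, capacity: int, mean: float, rng: np.random.Generator):
        self.name = name
        self.capacity = capacity
        self.mean = mean
        self.rng = rng
        self.busy = 0
        self.fifo: deque[int] = deque()
        self.times = [0.0]
        self.busys = [0]
        self.queues = [0]

    def record(self, t: float) -> None:
        self.times.append(t)
        self.busys.append(self.busy)
        self.queues.append(len(self.fifo))

    def finish(self, horizon: float) -> ResourceTrace:
        return ResourceTrace(
            role=self.name,
            capacity=self.capacity,
            times=np.asarray(self.times),
            busy=np.asarray(self.busys),
            queue=np.asarray(self.queues),
            horizon=horizon,
        )


def simulate_run(
    cfg: ScenarioConfig,
    rep_index: int,
    *,
    base_seed: int | None = None,
    collect_event_log: bool = False,
) -> RunResult:
    """Simulate one opening period of the center.

    Parameters
    ----------
    cfg
        Validated scenario. ``cfg.base_seed`` roots the random streams
        unless ``base_seed`` overrides it.
    rep_index
        Replication number; replications are mutually independent and
        the run is a pure function of ``(base_seed, rep_index)``.
    collect_event_log
        Record a ``(patient_id, event, time, role)`` log for debugging.
    """
    validate_config(cfg)
    seed = cfg.base_seed if base_seed is None else base_seed
    streams = make_streams(seed, rep_index)
    horizon = cfg.horizon

    roles = {
        "triage": _Role("triage", cfg.n_triage, cfg.eff_mean_triage, streams["triage"]),
        "doctor": _Role("doctor", cfg.n_doctor, cfg.eff_mean_doctor, streams["doctor"]),
        "exam": _Role("exam", cfg.n_exam, cfg.mean_exam, streams["exam"]),
        "admin": _Role("admin", cfg.n_admin, cfg.mean_admin, streams["admin"]),
    }
    arrival_rng = streams["arrival"]
    routing_rng = streams["routing"]
    mean_interarrival = 1.0 / cfg.arrival_rate

    records: list[PatientRecord] = []
    log: list[tuple[int, str, float, str]] | None = [] if collect_event_log else None

    heap: list[tuple[float, int, int, str, int]] = []
    seq = itertools.count()
    clock = 0.0

    def push(t: float, prio: int, kind: str, pid: int) -> None:
        heapq.heappush(heap, (t, prio, next(seq), kind, pid))

    def note(pid: int, event: str, t: float, role: str) -> None:
        if log is not None:
            log.append((pid, event, t, role))

    def mark_start(pid: int, role: str, t: float) -> None:
        rec = records[pid]
        if role == "triage":
            rec.triage_start = t
        elif role == "doctor":
            rec.doctor_visits[-1][1] = t
        elif role == "exam":
            rec.exam_visits[-1][1] = t
        else:
            rec.discharge_start = t
        note(pid, "service_start", t, role)

    def mark_end(pid: int, role: str, t: float) -> None:
        rec = records[pid]
        if role == "triage":
            rec.triage_end = t
        elif role == "doctor":
            rec.doctor_visits[-1][2] = t
        elif role == "exam":
            rec.exam_visits[-1][2] = t
        else:
            rec.discharge_end = t
            rec.disposition = "discharged"
        note(pid, "service_end", t, role)

    def enqueue(pid: int, role_name: str, t: float) -> None:
        rec = records[pid]
        if role_name == "doctor":
            rec.doctor_visits.append([t, None, None])
        elif role_name == "exam":
            rec.exam_visits.append([t, None, None])
        roles[role_name].fifo.append(pid)
        note(pid, "queue_entry", t, role_name)
        try_start(role_name, t)

    def try_start(role_name: str, t: float) -> None:
        role = roles[role_name]
        while role.busy < role.capacity and role.fifo:
            pid = role.fifo.popleft()
            role.busy += 1
            mark_start(pid, role_name, t)
            # draw at service start, from this role's own stream
            end = t + sample_duration(role.mean, role.rng)
            push(end, _PRIO_COMPLETION, f"end_{role_name}", pid)
        role.record(t)

    def schedule_next_arrival(t_prev: float) -> None:
        t = t_prev + sample_duration(mean_interarrival, arrival_rng)
        if t < horizon:  # arrivals only on [0, horizon)
            push(t, _PRIO_ARRIVAL, "arrival", len(records))

    schedule_next_arrival(0.0)

    while heap:
        t, prio, _, kind, pid = heapq.heappop(heap)
        if t > horizon:
            break  # clock stops; in-flight services stay truncated
        if t < clock - 1e-9:
            raise RuntimeError(
                f"event calendar corrupted: clock moved from {clock} back to {t}"
            )
        clock = t

        if kind == "arrival":
            records.append(PatientRecord(patient_id=pid, arrival_time=t))
            note(pid, "arrival", t, "triage")
            enqueue(pid, "triage", t)
            schedule_next_arrival(t)
            continue

        role_name = kind.removeprefix("end_")
        role = roles[role_name]
        role.busy -= 1
        mark_end(pid, role_name, t)
        if role_name == "triage":
            enqueue(pid, "doctor", t)
        elif role_name == "doctor":
            dest = "exam" if route(routing_rng.random(), cfg.p_exam) else "admin"
            enqueue(pid, dest, t)
        elif role_name == "exam":
            dest = "doctor" if route(routing_rng.random(), cfg.p_return) else "admin"
            enqueue(pid, dest, t)
        # admin completion: patient discharged, nothing to enqueue
        try_start(role_name, t)

    traces = {name: role.finish(horizon) for name, role in roles.items()}
    return RunResult(
        config=cfg,
        rep_index=rep_index,
        base_seed=seed,
        records=records,
        traces=traces,
        event_log=log,
    )


def event_log_frame(run: RunResult):
    """Event log of a run as a DataFrame (patient_id, event, time, role)."""
    import pandas as pd

    if run.event_log is None:
        raise ValueError("run was simulated without collect_event_log=True")
    return pd.DataFrame(run.event_log, columns=["patient_id", "event", "time", "role"])
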