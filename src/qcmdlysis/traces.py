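"""In-memory data model for multi-overtone QCM-D time series.

A QCM-D experiment records, for each odd overtone ``n`` of the sensor's
fundamental resonance, the frequency shift ``Δf_n`` (Hz) and dissipation
shift ``ΔD_n`` (conventional 1e-6 units) on a shared time grid (minutes).
Experiments are segmented into an ordered sequence of labelled phases
(buffer baseline, bacteria injection, flushes, static growth, phage
injection, ...) described by a :class:`PhaseSchedule`.

Conventions
-----------
* Time windows are half-open ``[start, end)`` in minutes from experiment
  start: a sample exactly at ``end`` is excluded, one exactly at ``start``
  is included.
* ``Δf`` is stored raw, not divided by the overtone number; the spread
  between raw overtones is meaningful for the lysis statistic.
* ``ΔD`` is stored in units of 1e-6 (a value of ``25.0`` means 25e-6).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "PHASE_NAMES",
    "MEDIA",
    "Phase",
    "PhaseSchedule",
    "OvertoneTrace",
    "QcmdExperiment",
    "OvertoneAbsentError",
    "EmptyWindowError",
    "ScheduleError",
    "get_overtone_series",
    "slice_window",
]

#: Canonical phase names, in experimental order.
PHASE_NAMES = (
    "baseline_pbs",
    "bacteria_injection",
    "flush_1",
    "growth_static",
    "second_injection",
    "flush_2",
    "post_static",
)

MEDIA = ("PBS", "medium", "bacteria_in_medium", "phage_in_medium")

ANALYSIS_OVERTONES = (3, 5, 7, 9, 11)


class OvertoneAbsentError(KeyError):
    """Requested overtone is not present in the experiment."""


class EmptyWindowError(ValueError):
    """A time window does not intersect the experiment's grid."""


class ScheduleError(ValueError):
    """A phase schedule violates ordering/contiguity constraints."""


@dataclass(frozen=True)
class Phase:
    """One labelled experimental window.

    Parameters
    ----------
    name : str
        One of :data:`PHASE_NAMES`.
    start, end : float
        Window bounds in minutes, half-open ``[start, end)``.
    medium : str
        What is in the flow cell (one of :data:`MEDIA`).
    flow_rate : float
        Pump rate in µL/min; ``0`` means static incubation.
    """

    name: str
    start: float
    end: float
    medium: str
    flow_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.name not in PHASE_NAMES:
            raise ScheduleError(f"unknown phase name {self.name!r}")
        if self.medium not in MEDIA:
            raise ScheduleError(f"unknown medium {self.medium!r}")
        if not self.end > self.start:
            raise ScheduleError(
                f"phase {self.name!r}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.flow_rate < 0:
            raise ScheduleError(f"phase {self.name!r}: negative flow rate")

    @property
    def duration(self) -> float:
        return self.end - self.start

    def contains(self, t: float) -> bool:
        return self.start <= t < self.end


@dataclass(frozen=True)
class PhaseSchedule:
    """Ordered, contiguous, non-overlapping experimental phases."""

    phases: tuple[Phase, ...]

    def __init__(self, phases: Sequence[Phase]):
        phases = tuple(phases)
        if not phases:
            raise ScheduleError("schedule must contain at least one phase")
        order = [PHASE_NAMES.index(p.name) for p in phases]
        if order != sorted(order) or len(set(order)) != len(order):
            raise ScheduleError("phases must appear at most once, in canonical order")
        for a, b in zip(phases, phases[1:]):
            if not np.isclose(a.end, b.start):
                raise ScheduleError(
                    f"phases {a.name!r} and {b.name!r} are not contiguous "
                    f"({a.end} != {b.start})"
                )
        object.__setattr__(self, "phases", phases)

    @property
    def start(self) -> float:
        return self.phases[0].start

    @property
    def end(self) -> float:
        return self.phases[-1].end

    def __iter__(self):
        return iter(self.phases)

    def names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.phases)

    def phase(self, name: str) -> Phase:
        for p in self.phases:
            if p.name == name:
                return p
        raise ScheduleError(f"schedule has no phase {name!r}")

    def has_phase(self, name: str) -> bool:
        return any(p.name == name for p in self.phases)

    def phase_at(self, t: float) -> Phase:
        """Phase containing time ``t`` (half-open windows; the final phase
        also claims its right endpoint so the last grid sample is covered)."""
        for p in self.phases:
            if p.contains(t):
                return p
        if np.isclose(t, self.end):
            return self.phases[-1]
        raise ScheduleError(f"time {t} min lies outside the schedule span")

    def clip(self, t_start: float, t_end: float) -> "PhaseSchedule":
        """Restrict the schedule to ``[t_start, t_end)``; phases with empty
        intersection are dropped."""
        kept = []
        for p in self.phases:
            lo, hi = max(p.start, t_start), min(p.end, t_end)
            if hi > lo:
                kept.append(replace(p, start=lo, end=hi))
        if not kept:
            raise EmptyWindowError(
                f"window [{t_start}, {t_end}) does not intersect the schedule"
            )
        return PhaseSchedule(kept)


@dataclass
class OvertoneTrace:
    """Paired Δf/ΔD time series for a single overtone.

    ``delta_f`` is in Hz (raw, not overtone-normalized); ``delta_D`` is in
    units of 1e-6.
    """

    overtone_number: int
    time: np.ndarray
    delta_f: np.ndarray
    delta_D: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.delta_f = np.asarray(self.delta_f, dtype=float)
        self.delta_D = np.asarray(self.delta_D, dtype=float)
        n = self.overtone_number
        if n < 1 or n % 2 == 0:
            raise ValueError(f"overtone number must be an odd integer >= 1, got {n}")
        if self.time.ndim != 1 or len(self.time) == 0:
            raise ValueError("time grid must be a non-empty 1-D array")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time grid must be strictly increasing")
        for name, arr in (("delta_f", self.delta_f), ("delta_D", self.delta_D)):
            if arr.shape != self.time.shape:
                raise ValueError(f"{name} must have the same length as time")

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class QcmdExperiment:
    """All overtone traces of one sensor run, plus phase bookkeeping.

    ``label`` is an optional ground-truth tag for simulated experiments
    (``control``, ``non_infectious`` or ``infectious``).
    """

    sensor_id: str
    traces: Mapping[int, OvertoneTrace]
    schedule: PhaseSchedule
    fundamental_frequency: float = 5e6
    label: Optional[str] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.traces:
            raise ValueError("experiment must contain at least one overtone trace")
        if self.fundamental_frequency <= 0:
            raise ValueError("fundamental frequency must be positive")
        grids = [tr.time for tr in self.traces.values()]
        ref = grids[0]
        for tr in self.traces.values():
            if tr.time.shape != ref.shape or not np.array_equal(tr.time, ref):
                raise ValueError("all overtone traces must share one time grid")
        for n, tr in self.traces.items():
            if n != tr.overtone_number:
                raise ValueError(
                    f"trace keyed {n} carries overtone_number {tr.overtone_number}"
                )
        # Grids follow the half-open convention (a run over [0, T) samples up
        # to T - dt), so the schedule may extend up to one grid step past the
        # final sample.
        step = float(np.median(np.diff(ref))) if len(ref) > 1 else 0.0
        if (
            self.schedule.start < ref[0] - step - 1e-9
            or self.schedule.end > ref[-1] + step + 1e-9
        ):
            raise ValueError(
                f"schedule span [{self.schedule.start}, {self.schedule.end}] exceeds "
                f"the time grid span [{ref[0]}, {ref[-1]}]"
            )
        if self.label is not None and self.label not in (
            "control",
            "non_infectious",
            "infectious",
        ):
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def time(self) -> np.ndarray:
        return next(iter(self.traces.values())).time

    @property
    def overtones(self) -> tuple[int, ...]:
        return tuple(sorted(self.traces))

    def has_full_overtone_set(self) -> bool:
        """Whether overtones 3..11 needed for the full analysis are present."""
        return all(n in self.traces for n in ANALYSIS_OVERTONES)


def get_overtone_series(
    exp: QcmdExperiment, n: int, channel: str
) -> np.ndarray:
    """Return one overtone's ``frequency`` (Δf) or ``dissipation`` (ΔD) series.

    Raises
    ------
    OvertoneAbsentError
        If overtone ``n`` is not recorded in the experiment.
    """
    if n not in exp.traces:
        raise OvertoneAbsentError(
            f"overtone {n} absent (available: {exp.overtones})"
        )
    trace = exp.traces[n]
    if channel == "frequency":
        return trace.delta_f
    if channel == "dissipation":
        return trace.delta_D
    raise ValueError(f"channel must be 'frequency' or 'dissipation', got {channel!r}")


def slice_window(exp: QcmdExperiment, t_start: float, t_end: float) -> QcmdExperiment:
    """Restrict an experiment to the half-open window ``[t_start, t_end)``.

    All traces are cut to the window and the schedule is clipped to the
    retained grid span.
    """
    if not t_start < t_end:
        raise ValueError(f"t_start ({t_start}) must be < t_end ({t_end})")
    time = exp.time
    mask = (time >= t_start) & (time < t_end)
    if not mask.any():
        raise EmptyWindowError(
            f"window [{t_start}, {t_end}) contains no samples of the grid"
        )
    new_traces = {
        n: OvertoneTrace(n, tr.time[mask], tr.delta_f[mask], tr.delta_D[mask])
        for n, tr in exp.traces.items()
    }
    schedule = exp.schedule.clip(
        max(t_start, exp.schedule.start), min(t_end, exp.schedule.end)
    )
    return QcmdExperiment(
        sensor_id=exp.sensor_id,
        traces=new_traces,
        schedule=schedule,
        fundamental_frequency=exp.fundamental_frequency,
        label=exp.label,
        metadata=dict(exp.metadata),
    )
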