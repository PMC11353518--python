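"""Hierarchical segmentation of a keystroke stream.

Three nested burst levels are delimited purely by the IKI preceding each
keystroke, compared against the translator's fitted thresholds:

* IKI >= ``tsp``   opens a new **Task Segment** (and Task, and motor program),
* ``rsp`` <= IKI < ``tsp`` opens a new **Task** within the segment,
* ``delay`` <= IKI < ``rsp`` opens a new **motor program** within the Task,
* IKI < ``delay`` continues the current motor program.

Comparisons use ``>=`` throughout: an IKI exactly at a threshold opens the
new unit.  The result is a partition — every event belongs to exactly one
motor program, one Task and one Task Segment, and every Task Segment
boundary is a Task boundary, every Task boundary a motor-program boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import KeystrokeLog, compute_ikis
from .pauses import TranslatorThresholds


@dataclass(frozen=True)
class Unit:
    """A contiguous event-index range [start, end] (inclusive)."""

    start: int
    end: int

    @property
    def n_events(self) -> int:
        return self.end - self.start + 1

    def slice(self) -> slice:
        return slice(self.start, self.end + 1)


class MotorProgram(Unit):
    """Automatized typing run: all internal IKIs below the 200 ms Delay."""


class Task(Unit):
    """Maximal run with no internal IKI >= RSP; a sequence of motor programs."""


class TaskSegment(Unit):
    """Maximal run with no internal IKI >= TSP; a sequence of Tasks."""


@dataclass(frozen=True)
class TranslationUnit:
    """A Task Segment together with the pause (TSP) that precedes it.

    The first unit of a session has no preceding pause (``pause is None``).
    """

    pause: int | None
    segment: TaskSegment


@dataclass
class SegmentedLog:
    """Three-level nested partition of one session's events.

    ``mp_ids``/``task_ids``/``ts_ids`` assign every event to its motor
    program, Task and Task Segment (0-based, increasing with time).
    """

    log: KeystrokeLog
    thresholds: TranslatorThresholds
    mp_ids: np.ndarray = field(repr=False)
    task_ids: np.ndarray = field(repr=False)
    ts_ids: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return len(self.log)

    @staticmethod
    def _units(ids: np.ndarray, cls: type[Unit]) -> list[Unit]:
        if len(ids) == 0:
            return []
        starts = np.flatnonzero(np.r_[True, ids[1:] != ids[:-1]])
        ends = np.r_[starts[1:] - 1, len(ids) - 1]
        return [cls(int(s), int(e)) for s, e in zip(starts, ends)]

    @cached_property
    def motor_programs(self) -> list[MotorProgram]:
        return self._units(self.mp_ids, MotorProgram)

    @cached_property
    def tasks(self) -> list[Task]:
        return self._units(self.task_ids, Task)

    @cached_property
    def task_segments(self) -> list[TaskSegment]:
        return self._units(self.ts_ids, TaskSegment)

    @cached_property
    def tasks_by_segment(self) -> list[list[Task]]:
        """Tasks grouped by their Task Segment, in stream order."""
        groups: list[list[Task]] = [[] for _ in self.task_segments]
        for task in self.tasks:
            groups[int(self.ts_ids[task.start])].append(task)
        return groups

    def tasks_of(self, segment: TaskSegment) -> list[Task]:
        return self.tasks_by_segment[int(self.ts_ids[segment.start])]

    def duration(self, unit: Unit) -> int:
        """First-to-last keydown span of a unit, excluding the preceding pause."""
        t = self.log.times
        return int(t[unit.end] - t[unit.start])

    def internal_ikis(self, unit: Unit) -> np.ndarray:
        """IKIs strictly inside a unit (between its consecutive events)."""
        t = self.log.times
        return np.diff(t[unit.slice()])

    def event_table(self) -> pd.DataFrame:
        """One row per event: index, motor_program_id, task_id, task_segment_id."""
        return pd.DataFrame(
            {
                "event_index": np.arange(len(self)),
                "motor_program_id": self.mp_ids,
                "task_id": self.task_ids,
                "task_segment_id": self.ts_ids,
            }
        )

    def segment_table(self) -> pd.DataFrame:
        """One row per Task Segment: id, start, end, duration, n_tasks, n_keystrokes."""
        t = self.log.times
        rows = []
        for i, seg in enumerate(self.task_segments):
            rows.append(
                (
                    i,
                    int(t[seg.start]),
                    int(t[seg.end]),
                    self.duration(seg),
                    len(self.tasks_of(seg)),
                    seg.n_events,
                )
            )
        return pd.DataFrame(
            rows,
            columns=[
                "task_segment_id",
                "start",
                "end",
                "duration",
                "n_tasks",
                "n_keystrokes",
            ],
        )


def segment(log: KeystrokeLog, thresholds: TranslatorThresholds) -> SegmentedLog:
    """Partition a session into motor programs, Tasks and Task Segments.

    Requires ``rsp < tsp`` (otherwise the two levels are indistinguishable
    and a :class:`ConfigurationError` is raised).  If ``delay >= rsp`` —
    an unusually fast typist — the motor-program level collapses into the
    Task level and a warning is emitted.
    """
    rsp, tsp, delay = thresholds.rsp, thresholds.tsp, thresholds.delay
    if rsp >= tsp:
        raise ConfigurationError(
            f"degenerate thresholds for {thresholds.translator_id}: "
            f"rsp ({rsp:.0f}) >= tsp ({tsp:.0f})"
        )
    if delay >= rsp:
        warnings.warn(
            f"translator {thresholds.translator_id}: delay ({delay:.0f} ms) >= rsp "
            f"({rsp:.0f} ms); collapsing the motor-program level into Tasks",
            stacklevel=2,
        )
        delay = rsp
    n = len(log)
    if n == 0:
        empty = np.array([], dtype=np.int64)
        return SegmentedLog(log, thresholds, empty, empty.copy(), empty.copy())
    ikis = compute_ikis(log).to_numpy() if n > 1 else np.array([], dtype=np.int64)
    mp_ids = np.r_[0, np.cumsum(ikis >= delay)]
    task_ids = np.r_[0, np.cumsum(ikis >= rsp)]
    ts_ids = np.r_[0, np.cumsum(ikis >= tsp)]
    return SegmentedLog(log, thresholds, mp_ids, task_ids, ts_ids)


def translation_units(segmented: SegmentedLog) -> list[TranslationUnit]:
    """Decompose a session into TUs: (preceding TSP, Task Segment) pairs.

    The pause of a TU is the IKI between the last keystroke of the previous
    Task Segment and the first keystroke of this one; the session's first TU
    has no pause.  Initial offset + sum of pauses + sum of segment durations
    telescopes to the session span.
    """
    t = segmented.log.times
    units: list[TranslationUnit] = []
    prev_end: int | None = None
    for seg in segmented.task_segments:
        pause = None if prev_end is None else int(t[seg.start] - t[prev_end])
        units.append(TranslationUnit(pause, seg))
        prev_end = seg.end
    return units


def iter_session_tasks(segmented: SegmentedLog) -> Iterator[tuple[int, Task]]:
    """Yield (task_segment_id, Task) pairs in stream order."""
    for ts_id, seg in enumerate(segmented.task_segments):
        for task in segmented.tasks_of(seg):
            yield ts_id, task
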