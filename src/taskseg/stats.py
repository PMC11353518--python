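"""Task / Task-Segment labeling and summary statistics, incl. HOF tables.

Tasks are labeled by their keystroke operations — **A** (insertions only),
**D** (deletions only), **C** (both) — and a Task Segment is labeled by the
concatenation of its Task labels in order ("AA", "DA", ...).  On top of the
labels this module computes:

* the Task-Segment label summary (counts, per-group shares, mean duration,
  mean internal IKI, mean keystrokes per Task),
* the transition matrix between successive HOF states,
* per-state duration/keystroke/Task statistics and the fraction of state
  time spent in Task Segment Pauses,
* the distribution of Task types per HOF state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import HOF_STATES, HOFAnnotation
from .segmentation import SegmentedLog, Task, TaskSegment, translation_units

TASK_LABELS = ("A", "D", "C")


def label_task(segmented: SegmentedLog, task: Task) -> str:
    """Label one Task: A = only insertions, D = only deletions, C = mixed."""
    ops = segmented.log.events["op"].to_numpy()[task.slice()]
    has_ins = bool((ops == "insert").any())
    has_del = bool((ops == "delete").any())
    if has_ins and has_del:
        return "C"
    return "A" if has_ins else "D"


def label_task_segment(segmented: SegmentedLog, segment: TaskSegment) -> str:
    """Label a Task Segment by concatenating its Task labels in order."""
    return "".join(label_task(segmented, t) for t in segmented.tasks_of(segment))


def session_labels(segmented: SegmentedLog) -> list[str]:
    """Task Segment labels for a whole session, in stream order."""
    return [label_task_segment(segmented, seg) for seg in segmented.task_segments]


def summarize_ts_labels(
    segmented_logs: Sequence[SegmentedLog],
    groupby: str = "group",
    top: int | None = None,
) -> pd.DataFrame:
    """Summarize Task Segment labels over a cohort of segmented sessions.

    One row per label, sorted by total count descending:

    * ``total`` — number of Task Segments bearing the label,
    * ``share_<g>`` — percentage of group *g*'s Task Segments (shares are
      computed over *all* labels; ``top`` only truncates the display),
    * ``dur_ts`` — mean first-to-last-keydown duration (ms),
    * ``iki`` — mean over all IKIs internal to the labeled segments
      (inter-Task Respites included, the preceding TSP excluded),
    * ``key_t`` — mean keystrokes per Task.

    ``groupby`` names the log metadata field used for the share columns
    (e.g. ``"group"`` for the target-language tag, or ``"translator_id"``).
    """
    rows = []
    for seg_log in segmented_logs:
        group = getattr(seg_log.log, groupby)
        for seg, tasks in zip(seg_log.task_segments, seg_log.tasks_by_segment):
            label = "".join(label_task(seg_log, t) for t in tasks)
            internal = seg_log.internal_ikis(seg)
            rows.append(
                (
                    label,
                    group,
                    seg_log.duration(seg),
                    internal.sum(),
                    len(internal),
                    seg.n_events,
                    len(tasks),
                )
            )
    if not rows:
        raise ValueError("no Task Segments to summarize")
    df = pd.DataFrame(
        rows,
        columns=["ts_label", "group", "dur", "iki_sum", "iki_n", "keys", "tasks"],
    )
    agg = df.groupby("ts_label").agg(
        total=("ts_label", "size"),
        dur_ts=("dur", "mean"),
        iki_sum=("iki_sum", "sum"),
        iki_n=("iki_n", "sum"),
        keys=("keys", "sum"),
        tasks=("tasks", "sum"),
    )
    agg["iki"] = agg["iki_sum"] / agg["iki_n"].replace(0, np.nan)
    agg["key_t"] = agg["keys"] / agg["tasks"]
    shares = (
        df.groupby(["ts_label", "group"]).size().unstack("group", fill_value=0)
    )
    shares = 100.0 * shares / shares.sum(axis=0)
    for g in shares.columns:
        agg[f"share_{g}"] = shares[g]
    agg = agg.drop(columns=["iki_sum", "iki_n", "keys", "tasks"])
    agg = agg.sort_values("total", ascending=False)
    out = agg.reset_index()
    return out.head(top) if top is not None else out


# ---------------------------------------------------------------------------
# HOF state statistics
# ---------------------------------------------------------------------------


def collapse_states(states: Sequence[str]) -> list[str]:
    """Collapse runs of identical adjacent states into single states."""
    out: list[str] = []
    for s in states:
        if not out or out[-1] != s:
            out.append(s)
    return out


def hof_transition_matrix(
    annotations: Iterable[HOFAnnotation],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Estimate the transition matrix between successive HOF states.

    Adjacent identical states are collapsed first, so the diagonal is
    structurally zero.  Transitions are counted within sessions only, never
    across session boundaries; a session with fewer than two (collapsed)
    states contributes nothing.  Returns ``(probabilities, counts)`` as
    3x3 DataFrames in the fixed state order O, F, H; rows of the
    probability matrix sum to 1 (rows with no observations stay 0).
    """
    counts = pd.DataFrame(
        np.zeros((3, 3)), index=list(HOF_STATES), columns=list(HOF_STATES)
    )
    by_session: dict[str, list[HOFAnnotation]] = {}
    for ann in annotations:
        by_session.setdefault(ann.session_id, []).append(ann)
    for anns in by_session.values():
        anns = sorted(anns, key=lambda a: a.start)
        states = collapse_states([a.state for a in anns])
        for a, b in zip(states, states[1:]):
            counts.loc[a, b] += 1
    row_sums = counts.sum(axis=1)
    probs = counts.div(row_sums.replace(0, np.nan), axis=0).fillna(0.0)
    return probs, counts


@dataclass
class HOFStatsResult:
    """Per-state summary statistics over annotated sessions.

    ``table`` has a row per (state, aggregate) with the per-session-first
    convention: each metric is averaged over the state visits within a
    session, then mean/min/max are taken across sessions.  Metrics:
    ``dur`` (ms per visit), ``keys``, ``ts`` (Task Segments), ``tasks``
    per visit, plus ``key_ts`` and ``key_t``.  ``tsp_time_fraction`` is the
    pooled fraction of state time spent in Task Segment Pauses, and
    ``unannotated_keystrokes`` counts events outside every interval.
    """

    table: pd.DataFrame
    tsp_time_fraction: pd.Series
    unannotated_keystrokes: int
    state_keystrokes: pd.Series


def _interval_index(
    annotations: Sequence[HOFAnnotation], times: np.ndarray
) -> np.ndarray:
    """Index of the (closed) interval containing each timestamp, else -1."""
    if not annotations:
        return np.full(len(times), -1)
    starts = np.array([a.start for a in annotations])
    ends = np.array([a.end for a in annotations])
    idx = np.searchsorted(starts, times, side="right") - 1
    idx_clipped = np.clip(idx, 0, len(annotations) - 1)
    inside = (idx >= 0) & (times <= ends[idx_clipped])
    return np.where(inside, idx, -1)


def hof_state_stats(
    segmented_logs: Sequence[SegmentedLog],
    annotations: Sequence[HOFAnnotation],
) -> HOFStatsResult:
    """Compute per-state duration/keystroke/Task-Segment/Task statistics.

    Keystrokes, Task Segments and Tasks are assigned to the annotation
    interval containing their (first) keystroke timestamp; keystrokes
    outside every interval go to an ``unannotated`` bucket, reported but not
    dropped silently.  An interval with no keystrokes still contributes its
    duration (e.g. Orientation, which produces none by definition).
    """
    by_session: dict[str, list[HOFAnnotation]] = {}
    for ann in annotations:
        by_session.setdefault(ann.session_id, []).append(ann)

    visit_rows = []  # one row per state visit
    tsp_in_state = {s: 0.0 for s in HOF_STATES}
    time_in_state = {s: 0.0 for s in HOF_STATES}
    unannotated = 0
    state_keys = {s: 0 for s in HOF_STATES}

    for seg_log in segmented_logs:
        session = seg_log.log.session_id
        anns = sorted(by_session.get(session, []), key=lambda a: a.start)
        times = seg_log.log.times
        ev_interval = _interval_index(anns, times)
        unannotated += int((ev_interval == -1).sum())
        ts_first = np.array([s.start for s in seg_log.task_segments], dtype=int)
        task_first = np.array([t.start for t in seg_log.tasks], dtype=int)
        ts_interval = ev_interval[ts_first] if len(ts_first) else ts_first
        task_interval = ev_interval[task_first] if len(task_first) else task_first
        for k, ann in enumerate(anns):
            keys = int((ev_interval == k).sum())
            n_ts = int((ts_interval == k).sum())
            n_tasks = int((task_interval == k).sum())
            visit_rows.append(
                (session, ann.state, ann.duration, keys, n_ts, n_tasks)
            )
            time_in_state[ann.state] += ann.duration
            state_keys[ann.state] += keys
        # TSP time inside each interval: overlap of inter-segment pauses
        for tu in translation_units(seg_log):
            if tu.pause is None:
                continue
            p_end = int(times[tu.segment.start])
            p_start = p_end - tu.pause
            for ann in anns:
                lo, hi = max(p_start, ann.start), min(p_end, ann.end)
                if hi > lo:
                    tsp_in_state[ann.state] += hi - lo

    if not visit_rows:
        raise ValueError("no annotated state visits")
    visits = pd.DataFrame(
        visit_rows, columns=["session", "state", "dur", "keys", "ts", "tasks"]
    )
    per_session = visits.groupby(["session", "state"]).mean(numeric_only=True)
    per_session["key_ts"] = per_session["keys"] / per_session["ts"].replace(0, np.nan)
    per_session["key_t"] = per_session["keys"] / per_session["tasks"].replace(0, np.nan)
    table = per_session.groupby("state").agg(["mean", "min", "max"])
    tsp_frac = pd.Series(
        {
            s: (tsp_in_state[s] / time_in_state[s] if time_in_state[s] else np.nan)
            for s in HOF_STATES
        },
        name="tsp_time_fraction",
    )
    return HOFStatsResult(
        table=table,
        tsp_time_fraction=tsp_frac,
        unannotated_keystrokes=unannotated,
        state_keystrokes=pd.Series(state_keys, name="keystrokes"),
    )


def task_distribution_by_state(
    segmented_logs: Sequence[SegmentedLog],
    annotations: Sequence[HOFAnnotation],
) -> pd.DataFrame:
    """Proportion of A/D/C Tasks realized in each HOF state.

    A Task belongs to the state interval containing its first keystroke's
    timestamp.  Columns (states) sum to 1; states with no Tasks are
    omitted (Orientation typically produces none).
    """
    by_session: dict[str, list[HOFAnnotation]] = {}
    for ann in annotations:
        by_session.setdefault(ann.session_id, []).append(ann)
    counts: dict[str, dict[str, int]] = {}
    for seg_log in segmented_logs:
        anns = sorted(
            by_session.get(seg_log.log.session_id, []), key=lambda a: a.start
        )
        if not anns:
            continue
        times = seg_log.log.times
        for task in seg_log.tasks:
            idx = _interval_index(anns, times[[task.start]])[0]
            if idx == -1:
                continue
            state = anns[idx].state
            lab = label_task(seg_log, task)
            counts.setdefault(state, {l: 0 for l in TASK_LABELS})[lab] += 1
    if not counts:
        raise ValueError("no Tasks fall inside annotated intervals")
    df = pd.DataFrame(counts).reindex(list(TASK_LABELS)).fillna(0.0)
    df = df[[s for s in HOF_STATES if s in df.columns]]
    return df / df.sum(axis=0)


def label_conservation(
    segmented_logs: Sequence[SegmentedLog],
) -> Mapping[str, int]:
    """Bookkeeping totals used by the conservation invariants."""
    n_segments = sum(len(s.task_segments) for s in segmented_logs)
    n_tasks = sum(len(s.tasks) for s in segmented_logs)
    labels = [lab for s in segmented_logs for lab in session_labels(s)]
    return {
        "n_segments": n_segments,
        "n_tasks": n_tasks,
        "n_labels": len(labels),
        "label_length_sum": sum(len(l) for l in labels),
    }
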