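"""Reading, validating and writing keystroke logs and HOF annotation tables.

A keystroke log is one translation session: an ordered stream of keypress
events, each with a key-down timestamp in integer milliseconds from session
start, the character produced (or removed), the operation (``insert`` or
``delete``) and the index of the source segment being translated.  Blank
spaces are normalized to the underscore ``"_"``.

The canonical on-disk format is a UTF-8 tab-separated table with the header

    session_id  translator_id  study_id  group  time  char  op  segment_index

A permissive ``tprdb_like`` dialect maps the column names used by CRITT
TPR-DB style keystroke tables onto the canonical ones.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

CANONICAL_COLUMNS = [
    "session_id",
    "translator_id",
    "study_id",
    "group",
    "time",
    "char",
    "op",
    "segment_index",
]

ANNOTATION_COLUMNS = ["session_id", "start", "end", "state"]

HOF_STATES = ("O", "F", "H")

OPS = ("insert", "delete")

#: TPR-DB style column names accepted by the ``tprdb_like`` dialect.
TPRDB_COLUMN_MAP = {
    "Session": "session_id",
    "Part": "translator_id",
    "Participant": "translator_id",
    "Study": "study_id",
    "TL": "group",
    "Lang": "group",
    "Time": "time",
    "Char": "char",
    "Type": "op",
    "Op": "op",
    "Seg": "segment_index",
    "STseg": "segment_index",
}


@dataclass(frozen=True)
class HOFAnnotation:
    """One manually annotated phenomenal-state interval.

    ``state`` is one of the HOF taxonomy labels: ``"H"`` (Hesitation),
    ``"O"`` (Orientation), ``"F"`` (Flow).  ``start``/``end`` are
    milliseconds on the session clock, ``start < end``, and the interval is
    treated as closed (a keystroke at exactly ``end`` belongs to it).
    """

    session_id: str
    start: int
    end: int
    state: str

    def __post_init__(self) -> None:
        if self.state not in HOF_STATES:
            raise ValidationError(
                f"annotation state must be one of {HOF_STATES}, got {self.state!r}"
            )
        if not self.start < self.end:
            raise ValidationError(
                f"annotation interval reversed or empty: start={self.start}, end={self.end}"
            )

    @property
    def duration(self) -> int:
        return self.end - self.start


@dataclass
class KeystrokeLog:
    """An ordered keypress stream of a single translation session.

    ``events`` is a DataFrame with the canonical columns; timestamps are
    non-decreasing and every row carries the same ``session_id``.
    """

    events: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.events = validate_events(self.events)

    # -- metadata ---------------------------------------------------------
    def _meta(self, column: str) -> str:
        return "" if self.events.empty else str(self.events[column].iloc[0])

    @property
    def session_id(self) -> str:
        return self._meta("session_id")

    @property
    def translator_id(self) -> str:
        return self._meta("translator_id")

    @property
    def study_id(self) -> str:
        return self._meta("study_id")

    @property
    def group(self) -> str:
        return self._meta("group")

    def __len__(self) -> int:
        return len(self.events)

    @property
    def times(self) -> np.ndarray:
        return self.events["time"].to_numpy()

    @property
    def span(self) -> int:
        """Session span: last minus first timestamp (0 for <2 events)."""
        if len(self) < 2:
            return 0
        t = self.times
        return int(t[-1] - t[0])


def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalize an event table (sorted, typed, one session)."""
    missing = [c for c in CANONICAL_COLUMNS if c not in events.columns]
    if missing:
        raise ValidationError(f"event table missing columns: {missing}")
    events = events.loc[:, CANONICAL_COLUMNS].copy()
    for col in ("session_id", "translator_id", "study_id", "group", "char", "op"):
        events[col] = events[col].astype(str)
    for col, kind in (("time", "timestamp"), ("segment_index", "segment index")):
        try:
            events[col] = events[col].astype(np.int64)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"non-numeric {kind} in column {col!r}: {exc}") from exc
    if len(events):
        if events["session_id"].nunique() > 1:
            raise ValidationError(
                f"log mixes sessions: {sorted(events['session_id'].unique())}"
            )
        if (events["time"] < 0).any():
            row = int(np.argmax(events["time"].to_numpy() < 0))
            raise ValidationError(f"negative timestamp at row {row}")
        if (events["segment_index"] < 0).any():
            raise ValidationError("negative segment_index")
        bad_op = ~events["op"].isin(OPS)
        if bad_op.any():
            row = int(np.argmax(bad_op.to_numpy()))
            raise ValidationError(
                f"row {row}: op must be one of {OPS}, got {events['op'].iloc[row]!r}"
            )
        if (events["char"].str.len() == 0).any():
            raise ValidationError("empty char token")
        events["char"] = events["char"].str.replace(" ", "_", regex=False)
        events = events.sort_values("time", kind="stable", ignore_index=True)
    return events.reset_index(drop=True)


def _read_table(path: str | Path | _stdio.IOBase) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc


def _normalize_op(value: str) -> str:
    low = value.strip().lower()
    if low.startswith("ins"):
        return "insert"
    if low.startswith("del"):
        return "delete"
    return value


def read_logs(
    path: str | Path, dialect: str = "canonical_tsv"
) -> list[KeystrokeLog]:
    """Read a keystroke table that may contain several sessions.

    Returns one :class:`KeystrokeLog` per ``session_id``, in order of first
    appearance.
    """
    df = _read_table(path)
    if dialect == "tprdb_like":
        df = df.rename(columns=TPRDB_COLUMN_MAP)
        for col in CANONICAL_COLUMNS:
            if col not in df.columns:
                df[col] = "0" if col in ("time", "segment_index") else "unknown"
        df["op"] = df["op"].map(_normalize_op)
    elif dialect != "canonical_tsv":
        raise ValueError(f"unknown dialect {dialect!r}")
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: header missing columns {missing}")
    logs = []
    for _, sub in df.groupby("session_id", sort=False):
        logs.append(KeystrokeLog(sub))
    return logs


def read_log(path: str | Path, dialect: str = "canonical_tsv") -> KeystrokeLog:
    """Read a single-session keystroke log.

    Raises :class:`ValidationError` if the file holds more than one session
    (use :func:`read_logs` for multi-session tables).
    """
    logs = read_logs(path, dialect=dialect)
    if not logs:
        raise ValidationError(f"{path}: no events")
    if len(logs) > 1:
        raise ValidationError(
            f"{path}: expected one session, found {len(logs)}; use read_logs()"
        )
    return logs[0]


def write_log(log: KeystrokeLog, path: str | Path) -> None:
    """Write a log (canonical TSV).  ``read_log(write_log(x)) == x``."""
    log.events.to_csv(path, sep="\t", index=False)


def write_logs(logs: Iterable[KeystrokeLog], path: str | Path) -> None:
    frames = [log.events for log in logs]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def compute_ikis(log: KeystrokeLog) -> pd.Series:
    """Inter-keystroke intervals: the lag between successive key-down events.

    Returns a Series of length ``len(log) - 1`` indexed by the position of
    the event each IKI *precedes* (1..n-1); the first keystroke of a session
    carries no IKI.  All values are non-negative integers.
    """
    if len(log) < 1:
        raise ValidationError("compute_ikis requires at least one event")
    t = log.times
    return pd.Series(np.diff(t), index=np.arange(1, len(t)), name="iki")


def read_annotations(path: str | Path) -> list[HOFAnnotation]:
    """Read an HOF annotation table (TSV: session_id, start, end, state).

    Intervals of one session must be time-ordered and non-overlapping;
    offending rows are named in the error.
    """
    df = _read_table(path)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: header missing columns {missing}")
    anns = []
    for row, rec in enumerate(df.itertuples(index=False)):
        try:
            start, end = int(rec.start), int(rec.end)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{path} row {row}: non-numeric interval") from exc
        anns.append(HOFAnnotation(str(rec.session_id), start, end, str(rec.state)))
    validate_annotations(anns, origin=str(path))
    return anns


def validate_annotations(
    annotations: Sequence[HOFAnnotation], origin: str = "annotations"
) -> None:
    """Check per-session ordering and disjointness of closed intervals."""
    by_session: dict[str, list[tuple[int, HOFAnnotation]]] = {}
    for row, ann in enumerate(annotations):
        by_session.setdefault(ann.session_id, []).append((row, ann))
    for session, rows in by_session.items():
        for (row_a, a), (row_b, b) in zip(rows, rows[1:]):
            if b.start <= a.end:
                kind = "overlap" if b.start < a.end else "touch"
                if b.start < a.start:
                    kind = "out-of-order"
                raise ValidationError(
                    f"{origin}: session {session} rows {row_a} and {row_b} {kind} "
                    f"([{a.start},{a.end}] then [{b.start},{b.end}])"
                )


def write_annotations(
    annotations: Sequence[HOFAnnotation], path: str | Path
) -> None:
    pd.DataFrame(
        [(a.session_id, a.start, a.end, a.state) for a in annotations],
        columns=ANNOTATION_COLUMNS,
    ).to_csv(path, sep="\t", index=False)
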