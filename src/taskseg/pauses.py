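"""Keystroke boundary classes, pause taxonomy and per-translator thresholds.

Typing unfolds in bursts separated by pauses of very different character.
The taxonomy used here distinguishes the IKI *preceding* a keystroke by the
kind of keystroke it leads into:

* **WP** (within-word pause): IKI preceding a within-word keystroke,
* **BP** (between-word pause): IKI preceding a word-initial keystroke,
* **SP** (between-segment pause): IKI preceding a segment-initial keystroke.

Because translators type at very different speeds, the burst-segmentation
thresholds are fitted per translator from the pooled WP and BP samples:

    RSP (Respite)            = 2 * median(WP)
    TSP (Task Segment Pause) = 3 * median(BP)

together with a fixed 200 ms *Delay* separating motor programs and a
*Superpause* threshold (``superpause_multiplier * TSP`` by default) marking
Orientation-scale interruptions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import EstimationError
from .io import KeystrokeLog, compute_ikis

#: Word-boundary keystrokes.  Blank spaces are normalized to "_" upstream.
#: The typographic quote characters appear in logged data alongside their
#: ASCII counterparts, so both variants are included by default; pass an
#: explicit set to restrict the alphabet.
DEFAULT_BOUNDARY_CHARS = frozenset("`“”‘’\"'_.!?:=@$%&*()[]{}")

#: The minimal boundary alphabet (typographic quotes only, no ASCII ones).
STRICT_BOUNDARY_CHARS = frozenset("`“’_.!?:=@$%&*()[]{}")

#: Fixed motor-program threshold in ms (not fitted).
DELAY_MS = 200.0

BOUNDARY_CLASSES = (
    "word_boundary",
    "within_word",
    "word_initial",
    "segment_initial",
    "word_final_or_other",
)

PAUSE_CLASSES = ("WP", "BP", "SP", "unclassified")


@dataclass(frozen=True)
class TranslatorThresholds:
    """Per-translator pause thresholds and the medians they derive from.

    ``rsp = 2 * median_wp`` and ``tsp = 3 * median_bp``; ``delay`` is the
    global 200 ms motor-program threshold and ``superpause`` a configurable
    multiple of ``tsp``.  ``degenerate`` flags the (never silently accepted)
    case ``rsp >= tsp``.
    """

    translator_id: str
    median_wp: float
    median_bp: float
    rsp: float
    tsp: float
    delay: float
    superpause: float
    n_wp: int
    n_bp: int
    median_sp: float = float("nan")
    n_sp: int = 0

    @property
    def degenerate(self) -> bool:
        return self.rsp >= self.tsp


def classify_boundary(
    log: KeystrokeLog,
    boundary_chars: frozenset[str] | set[str] = DEFAULT_BOUNDARY_CHARS,
) -> pd.Series:
    """Assign one boundary class to every keystroke of a session.

    Rules (applied in order of precedence):

    * a keystroke whose character is in ``boundary_chars`` — or a named
      multi-character token such as ``Return`` — is a ``word_boundary``;
    * the first non-boundary keystroke of a new segment (a change of
      ``segment_index``) is ``segment_initial``;
    * any other non-boundary keystroke preceded by a boundary keystroke
      (or by session start) is ``word_initial``;
    * a non-boundary keystroke followed by a boundary keystroke is
      ``word_final_or_other``;
    * the remainder — non-boundary characters flanked by non-boundary
      characters — are ``within_word``.

    Deletions are classified by the character they remove, with the same
    alphabet.  A missing follower (session end) does not count as a
    boundary, a missing predecessor (session start) does.
    """
    events = log.events
    n = len(events)
    if n == 0:
        return pd.Series([], dtype=object, name="boundary_class")
    chars = events["char"].to_numpy()
    is_boundary = np.fromiter(
        (c in boundary_chars or len(c) > 1 for c in chars), dtype=bool, count=n
    )
    prev_is_boundary = np.empty(n, dtype=bool)
    prev_is_boundary[0] = True  # session start behaves like a boundary
    prev_is_boundary[1:] = is_boundary[:-1]
    next_is_boundary = np.zeros(n, dtype=bool)
    next_is_boundary[:-1] = is_boundary[1:]

    seg = events["segment_index"].to_numpy()
    new_segment = np.empty(n, dtype=bool)
    new_segment[0] = True
    new_segment[1:] = seg[1:] != seg[:-1]
    # first non-boundary keystroke at or after each segment change
    segment_group = np.cumsum(new_segment)
    first_nonb = np.zeros(n, dtype=bool)
    seen: set[int] = set()
    for i in range(n):
        if not is_boundary[i] and segment_group[i] not in seen:
            seen.add(int(segment_group[i]))
            first_nonb[i] = True

    out = np.where(
        is_boundary,
        "word_boundary",
        np.where(
            first_nonb & prev_is_boundary,
            "segment_initial",
            np.where(
                prev_is_boundary,
                "word_initial",
                np.where(next_is_boundary, "word_final_or_other", "within_word"),
            ),
        ),
    )
    return pd.Series(out, name="boundary_class")


_PAUSE_OF_BOUNDARY = {
    "within_word": "WP",
    "word_initial": "BP",
    "segment_initial": "SP",
    "word_boundary": "unclassified",
    "word_final_or_other": "unclassified",
}


def classify_pauses(
    log: KeystrokeLog,
    boundaries: pd.Series | None = None,
    ikis: pd.Series | None = None,
    boundary_chars: frozenset[str] | set[str] = DEFAULT_BOUNDARY_CHARS,
) -> pd.Series:
    """Classify every IKI by the keystroke it precedes.

    Returns a Series aligned with :func:`taskseg.io.compute_ikis` (indexed
    by event position 1..n-1): ``WP``/``BP``/``SP`` for IKIs preceding
    within-word, word-initial and segment-initial keystrokes, otherwise
    ``unclassified``.  The session's first keystroke has no IKI and hence no
    pause class; counts over the classes are conserved
    (``#WP + #BP + #SP + #unclassified = n_events - 1``).
    """
    if boundaries is None:
        boundaries = classify_boundary(log, boundary_chars)
    if ikis is None:
        ikis = compute_ikis(log)
    classes = boundaries.iloc[1:].map(_PAUSE_OF_BOUNDARY).to_numpy()
    return pd.Series(classes, index=ikis.index, name="pause_class")


def pause_samples(
    logs: Iterable[KeystrokeLog],
    boundary_chars: frozenset[str] | set[str] = DEFAULT_BOUNDARY_CHARS,
) -> dict[str, np.ndarray]:
    """Pool WP/BP/SP IKI samples over the sessions of one translator."""
    pools: dict[str, list[np.ndarray]] = {"WP": [], "BP": [], "SP": []}
    for log in logs:
        if len(log) < 2:
            continue
        ikis = compute_ikis(log)
        classes = classify_pauses(log, ikis=ikis, boundary_chars=boundary_chars)
        values = ikis.to_numpy(dtype=float)
        for name in pools:
            pools[name].append(values[classes.to_numpy() == name])
    return {
        name: (np.concatenate(parts) if parts else np.array([], dtype=float))
        for name, parts in pools.items()
    }


def fit_thresholds(
    logs: Sequence[KeystrokeLog],
    translator_id: str | None = None,
    superpause_multiplier: float = 5.0,
    min_count: int = 20,
    boundary_chars: frozenset[str] | set[str] = DEFAULT_BOUNDARY_CHARS,
    delay: float = DELAY_MS,
) -> TranslatorThresholds:
    """Fit RSP/TSP/superpause thresholds for one translator.

    All sessions of the translator are pooled before taking medians (the
    thresholds are a property of the translator, not of a session).  An
    even-length sample's median is the mean of the two middle values.  At
    least ``min_count`` WP and BP observations are required.  ``rsp >= tsp``
    is legal but loudly flagged with a warning, never silently accepted.
    """
    logs = list(logs)
    if translator_id is None:
        translator_id = logs[0].translator_id if logs else "unknown"
    samples = pause_samples(logs, boundary_chars)
    n_wp, n_bp, n_sp = (len(samples[k]) for k in ("WP", "BP", "SP"))
    if n_wp < min_count or n_bp < min_count:
        raise EstimationError(
            f"translator {translator_id}: need >= {min_count} WP and BP "
            f"observations, got n_wp={n_wp}, n_bp={n_bp}"
        )
    median_wp = float(np.median(samples["WP"]))
    median_bp = float(np.median(samples["BP"]))
    median_sp = float(np.median(samples["SP"])) if n_sp else float("nan")
    rsp = 2.0 * median_wp
    tsp = 3.0 * median_bp
    thresholds = TranslatorThresholds(
        translator_id=translator_id,
        median_wp=median_wp,
        median_bp=median_bp,
        rsp=rsp,
        tsp=tsp,
        delay=float(delay),
        superpause=superpause_multiplier * tsp,
        n_wp=n_wp,
        n_bp=n_bp,
        median_sp=median_sp,
        n_sp=n_sp,
    )
    if thresholds.degenerate:
        warnings.warn(
            f"translator {translator_id}: rsp ({rsp:.0f} ms) >= tsp ({tsp:.0f} ms); "
            "Task and Task Segment levels are not separated",
            stacklevel=2,
        )
    return thresholds


def thresholds_frame(thresholds: Iterable[TranslatorThresholds]) -> pd.DataFrame:
    """Tabulate fitted thresholds, one row per translator."""
    rows = [
        (
            t.translator_id,
            t.median_wp,
            t.median_bp,
            t.rsp,
            t.tsp,
            t.superpause,
            t.n_wp,
            t.n_bp,
        )
        for t in thresholds
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "translator_id",
            "median_wp",
            "median_bp",
            "rsp",
            "tsp",
            "superpause",
            "n_wp",
            "n_bp",
        ],
    )
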