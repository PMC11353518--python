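"""Model/Results interface over the keystroke-analysis pipeline.

``TaskSegmentModel`` is built from a cohort of keystroke logs (optionally
with HOF annotations); ``fit()`` estimates per-translator pause thresholds,
segments every session and returns a ``TaskSegmentResults`` carrying the
estimates and the derived tables:

>>> model = TaskSegmentModel(logs)
>>> res = model.fit()
>>> print(res.summary())
>>> res.ts_label_summary(top=10)
>>> res.recognition(alpha=0.05)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import pauses, profiles, segmentation, stats
from .errors import EstimationError, ValidationError
from .io import HOFAnnotation, KeystrokeLog, compute_ikis
from .pauses import DEFAULT_BOUNDARY_CHARS, TranslatorThresholds
from .segmentation import SegmentedLog


class TaskSegmentModel:
    """Pause-threshold and Task-Segment model of a keystroke-log cohort.

    Parameters
    ----------
    logs:
        One :class:`KeystrokeLog` per session.
    annotations:
        Optional HOF state intervals for (a subset of) the sessions.
    delay:
        Motor-program threshold in ms (fixed, not fitted).
    superpause_multiplier:
        Superpause threshold as a multiple of the fitted TSP.
    min_pause_count:
        Minimum pooled WP and BP observations per translator.
    boundary_chars:
        Word-boundary keystroke alphabet.
    """

    def __init__(
        self,
        logs: Sequence[KeystrokeLog],
        annotations: Sequence[HOFAnnotation] | None = None,
        *,
        delay: float = pauses.DELAY_MS,
        superpause_multiplier: float = 5.0,
        min_pause_count: int = 20,
        boundary_chars: frozenset[str] | set[str] = DEFAULT_BOUNDARY_CHARS,
    ) -> None:
        logs = list(logs)
        if not logs:
            raise ValidationError("TaskSegmentModel needs at least one session")
        seen: set[str] = set()
        for log in logs:
            if log.session_id in seen:
                raise ValidationError(f"duplicate session_id {log.session_id!r}")
            seen.add(log.session_id)
        self.logs = logs
        self.annotations = list(annotations) if annotations else []
        self.delay = float(delay)
        self.superpause_multiplier = float(superpause_multiplier)
        self.min_pause_count = int(min_pause_count)
        self.boundary_chars = frozenset(boundary_chars)

    @classmethod
    def from_dataframe(
        cls,
        events: pd.DataFrame,
        annotations: Sequence[HOFAnnotation] | None = None,
        **kwargs,
    ) -> "TaskSegmentModel":
        """Build a model from a canonical event table (may mix sessions)."""
        if "session_id" not in events.columns:
            raise ValidationError("event table needs a session_id column")
        logs = [
            KeystrokeLog(sub) for _, sub in events.groupby("session_id", sort=False)
        ]
        return cls(logs, annotations, **kwargs)

    def fit(self) -> "TaskSegmentResults":
        """Fit thresholds per translator and segment every session."""
        by_translator: dict[str, list[KeystrokeLog]] = {}
        for log in self.logs:
            by_translator.setdefault(log.translator_id, []).append(log)
        thresholds: dict[str, TranslatorThresholds] = {}
        for translator, logs in by_translator.items():
            thresholds[translator] = pauses.fit_thresholds(
                logs,
                translator_id=translator,
                superpause_multiplier=self.superpause_multiplier,
                min_count=self.min_pause_count,
                boundary_chars=self.boundary_chars,
                delay=self.delay,
            )
        segmented = {
            log.session_id: segmentation.segment(
                log, thresholds[log.translator_id]
            )
            for log in self.logs
        }
        return TaskSegmentResults(self, thresholds, segmented)


@dataclass
class TaskSegmentResults:
    """Fitted thresholds plus the segmentations and tables derived from them."""

    model: TaskSegmentModel
    thresholds: dict[str, TranslatorThresholds]
    segmented: dict[str, SegmentedLog] = field(repr=False)

    # -- estimates --------------------------------------------------------
    @property
    def thresholds_frame(self) -> pd.DataFrame:
        return pauses.thresholds_frame(self.thresholds.values())

    def iki_sample(self, session_id: str) -> profiles.IKISample:
        """A session's IKI sample for distribution-level profiling."""
        seg = self.segmented[session_id]
        return profiles.IKISample(
            session_id, compute_ikis(seg.log).to_numpy(dtype=float)
        )

    # -- tables -----------------------------------------------------------
    def ts_label_summary(
        self, groupby: str = "group", top: int | None = None
    ) -> pd.DataFrame:
        return stats.summarize_ts_labels(
            list(self.segmented.values()), groupby=groupby, top=top
        )

    def hof_transition_matrix(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        self._require_annotations()
        return stats.hof_transition_matrix(self.model.annotations)

    def hof_state_stats(self) -> stats.HOFStatsResult:
        self._require_annotations()
        return stats.hof_state_stats(
            list(self.segmented.values()), self.model.annotations
        )

    def task_distribution_by_state(self) -> pd.DataFrame:
        self._require_annotations()
        return stats.task_distribution_by_state(
            list(self.segmented.values()), self.model.annotations
        )

    def _require_annotations(self) -> None:
        if not self.model.annotations:
            raise EstimationError("no HOF annotations were supplied to the model")

    # -- profiling --------------------------------------------------------
    def recognition(
        self, alpha: float = 0.05, min_iki_count: int = 1
    ) -> profiles.RecognitionResult:
        """Same/different-translator recognition from pairwise KS2 tests."""
        samples = {
            sid: self.iki_sample(sid) for sid in self.segmented
        }
        translator_of = {
            sid: seg.log.translator_id for sid, seg in self.segmented.items()
        }
        return profiles.recognition_rates(
            samples, translator_of, alpha=alpha, min_iki_count=min_iki_count
        )

    def rsp_tsp_correlation(self) -> tuple[float, float] | None:
        """Spearman correlation of fitted RSP vs TSP across translators."""
        return profiles.rsp_tsp_correlation(list(self.thresholds.values()))

    # -- presentation -----------------------------------------------------
    def summary(self) -> str:
        """Human-readable overview of the fit."""
        tf = self.thresholds_frame
        n_sessions = len(self.segmented)
        n_events = sum(len(s) for s in self.segmented.values())
        n_ts = sum(len(s.task_segments) for s in self.segmented.values())
        n_tasks = sum(len(s.tasks) for s in self.segmented.values())
        lines = [
            "Task Segment model",
            "==================",
            f"sessions: {n_sessions}   translators: {len(tf)}   "
            f"keystrokes: {n_events}",
            f"task segments: {n_ts}   tasks: {n_tasks}   "
            f"delay: {self.model.delay:.0f} ms",
            "",
            "Per-translator thresholds (ms)",
            tf.to_string(index=False, float_format=lambda v: f"{v:.1f}"),
        ]
        corr = None
        if len(tf) >= 3:
            try:
                corr = self.rsp_tsp_correlation()
            except EstimationError:
                corr = None
        if corr is not None:
            lines += ["", f"RSP-TSP Spearman rho: {corr[0]:.2f} (p={corr[1]:.3g})"]
        degenerate = [t.translator_id for t in self.thresholds.values() if t.degenerate]
        if degenerate:
            lines += ["", f"WARNING: rsp >= tsp for translators {degenerate}"]
        return "\n".join(lines)

    def plot_iki_distributions(self, ax=None, bins: int = 60, log_x: bool = True):
        """Overlay per-translator IKI densities (the pausing fingerprint)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        by_translator: dict[str, list[np.ndarray]] = {}
        for sid, seg in self.segmented.items():
            if len(seg.log) < 2:
                continue
            by_translator.setdefault(seg.log.translator_id, []).append(
                compute_ikis(seg.log).to_numpy(dtype=float)
            )
        for translator, parts in sorted(by_translator.items()):
            values = np.concatenate(parts)
            values = values[values > 0]
            data = np.log10(values) if log_x else values
            ax.hist(data, bins=bins, density=True, histtype="step", label=translator)
        ax.set_xlabel("log10 IKI (ms)" if log_x else "IKI (ms)")
        ax.set_ylabel("density")
        ax.legend(fontsize="small")
        return ax
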