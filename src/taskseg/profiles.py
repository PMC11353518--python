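"""Distribution-level translator profiling.

Each translator leaves a personal fingerprint in the distribution of their
inter-keystroke intervals.  This module compares session-level IKI samples
with the two-sample Kolmogorov–Smirnov test: two sessions of the *same*
translator should look like draws from one population (KS p >= alpha),
sessions of *different* translators like draws from different populations
(p < alpha).  It also relates the fitted RSP and TSP thresholds across a
group of translators via Spearman rank correlation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import EstimationError
from .pauses import TranslatorThresholds


@dataclass(frozen=True)
class IKISample:
    """A session's (or translator's) IKI sample in milliseconds."""

    owner: str
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or len(values) == 0:
            raise EstimationError(f"IKI sample {self.owner!r} is empty")
        if (values < 0).any():
            raise ValueError(f"IKI sample {self.owner!r} has negative values")
        object.__setattr__(self, "values", values)

    @property
    def n(self) -> int:
        return len(self.values)


def ks2_pair(
    sample_a: IKISample | np.ndarray, sample_b: IKISample | np.ndarray
) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov test between two IKI samples.

    Returns ``(D, p)`` where D is the supremum distance between the two
    empirical CDFs and p comes from the asymptotic two-sample KS
    distribution.  Symmetric in its arguments; empty samples are an error.
    """
    a = sample_a.values if isinstance(sample_a, IKISample) else np.asarray(sample_a)
    b = sample_b.values if isinstance(sample_b, IKISample) else np.asarray(sample_b)
    if len(a) == 0 or len(b) == 0:
        raise EstimationError("KS2 requires two non-empty samples")
    res = sps.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


@dataclass
class RecognitionResult:
    """Same/different-translator recognition rates from pairwise KS2 tests.

    * ``same_recognized_rate``: fraction of same-translator session pairs
      with p >= alpha (correctly *not* rejected as one population);
    * ``diff_recognized_rate``: fraction of different-translator pairs with
      p < alpha.  Either rate is ``None`` when no such pairs exist.
    """

    alpha: float
    n_same_pairs: int
    n_diff_pairs: int
    same_recognized_rate: float | None
    diff_recognized_rate: float | None
    pairs: pd.DataFrame = field(repr=False)


def recognition_rates(
    sessions: Mapping[str, IKISample] | Sequence[IKISample],
    translator_of: Mapping[str, str] | None = None,
    alpha: float = 0.05,
    min_iki_count: int = 1,
) -> RecognitionResult:
    """Run KS2 over all unordered session pairs and score recognition.

    ``sessions`` maps session ids to IKI samples (or is a sequence of
    samples whose ``owner`` is the session id); ``translator_of`` maps
    session id to translator id and defaults to ``owner`` itself (useful
    when samples are already keyed by translator).  Sessions with fewer
    than ``min_iki_count`` IKIs are dropped.
    """
    if not isinstance(sessions, Mapping):
        sessions = {s.owner: s for s in sessions}
    if translator_of is None:
        translator_of = {sid: s.owner for sid, s in sessions.items()}
    kept = {sid: s for sid, s in sessions.items() if s.n >= min_iki_count}
    if len(kept) < 2:
        raise EstimationError("recognition requires at least two usable sessions")
    if len({translator_of[sid] for sid in kept}) < 2:
        raise EstimationError("recognition requires at least two translators")
    rows = []
    for (sid_a, a), (sid_b, b) in itertools.combinations(kept.items(), 2):
        d, p = ks2_pair(a, b)
        same = translator_of[sid_a] == translator_of[sid_b]
        rows.append((sid_a, sid_b, same, d, p))
    pairs = pd.DataFrame(
        rows, columns=["session_a", "session_b", "same_translator", "D", "p"]
    )
    same_pairs = pairs[pairs["same_translator"]]
    diff_pairs = pairs[~pairs["same_translator"]]
    same_rate = (
        float((same_pairs["p"] >= alpha).mean()) if len(same_pairs) else None
    )
    diff_rate = float((diff_pairs["p"] < alpha).mean()) if len(diff_pairs) else None
    return RecognitionResult(
        alpha=alpha,
        n_same_pairs=len(same_pairs),
        n_diff_pairs=len(diff_pairs),
        same_recognized_rate=same_rate,
        diff_recognized_rate=diff_rate,
        pairs=pairs,
    )


#: Largest n for which the Spearman p-value is computed by exact enumeration
#: of all pairings (9! = 362,880 permutations).
EXACT_PERMUTATION_MAX_N = 9


def rsp_tsp_correlation(
    thresholds: Sequence[TranslatorThresholds],
) -> tuple[float, float] | None:
    """Spearman rank correlation between per-translator RSP and TSP.

    Midranks handle ties.  For n <= 9 the two-sided p-value is computed by
    exact enumeration over all pairings; for larger n the usual asymptotic
    approximation is used.  Returns ``None`` when either vector is constant
    (the correlation is undefined); requires at least three translators.
    """
    if len(thresholds) < 3:
        raise EstimationError(
            f"RSP-TSP correlation requires >= 3 translators, got {len(thresholds)}"
        )
    rsp = np.array([t.rsp for t in thresholds], dtype=float)
    tsp = np.array([t.tsp for t in thresholds], dtype=float)
    if np.ptp(rsp) == 0 or np.ptp(tsp) == 0:
        return None
    n = len(rsp)
    if n <= EXACT_PERMUTATION_MAX_N:
        def statistic(y):
            return sps.spearmanr(rsp, y).statistic

        res = sps.permutation_test(
            (tsp,),
            statistic,
            permutation_type="pairings",
            alternative="two-sided",
            n_resamples=math.factorial(n),
        )
        rho, p = float(statistic(tsp)), float(res.pvalue)
    else:
        out = sps.spearmanr(rsp, tsp)
        rho, p = float(out.statistic), float(out.pvalue)
    return rho, p
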