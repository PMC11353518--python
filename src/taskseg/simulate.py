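"""Seeded hierarchical keystroke-log generator.

The generator instantiates a three-layer architecture of translation
production:

* **phenomenal layer** — a first-order Markov chain over the HOF states
  (Orientation, Flow, Hesitation) with no self-transitions;
* **cognitive layer** — each Flow/Hesitation visit emits one or more Task
  Segments separated by pauses in the Task-Segment-Pause band, with
  state-specific burst sizes; Orientation emits a superpause-scale silence
  and no keystrokes (it models first-pass reading);
* **sensorimotor layer** — each Task Segment is a run of Tasks separated by
  Respite-band pauses; each Task types characters of a synthetic word
  stream with lognormal within-word and between-word IKIs, or deletes
  previously typed characters (D/C Tasks backspace in reverse order).

The primitive timing parameters are *pause ranges*, not thresholds, so the
emitted ground truth is independent of the estimators under test.  The
within/between-word lognormals are truncated below ``iki_cap`` and
calibrated so the truncated law has exactly the configured median; with the
default margins (cap < respite band < TSP band < superpause) the fitted
thresholds separate the bands and segmentation recovers the generated
boundaries exactly.

Everything is reproducible from the config seed; cohorts derive per-session
seeds from a master seed via ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .errors import ConfigurationError
from .io import HOF_STATES, HOFAnnotation, KeystrokeLog

#: Default phenomenal-state transition matrix (row/column order O, F, H):
#: Orientation mostly resolves into Flow, Flow alternates with Orientation,
#: Hesitation almost always recovers into Flow.
DEFAULT_TRANSITIONS = (
    (0.00, 0.86, 0.14),
    (0.60, 0.00, 0.40),
    (0.09, 0.91, 0.00),
)

_LETTERS = np.array(list("abcdefghijklmnopqrstuvwxyz"))


def _as_matrix(m) -> np.ndarray:
    a = np.asarray(m, dtype=float)
    if a.shape != (3, 3):
        raise ConfigurationError(f"transition matrix must be 3x3, got {a.shape}")
    return a


@dataclass
class GeneratorConfig:
    """Full parameterization of one synthetic translator.

    Timing units are milliseconds.  ``state_transitions`` follows the fixed
    O, F, H order with a structurally zero diagonal.  Per-state parameters
    are keyed by ``"F"``/``"H"`` (Orientation types nothing).  The pause
    geometry must satisfy

        iki_cap <= respite_range[0] <= respite_range[1]
                <= tsp_range[0] <= tsp_range[1] <= superpause_min

    so that the four pause populations occupy disjoint bands; the exposed
    ``rsp_true``/``tsp_true``/``superpause_true`` are the band lower edges.
    """

    translator_id: str = "T01"
    study_id: str = "SYN"
    group: str = "es"
    seed: int = 0
    n_states: int = 30
    state_transitions: tuple = DEFAULT_TRANSITIONS
    initial_state: tuple = (1.0, 0.0, 0.0)
    # cognitive layer: burst composition per phenomenal state
    ts_per_state: Mapping[str, float] = field(
        default_factory=lambda: {"F": 2.10, "H": 1.95}
    )
    tasks_per_ts: Mapping[str, float] = field(
        default_factory=lambda: {"F": 2.20, "H": 1.15}
    )
    keys_per_task: Mapping[str, float] = field(
        default_factory=lambda: {"F": 5.47, "H": 1.34}
    )
    label_mixture: Mapping[str, tuple] = field(
        default_factory=lambda: {"F": (0.81, 0.08, 0.11), "H": (0.53, 0.41, 0.06)}
    )
    # sensorimotor layer: IKI model
    median_wp: float = 140.0
    sigma_wp: float = 0.45
    median_bp: float = 203.0
    sigma_bp: float = 0.45
    iki_cap: float = 270.0
    respite_range: tuple = (330.0, 550.0)
    tsp_range: tuple = (700.0, 2800.0)
    superpause_min: float = 3000.0
    o_pause_mean: float = 4838.0
    # text model
    word_length_mean: float = 5.0
    segment_words: int = 10
    boundary_char: str = "_"

    def __post_init__(self) -> None:
        self.state_transitions = tuple(
            tuple(row) for row in _as_matrix(self.state_transitions)
        )
        m = _as_matrix(self.state_transitions)
        if not np.allclose(np.diag(m), 0.0):
            raise ConfigurationError("transition matrix diagonal must be zero")
        if not np.allclose(m.sum(axis=1), 1.0):
            raise ConfigurationError("transition matrix rows must sum to 1")
        init = np.asarray(self.initial_state, dtype=float)
        if init.shape != (3,) or not math.isclose(init.sum(), 1.0, rel_tol=1e-9):
            raise ConfigurationError("initial_state must be a distribution over O,F,H")
        for state, mix in self.label_mixture.items():
            mix = tuple(float(x) for x in mix)
            if len(mix) != 3 or any(x < 0 for x in mix) or not math.isclose(
                sum(mix), 1.0, rel_tol=1e-9
            ):
                raise ConfigurationError(
                    f"label mixture for state {state} must be 3 probabilities summing to 1"
                )
        if self.sigma_wp <= 0 or self.sigma_bp <= 0:
            raise ConfigurationError("IKI dispersions must be positive")
        lo_r, hi_r = self.respite_range
        lo_t, hi_t = self.tsp_range
        ordered = (
            0
            < self.iki_cap
            <= lo_r
            <= hi_r
            <= lo_t
            <= hi_t
            <= self.superpause_min
        )
        if not ordered:
            raise ConfigurationError(
                "pause bands must be ordered: iki_cap <= respite <= tsp <= superpause"
            )
        if not (self.median_wp < self.iki_cap and self.median_bp < self.iki_cap):
            raise ConfigurationError("IKI medians must lie below iki_cap")
        if self.o_pause_mean <= self.superpause_min:
            raise ConfigurationError("o_pause_mean must exceed superpause_min")
        if self.word_length_mean < 1 or self.segment_words < 1:
            raise ConfigurationError("text model parameters must be >= 1")
        self._mu_wp = _calibrate_mu(self.median_wp, self.sigma_wp, self.iki_cap)
        self._mu_bp = _calibrate_mu(self.median_bp, self.sigma_bp, self.iki_cap)

    # exposed band edges (the paper-facing threshold semantics)
    @property
    def rsp_true(self) -> float:
        return float(self.respite_range[0])

    @property
    def tsp_true(self) -> float:
        return float(self.tsp_range[0])

    @property
    def superpause_true(self) -> float:
        return float(self.superpause_min)

    def to_mapping(self) -> dict:
        d = asdict(self)
        d.pop("_mu_wp", None)
        d.pop("_mu_bp", None)
        return d

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "GeneratorConfig":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in mapping.items() if k in known})


def _calibrate_mu(median: float, sigma: float, cap: float) -> float:
    """Log-scale such that the lognormal truncated at ``cap`` has ``median``.

    Solves Phi((ln m - mu)/s) = Phi((ln c - mu)/s) / 2 for mu; truncation
    removes upper-tail mass, so the root lies above ln(median).
    """
    lm, lc = math.log(median), math.log(cap)

    def f(mu: float) -> float:
        return norm.cdf((lm - mu) / sigma) - 0.5 * norm.cdf((lc - mu) / sigma)

    return float(brentq(f, lm, lm + 12.0 * sigma, xtol=1e-10))


class _TruncatedLognormal:
    """Vectorized inverse-CDF sampler for a lognormal truncated at ``cap``."""

    def __init__(self, mu: float, sigma: float, cap: float):
        self.mu, self.sigma = mu, sigma
        self.u_max = float(norm.cdf((math.log(cap) - mu) / sigma))

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        u = rng.uniform(0.0, self.u_max, size)
        return np.exp(self.mu + self.sigma * norm.ppf(u))


class _Pool:
    """Buffered draws so per-keystroke sampling stays vectorized."""

    def __init__(self, sampler: _TruncatedLognormal, rng: np.random.Generator):
        self.sampler, self.rng = sampler, rng
        self.buf = np.array([])
        self.i = 0

    def next(self) -> float:
        if self.i >= len(self.buf):
            self.buf = self.sampler.draw(self.rng, 1024)
            self.i = 0
        v = self.buf[self.i]
        self.i += 1
        return float(v)


@dataclass
class GroundTruth:
    """Generator-side truth emitted alongside a synthetic log."""

    annotations: list[HOFAnnotation]
    state_sequence: list[str]
    task_start_indices: np.ndarray
    ts_start_indices: np.ndarray
    task_labels: list[str]
    config: GeneratorConfig

    @property
    def true_thresholds(self) -> dict[str, float]:
        c = self.config
        return {
            "rsp_true": c.rsp_true,
            "tsp_true": c.tsp_true,
            "superpause_true": c.superpause_true,
        }


def sample_states(
    config: GeneratorConfig, n: int, rng: np.random.Generator | None = None
) -> list[str]:
    """Sample a phenomenal HOF state sequence of length ``n`` from the chain."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    m = _as_matrix(config.state_transitions)
    states = [int(rng.choice(3, p=np.asarray(config.initial_state, dtype=float)))]
    # pre-draw uniforms and invert the per-row CDFs
    cdf = np.cumsum(m, axis=1)
    u = rng.uniform(size=n - 1)
    for k in range(n - 1):
        states.append(int(np.searchsorted(cdf[states[-1]], u[k], side="right")))
    return [HOF_STATES[s] for s in states]


class _WordStream:
    """Synthetic text source: "_"-led words of random length, a new source
    segment every ``segment_words`` completed words.

    Words are emitted as ``"_"`` followed by their letters, and every Task
    opens a fresh word (typists pause *between* words: the structural pause
    preceding a Task then falls on the boundary keystroke, whose IKI is
    unclassified, leaving the WP/BP samples clean).  A Task ending mid-word
    simply abandons the fragment.
    """

    def __init__(self, config: GeneratorConfig, rng: np.random.Generator):
        self.rng = rng
        self.config = config
        self.segment_index = 0
        self.words_done = 0
        self.pos = 0  # 0 = boundary pending, else next letter position
        self.word_len = self._new_len()

    def _new_len(self) -> int:
        return 1 + int(self.rng.poisson(self.config.word_length_mean - 1.0))

    def start_word(self) -> None:
        if self.pos != 0:  # abandon the unfinished word
            self.pos = 0
            self.word_len = self._new_len()

    def next_char(self) -> tuple[str, str]:
        """Return (char, iki_class) with iki_class in {"wp", "bp"}."""
        if self.pos == 0:
            self.pos = 1
            return self.config.boundary_char, "wp"
        cls = "bp" if self.pos == 1 else "wp"
        self.pos += 1
        if self.pos > self.word_len:  # word complete
            self.words_done += 1
            if self.words_done % self.config.segment_words == 0:
                self.segment_index += 1
            self.pos = 0
            self.word_len = self._new_len()
        return str(self.rng.choice(_LETTERS)), cls


def generate_session(
    config: GeneratorConfig,
    session_id: str | None = None,
    rng: np.random.Generator | None = None,
    n_states: int | None = None,
    min_keystrokes: int | None = None,
) -> tuple[KeystrokeLog, GroundTruth]:
    """Generate one synthetic translation session plus its ground truth.

    The HOF chain runs for ``n_states`` visits (or until ``min_keystrokes``
    keystrokes have been produced, whichever is longer).  Fully reproducible
    from ``config.seed`` (or an explicit ``rng``).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if session_id is None:
        session_id = f"{config.translator_id}_s1"
    n_states = n_states if n_states is not None else config.n_states

    wp_pool = _Pool(
        _TruncatedLognormal(config._mu_wp, config.sigma_wp, config.iki_cap), rng
    )
    bp_pool = _Pool(
        _TruncatedLognormal(config._mu_bp, config.sigma_bp, config.iki_cap), rng
    )
    words = _WordStream(config, rng)
    mixtures = {s: np.asarray(config.label_mixture[s], float) for s in ("F", "H")}

    times: list[int] = []
    chars: list[str] = []
    ops: list[str] = []
    segs: list[int] = []
    typed: list[str] = []

    clock = 0
    pending: float | None = None  # structural pause preceding the next event
    annotations: list[tuple[int, int, str]] = []
    prev_ann_end: int | None = None
    state_seq: list[str] = []
    task_starts: list[int] = []
    ts_starts: list[int] = []
    task_labels: list[str] = []

    def emit(char: str, op: str, iki: float | None) -> None:
        nonlocal clock
        if times:
            clock += max(1, int(round(iki if iki is not None else 0.0)))
        elif iki is not None:
            clock += int(round(iki))  # offset of the session's first keystroke
        times.append(clock)
        chars.append(char)
        ops.append(op)
        segs.append(words.segment_index)

    def take_pending(default_pool: _Pool) -> float:
        nonlocal pending
        if pending is not None:
            value, pending = pending, None
            return value
        return default_pool.next()

    def emit_task(state: str) -> None:
        lab = ("A", "D", "C")[int(rng.choice(3, p=mixtures[state]))]
        n_keys = 1 + int(rng.poisson(max(config.keys_per_task[state] - 1.0, 0.0)))
        if lab == "C":
            n_keys = max(2, n_keys)
        if lab in ("D", "C") and not typed:
            lab = "A"  # nothing typed yet to delete
        task_starts.append(len(times))
        if lab == "A":
            n_ins, n_del = n_keys, 0
        elif lab == "D":
            n_ins, n_del = 0, min(n_keys, len(typed))
        else:
            n_ins = max(1, n_keys - max(1, n_keys // 3))
            n_del = n_keys - n_ins
        if n_ins:
            words.start_word()  # inserting Tasks open at a word boundary
        for _ in range(n_ins):
            char, cls = words.next_char()
            pool = bp_pool if cls == "bp" else wp_pool
            emit(char, "insert", take_pending(pool))
            typed.append(char)
        for _ in range(n_del):
            emit(typed.pop(), "delete", take_pending(wp_pool))
        task_labels.append(lab)

    transitions = _as_matrix(config.state_transitions)
    state_seq.extend(sample_states(config, n_states, rng))
    visits = 0
    while visits < n_states or (
        min_keystrokes is not None and len(times) < min_keystrokes
    ):
        if visits >= len(state_seq):  # extend the chain beyond n_states
            prev = HOF_STATES.index(state_seq[-1])
            state_seq.append(HOF_STATES[int(rng.choice(3, p=transitions[prev]))])
        state = state_seq[visits]
        visits += 1
        if state == "O":
            o_dur = config.superpause_min + rng.exponential(
                config.o_pause_mean - config.superpause_min
            )
            start = clock + 1 if times else 0
            end = int(round(start + o_dur))
            annotations.append((start, end, "O"))
            pending = (end + 1) - clock
            prev_ann_end = end
            continue
        visit_start = prev_ann_end + 1 if prev_ann_end is not None else 0
        n_ts = 1 + int(rng.poisson(config.ts_per_state[state] - 1.0))
        for _ in range(n_ts):
            if times and pending is None:
                pending = rng.uniform(*config.tsp_range)
            ts_starts.append(len(times))
            n_tasks = 1 + int(rng.poisson(config.tasks_per_ts[state] - 1.0))
            for j in range(n_tasks):
                if j > 0:
                    pending = rng.uniform(*config.respite_range)
                emit_task(state)
        end = max(clock, visit_start + 1)
        annotations.append((visit_start, end, state))
        prev_ann_end = end

    events = pd.DataFrame(
        {
            "session_id": session_id,
            "translator_id": config.translator_id,
            "study_id": config.study_id,
            "group": config.group,
            "time": times,
            "char": chars,
            "op": ops,
            "segment_index": segs,
        }
    )
    log = KeystrokeLog(events)
    truth = GroundTruth(
        annotations=[
            HOFAnnotation(session_id, s, e, st) for s, e, st in annotations
        ],
        state_sequence=state_seq[: visits],
        task_start_indices=np.asarray(task_starts, dtype=int),
        ts_start_indices=np.asarray(ts_starts, dtype=int),
        task_labels=task_labels,
        config=config,
    )
    return log, truth


def generate_cohort(
    configs: Sequence[GeneratorConfig],
    n_sessions_per_translator: int,
    master_seed: int,
    n_states: int | None = None,
    min_keystrokes: int | None = None,
) -> tuple[list[tuple[KeystrokeLog, GroundTruth]], pd.DataFrame]:
    """Generate a cohort of sessions with deterministic per-session seeds.

    Returns the list of ``(log, ground_truth)`` pairs and a metadata table
    (session_id, translator_id, group, seed used, event count).
    """
    if not configs:
        raise ConfigurationError("generate_cohort needs at least one config")
    root = np.random.SeedSequence(master_seed)
    children = root.spawn(len(configs) * n_sessions_per_translator)
    sessions = []
    meta_rows = []
    k = 0
    for config in configs:
        for j in range(n_sessions_per_translator):
            rng = np.random.default_rng(children[k])
            session_id = f"{config.translator_id}_s{j + 1}"
            log, truth = generate_session(
                config,
                session_id=session_id,
                rng=rng,
                n_states=n_states,
                min_keystrokes=min_keystrokes,
            )
            sessions.append((log, truth))
            meta_rows.append(
                (
                    session_id,
                    config.translator_id,
                    config.group,
                    children[k].entropy,
                    len(log),
                )
            )
            k += 1
    meta = pd.DataFrame(
        meta_rows,
        columns=["session_id", "translator_id", "group", "master_entropy", "n_events"],
    )
    return sessions, meta
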