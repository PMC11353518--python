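"""Generator contracts: reproducibility, ground truth, parameter recovery."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from taskseg.errors import ConfigurationError
from taskseg.io import compute_ikis, validate_annotations
from taskseg.pauses import fit_thresholds
from taskseg.segmentation import segment
from taskseg.simulate import (
    GeneratorConfig,
    generate_cohort,
    generate_session,
    sample_states,
)


def test_same_seed_identical_logs():
    a, ta = generate_session(GeneratorConfig(seed=21), n_states=15)
    b, tb = generate_session(GeneratorConfig(seed=21), n_states=15)
    pd.testing.assert_frame_equal(a.events, b.events)
    assert ta.annotations == tb.annotations
    assert ta.task_labels == tb.task_labels


def test_different_seeds_differ():
    a, _ = generate_session(GeneratorConfig(seed=1), n_states=15)
    b, _ = generate_session(GeneratorConfig(seed=2), n_states=15)
    assert not a.events.equals(b.events)


def test_pure_insertion_mixture_forces_a_labels():
    cfg = GeneratorConfig(
        seed=3,
        label_mixture={"F": (1.0, 0.0, 0.0), "H": (1.0, 0.0, 0.0)},
    )
    log, truth = generate_session(cfg, n_states=20)
    assert set(truth.task_labels) == {"A"}
    assert (log.events["op"] == "insert").all()


def test_ground_truth_aligns_with_log():
    log, truth = generate_session(GeneratorConfig(seed=4), n_states=40)
    n = len(log)
    # boundaries point at real events, segments nest inside tasks
    assert truth.task_start_indices[0] == 0
    assert truth.ts_start_indices[0] == 0
    assert truth.task_start_indices.max() < n
    assert set(truth.ts_start_indices) <= set(truth.task_start_indices)
    assert len(truth.task_labels) == len(truth.task_start_indices)
    # annotations are valid, ordered and cover every keystroke
    validate_annotations(truth.annotations)
    times = log.times
    starts = np.array([a.start for a in truth.annotations])
    ends = np.array([a.end for a in truth.annotations])
    idx = np.searchsorted(starts, times, side="right") - 1
    assert (idx >= 0).all()
    assert (times <= ends[idx]).all()
    # Orientation intervals contain no keystrokes
    for k, ann in enumerate(truth.annotations):
        if ann.state == "O":
            assert not ((idx == k).any())


def test_timestamps_strictly_increase_after_first():
    log, _ = generate_session(GeneratorConfig(seed=6), n_states=30)
    assert (np.diff(log.times) >= 1).all()


def test_invalid_configs_rejected():
    with pytest.raises(ConfigurationError, match="diagonal"):
        GeneratorConfig(state_transitions=((0.5, 0.4, 0.1),) * 3)
    with pytest.raises(ConfigurationError, match="bands"):
        GeneratorConfig(respite_range=(800.0, 900.0), tsp_range=(700.0, 2800.0))
    with pytest.raises(ConfigurationError, match="mixture"):
        GeneratorConfig(label_mixture={"F": (0.5, 0.5, 0.5), "H": (1, 0, 0)})


def test_cohort_ids_and_determinism():
    cfgs = [
        GeneratorConfig(translator_id="P01"),
        GeneratorConfig(translator_id="P02"),
    ]
    sessions, meta = generate_cohort(cfgs, 2, master_seed=5, n_states=10)
    assert meta["session_id"].tolist() == [
        "P01_s1",
        "P01_s2",
        "P02_s1",
        "P02_s2",
    ]
    assert meta["session_id"].is_unique
    again, _ = generate_cohort(cfgs, 2, master_seed=5, n_states=10)
    pd.testing.assert_frame_equal(sessions[3][0].events, again[3][0].events)


def test_parameter_recovery_at_10k_keystrokes():
    """The fitted WP/BP medians recover the configured timing medians."""
    cfg = GeneratorConfig(seed=11)
    log, _ = generate_session(cfg, min_keystrokes=10_000)
    th = fit_thresholds([log])
    assert th.median_wp == pytest.approx(cfg.median_wp, rel=0.05)
    assert th.median_bp == pytest.approx(cfg.median_bp, rel=0.05)


def test_fitted_thresholds_bracket_pause_bands():
    """rsp lands between the capped IKI law and the Respite band; tsp
    between the Respite and TSP bands."""
    cfg = GeneratorConfig(seed=12)
    log, _ = generate_session(cfg, min_keystrokes=10_000)
    th = fit_thresholds([log])
    assert cfg.iki_cap < th.rsp < cfg.respite_range[0]
    assert cfg.respite_range[1] < th.tsp < cfg.tsp_range[0]


def test_segmentation_recovers_true_boundaries():
    """In the well-separated default regime the pipeline reproduces the
    generated Task and Task Segment boundaries exactly (F1 = 1)."""
    cfg = GeneratorConfig(seed=13)
    log, truth = generate_session(cfg, min_keystrokes=8_000)
    th = fit_thresholds([log])
    seg = segment(log, th)
    assert [t.start for t in seg.tasks] == truth.task_start_indices.tolist()
    assert [s.start for s in seg.task_segments] == truth.ts_start_indices.tolist()


def test_structural_pauses_respect_bands():
    cfg = GeneratorConfig(seed=14)
    log, truth = generate_session(cfg, n_states=60)
    ikis = compute_ikis(log).to_numpy()
    task_starts = set(truth.task_start_indices.tolist())
    ts_starts = set(truth.ts_start_indices.tolist())
    for i, iki in zip(range(1, len(log)), ikis):
        if i in ts_starts:
            assert iki >= cfg.tsp_range[0]
        elif i in task_starts:
            assert cfg.respite_range[0] <= iki < cfg.respite_range[1] + 1
        else:
            assert iki <= cfg.iki_cap


def test_state_chain_matches_transition_matrix():
    cfg = GeneratorConfig(seed=15)
    rng = np.random.default_rng(15)
    states = sample_states(cfg, 40_000, rng)
    m = np.asarray(cfg.state_transitions)
    order = {"O": 0, "F": 1, "H": 2}
    counts = np.zeros((3, 3))
    for a, b in zip(states, states[1:]):
        counts[order[a], order[b]] += 1
    est = counts / counts.sum(axis=1, keepdims=True)
    assert np.abs(est - m).max() < 0.02


def test_keys_per_ts_ordering_flow_above_hesitation():
    """Flow bursts are larger than Hesitation bursts, per the per-state
    burst parameters."""
    cfg = GeneratorConfig(seed=16)
    log, truth = generate_session(cfg, min_keystrokes=4_000)
    from taskseg.stats import hof_state_stats

    th = fit_thresholds([log])
    seg = segment(log, th)
    result = hof_state_stats([seg], truth.annotations)
    key_ts = result.table[("key_ts", "mean")]
    assert key_ts["F"] > key_ts["H"]


def test_config_round_trips_through_mapping():
    cfg = GeneratorConfig(seed=17, median_wp=150.0)
    again = GeneratorConfig.from_mapping(cfg.to_mapping())
    assert again == cfg
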