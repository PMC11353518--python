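"""Hierarchical segmentation: examples, oracle equivalence, invariants."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from taskseg.errors import ConfigurationError
from taskseg.io import KeystrokeLog
from taskseg.pauses import TranslatorThresholds
from taskseg.segmentation import segment, translation_units


def make_thresholds(rsp=300.0, tsp=900.0, delay=200.0):
    return TranslatorThresholds(
        translator_id="t1",
        median_wp=rsp / 2,
        median_bp=tsp / 3,
        rsp=rsp,
        tsp=tsp,
        delay=delay,
        superpause=5 * tsp,
        n_wp=100,
        n_bp=100,
    )


def log_from_ikis(make_log, ikis, **kwargs):
    times = np.r_[0, np.cumsum(ikis)].astype(int)
    return make_log(times.tolist(), **kwargs)


def oracle_units(times, threshold):
    """Brute-force unit partition: walk every adjacent pair independently."""
    units = [[0]]
    for i in range(1, len(times)):
        if times[i] - times[i - 1] >= threshold:
            units.append([])
        units[-1].append(i)
    return units


def assert_matches_oracle(seg, times, thresholds):
    mp_cutoff = max(thresholds.delay, thresholds.rsp) if thresholds.delay >= thresholds.rsp else thresholds.delay
    for ids, cutoff in [
        (seg.ts_ids, thresholds.tsp),
        (seg.task_ids, thresholds.rsp),
        (seg.mp_ids, mp_cutoff),
    ]:
        expect = oracle_units(times, cutoff)
        got = [list(np.flatnonzero(ids == k)) for k in range(ids.max() + 1)]
        assert got == expect


def test_toy_example_two_segments(make_log):
    """IKIs [100, 350, 100, 1000, 100] with rsp=300/tsp=900: the 1000 ms
    pause opens a second Task Segment, the 350 ms Respite a second Task."""
    log = log_from_ikis(make_log, [100, 350, 100, 1000, 100])
    seg = segment(log, make_thresholds())
    assert len(seg.task_segments) == 2
    first, second = seg.task_segments
    assert len(seg.tasks_of(first)) == 2
    assert len(seg.tasks_of(second)) == 1
    assert (first.start, first.end) == (0, 3)
    assert (second.start, second.end) == (4, 5)


def test_all_fast_ikis_single_units(make_log):
    log = log_from_ikis(make_log, [100] * 7)
    seg = segment(log, make_thresholds())
    assert len(seg.task_segments) == 1
    assert len(seg.tasks) == 1
    assert len(seg.motor_programs) == 1


def test_empty_log(make_log):
    log = make_log([])
    seg = segment(log, make_thresholds())
    assert len(seg.task_segments) == 0
    assert len(translation_units(seg)) == 0


def test_threshold_boundary_is_inclusive(make_log):
    """An IKI exactly equal to a threshold opens the new unit (>= rule)."""
    log = log_from_ikis(make_log, [300, 900, 200])
    seg = segment(log, make_thresholds())
    assert len(seg.tasks) == 3  # 300 >= rsp, 900 >= rsp
    assert len(seg.task_segments) == 2  # 900 >= tsp
    assert len(seg.motor_programs) == 4  # 200 >= delay


def test_degenerate_thresholds_raise(make_log):
    log = log_from_ikis(make_log, [100, 200])
    with pytest.raises(ConfigurationError, match="rsp.*>= tsp"):
        segment(log, make_thresholds(rsp=900, tsp=900))


def test_delay_above_rsp_collapses_motor_programs(make_log):
    log = log_from_ikis(make_log, [100, 250, 100])
    with pytest.warns(UserWarning, match="collapsing"):
        seg = segment(log, make_thresholds(rsp=220, tsp=900, delay=230))
    # motor-program boundaries coincide with Task boundaries
    assert np.array_equal(seg.mp_ids, seg.task_ids)


@given(
    st.lists(st.integers(min_value=0, max_value=1500), min_size=1, max_size=120),
    st.integers(min_value=210, max_value=700),
    st.integers(min_value=50, max_value=900),
)
def test_matches_bruteforce_oracle(ikis, rsp, gap):
    """segment() agrees with an independent pairwise-threshold oracle."""
    tsp = rsp + gap
    times = np.r_[0, np.cumsum(ikis)].astype(int)
    events = pd.DataFrame(
        {
            "session_id": "s",
            "translator_id": "t",
            "study_id": "x",
            "group": "g",
            "time": times,
            "char": "a",
            "op": "insert",
            "segment_index": 0,
        }
    )
    thresholds = make_thresholds(rsp=float(rsp), tsp=float(tsp))
    seg = segment(KeystrokeLog(events), thresholds)
    assert_matches_oracle(seg, times, thresholds)


@given(
    st.lists(st.integers(min_value=0, max_value=2000), min_size=1, max_size=100),
    st.integers(min_value=210, max_value=900),
    st.integers(min_value=0, max_value=500),
)
def test_monotonicity_in_thresholds(ikis, rsp, bump):
    """Raising tsp never creates more Task Segments; raising rsp never
    creates more Tasks."""
    times = np.r_[0, np.cumsum(ikis)].astype(int)
    events = pd.DataFrame(
        {
            "session_id": "s",
            "translator_id": "t",
            "study_id": "x",
            "group": "g",
            "time": times,
            "char": "a",
            "op": "insert",
            "segment_index": 0,
        }
    )
    log = KeystrokeLog(events)
    low = segment(log, make_thresholds(rsp=float(rsp), tsp=float(rsp + 10)))
    high = segment(
        log, make_thresholds(rsp=float(rsp + bump), tsp=float(rsp + 10 + bump))
    )
    assert len(high.task_segments) <= len(low.task_segments)
    assert len(high.tasks) <= len(low.tasks)


def test_nesting_and_partition(make_log):
    rng = np.random.default_rng(0)
    ikis = rng.integers(0, 1500, size=400)
    log = log_from_ikis(make_log, ikis.tolist())
    seg = segment(log, make_thresholds())
    # partition: concatenated segments reproduce the event sequence
    order = [i for s in seg.task_segments for i in range(s.start, s.end + 1)]
    assert order == list(range(len(log)))
    # nesting: unit ids are refinements
    for coarse, fine in [(seg.ts_ids, seg.task_ids), (seg.task_ids, seg.mp_ids)]:
        starts_coarse = set(np.flatnonzero(np.r_[True, coarse[1:] != coarse[:-1]]))
        starts_fine = set(np.flatnonzero(np.r_[True, fine[1:] != fine[:-1]]))
        assert starts_coarse <= starts_fine


def test_translation_units_pause_and_conservation(make_log):
    log = log_from_ikis(make_log, [100, 100, 1200, 100, 2500, 50])
    seg = segment(log, make_thresholds())
    units = translation_units(seg)
    assert [u.pause for u in units] == [None, 1200, 2500]
    # offset + pauses + segment durations telescope to the session span
    total = sum(u.pause or 0 for u in units) + sum(
        seg.duration(u.segment) for u in units
    )
    assert total == log.span


def test_single_segment_translation_unit(make_log):
    log = log_from_ikis(make_log, [100, 100])
    units = translation_units(segment(log, make_thresholds()))
    assert len(units) == 1 and units[0].pause is None


def test_tables_shapes(make_log):
    log = log_from_ikis(make_log, [100, 350, 100, 1000, 100])
    seg = segment(log, make_thresholds())
    ev = seg.event_table()
    assert list(ev.columns) == [
        "event_index",
        "motor_program_id",
        "task_id",
        "task_segment_id",
    ]
    assert len(ev) == len(log)
    st_table = seg.segment_table()
    assert st_table["n_keystrokes"].sum() == len(log)
    assert st_table["n_tasks"].sum() == len(seg.tasks)
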