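"""Shared fixtures: hand-built logs and small generated cohorts."""

from __future__ import annotations

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from taskseg.io import KeystrokeLog
from taskseg.simulate import GeneratorConfig, generate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def make_log():
    """Factory for hand-built single-session logs.

    ``make_log(times, chars, ops=..., segs=...)``; omitted fields default to
    plain letter inserts in segment 0.
    """

    def _make(
        times,
        chars=None,
        ops=None,
        segs=None,
        session_id="s1",
        translator_id="t1",
        group="es",
    ) -> KeystrokeLog:
        n = len(times)
        chars = list(chars) if chars is not None else ["a"] * n
        ops = list(ops) if ops is not None else ["insert"] * n
        segs = list(segs) if segs is not None else [0] * n
        return KeystrokeLog(
            pd.DataFrame(
                {
                    "session_id": session_id,
                    "translator_id": translator_id,
                    "study_id": "TEST",
                    "group": group,
                    "time": list(times),
                    "char": chars,
                    "op": ops,
                    "segment_index": segs,
                }
            )
        )

    return _make


@pytest.fixture(scope="session")
def small_cohort():
    """Two synthetic translators x two sessions, with ground truth."""
    configs = [
        GeneratorConfig(translator_id="P01", seed=1),
        GeneratorConfig(
            translator_id="P02",
            seed=2,
            median_wp=180.0,
            median_bp=235.0,
            iki_cap=320.0,
            respite_range=(390.0, 640.0),
            tsp_range=(790.0, 2800.0),
        ),
    ]
    sessions, meta = generate_cohort(configs, 2, master_seed=99, n_states=60)
    return sessions, meta
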