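# taskseg

Pause taxonomy, hierarchical burst segmentation and translator profiling
for keystroke logs of translation (and other writing) sessions.

Human text production comes in bursts: runs of fast keystrokes separated
by pauses whose duration reflects what the writer is doing — executing an
automatized motor routine, taking a breath between chunks, or stopping to
think. `taskseg` is for translation-process and writing researchers who
have keystroke logs (one timestamped keypress per row, as in CRITT
TPR-DB-style tables) and want to turn them into interpretable units and
statistics without hand-tuning a pause threshold per study.

## The model

For each translator *i*, pooled over their sessions, the package classifies
every inter-keystroke interval (IKI) by the keystroke it precedes —
within-word pause (WP), between-word pause (BP), between-segment pause
(SP) — and fits two translator-specific thresholds:

    RSP_i = 2 · median(WP_i)        (Respite)
    TSP_i = 3 · median(BP_i)        (Task Segment Pause)

together with a fixed 200 ms Delay. These thresholds drive a three-level
nested segmentation of the keystroke stream:

* **motor programs** — runs with all internal IKIs < 200 ms;
* **Tasks** — runs with no internal IKI ≥ RSP, labeled **A** (insertions
  only), **D** (deletions only) or **C** (mixed);
* **Task Segments** — runs of Tasks with no internal IKI ≥ TSP, labeled by
  concatenating their Task labels (`A`, `AA`, `DA`, ...).

On top of the segmentation it computes label summary tables, statistics
conditioned on annotated phenomenal states (Hesitation / Orientation /
Flow intervals, consumed as input), the transition matrix between those
states, and distribution-level translator fingerprinting: two-sample
Kolmogorov–Smirnov tests between session IKI samples decide whether two
sessions look like the same or different typists.

A seeded hierarchical generator produces synthetic sessions from a
three-layer stochastic process (HOF Markov chain → Task-Segment/Task
composition → lognormal IKIs), with ground-truth boundaries and
annotations, so every stage of the pipeline is testable without
downloading data. See `docs/methods.md` for the full model description
and the design decisions.

## Worked example

```python
from taskseg import TaskSegmentModel, GeneratorConfig, generate_cohort

configs = [
    GeneratorConfig(translator_id="P01", seed=1),
    GeneratorConfig(translator_id="P02", seed=2, median_wp=180.0, median_bp=235.0,
                    iki_cap=320.0, respite_range=(390.0, 640.0), tsp_range=(790.0, 2800.0)),
]
sessions, meta = generate_cohort(configs, n_sessions_per_translator=2,
                                 master_seed=7, min_keystrokes=2000)
logs = [log for log, _ in sessions]
annotations = [a for _, truth in sessions for a in truth.annotations]

results = TaskSegmentModel(logs, annotations).fit()
print(results.summary())
```

prints

```
Task Segment model
==================
sessions: 4   translators: 2   keystrokes: 8034
task segments: 929   tasks: 1710   delay: 200 ms

Per-translator thresholds (ms)
translator_id  median_wp  median_bp   rsp   tsp  superpause  n_wp  n_bp
          P01      140.0      200.0 280.0 600.0      3000.0  1332   878
          P02      183.0      236.0 366.0 708.0      3540.0  1345   855
```

The fitted WP medians (140 and 183 ms) recover each generator's configured
within-word timing, and the thresholds follow as `rsp = 2·median_wp`,
`tsp = 3·median_bp`. Continuing,

```python
print(results.ts_label_summary(top=4))
rec = results.recognition(alpha=0.05)
print(rec.same_recognized_rate, rec.diff_recognized_rate)
```

```
ts_label  total  dur_ts    iki  key_t  share_es
       A    292  490.51 179.71   3.73     31.43
      AA    128 1955.65 207.39   5.21     13.78
       D    128  102.62 156.37   1.66     13.78
     AAA     75 3463.04 217.35   5.64      8.07
1.0 1.0
```

Single-insertion bursts (`A`) dominate the Task-Segment labels — 31% of
all segments here, averaging 3.7 keystrokes at a 180 ms internal IKI —
and the KS2 fingerprinting recognizes all same-translator session pairs as
one population and all different-translator pairs as distinct ones
(rates 1.0 and 1.0).

A `taskseg` command-line tool wraps the same pipeline for files on disk:
`taskseg simulate` / `thresholds` / `segment` / `summarize` / `hofstats` /
`identify` (see `--help` for each).

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates a three-translator synthetic cohort from the given seed and
runs the complete pipeline on it — threshold fitting, segmentation, label
summaries, HOF transition matrix and state statistics, TSP time fractions,
Task-type distributions per state, KS2 recognition and the RSP–TSP
correlation — printing every table it computes and writing the results
JSON to the given path.
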