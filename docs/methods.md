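# Methods

`taskseg` analyses keystroke logs of translation (or other writing)
sessions. Its object of study is the *pausing structure* of typing: text
production comes in bursts, and the inter-keystroke intervals (IKIs) that
separate bursts carry information about the underlying production process
on several time scales at once.

## Pause taxonomy and thresholds

Every keystroke gets a key-down timestamp in integer milliseconds; the IKI
preceding a keystroke is classified by the kind of keystroke it leads into.
A **word-boundary** keystroke is one of

    ` “ ” ‘ ’ " ' _ . ! ? : = @ $ % & * ( ) [ ] { }

(blank spaces are normalized to `_`). A keystroke flanked by non-boundary
keystrokes on both sides is **within-word**; the first non-boundary
keystroke after a boundary (or after session start) is **word-initial**,
promoted to **segment-initial** when it is the first non-boundary
keystroke of a new source segment; a non-boundary keystroke followed by a
boundary is **word-final** and takes part in no pause median. The IKI
preceding a within-word / word-initial / segment-initial keystroke is a
**WP** / **BP** / **SP** respectively; all other IKIs are unclassified.

Design choices in this classification:

* Deletions are classified by the character they remove, with the same
  alphabet — burst labels include deletions and no separate rule exists.
* Multi-character tokens (`Return`, `Tab`, ...) count as boundary
  keystrokes: they terminate words the same way a space does.
* Both typographic and ASCII quote characters are in the default alphabet,
  because logged data contains either depending on the keyboard layout; the
  narrower typographic-only set is exported as `STRICT_BOUNDARY_CHARS` and
  any alphabet can be passed explicitly.
* A missing follower (session end) does not count as a boundary; a missing
  predecessor (session start) does.

Because typing speed varies enormously between people, the burst thresholds
are *fitted per translator*, pooling all of their sessions:

    RSP = 2 * median(WP)      (Respite: separates Tasks)
    TSP = 3 * median(BP)      (Task Segment Pause: separates Task Segments)

with a fixed **Delay** of 200 ms separating motor programs and a
**Superpause** threshold of `5 * TSP` by default. The superpause scale has
no canonical numeric definition beyond "much larger than TSP"; the
multiplier is therefore an explicit, configurable parameter rather than a
hidden constant, and nothing in the segmentation depends on it. Medians use
the mean-of-middle-two rule for even samples; at least 20 WP and 20 BP
observations are required per translator (configurable), and a fit with
`RSP >= TSP` is flagged loudly — it would collapse the hierarchy.

## Segmentation

Segmentation is driven purely by IKIs. Walking the event stream, an IKI
`>= TSP` opens a new Task Segment, an IKI in `[RSP, TSP)` a new Task, and
an IKI in `[Delay, RSP)` a new motor program. All comparisons use `>=`
(an IKI exactly at a threshold opens the unit); the source material never
pins down this tie, so the inclusive convention — matching the "IKI ≥ 200
ms" delay definition — is applied uniformly. The result is a nested
partition: every event lies in exactly one motor program ⊂ Task ⊂ Task
Segment. If a very fast typist yields `Delay >= RSP`, the motor-program
level is collapsed into the Task level with a warning.

A Task Segment's duration spans its first to last keydown, *excluding* the
preceding pause; a **Translation Unit** is the pair (preceding TSP, Task
Segment), so initial offset + pauses + durations telescope to the session
span.

## Labels and summary tables

Tasks are labeled **A** (insertions only), **D** (deletions only) or **C**
(mixed); a Task Segment's label concatenates its Task labels in order. The
label summary reports counts, per-group percentage shares (computed over
the full label distribution, then truncated for display), mean duration,
mean internal IKI and mean keystrokes per Task. The mean IKI includes
inter-Task Respites inside the segment but never the preceding TSP — this
keeps the IKI and duration columns consistent with the TU decomposition;
it is a convention, flagged here because reasonable alternatives exist.

## HOF statistics

HOF annotations (Hesitation / Orientation / Flow intervals) are inputs,
not inferred. Keystrokes are assigned to the closed interval containing
their timestamp; Tasks and Task Segments to the interval containing their
first keystroke (a deterministic rule for straddling units); keystrokes
outside every interval are counted in an explicit unannotated bucket.

The transition matrix collapses adjacent identical states first, so its
diagonal is structurally zero, and never counts transitions across session
boundaries. Per-state statistics follow a per-session-first convention:
each metric is averaged over the state visits within a session, then
mean/min/max are taken across sessions. The fraction of state time spent
in TSPs divides the summed overlap of inter-segment pauses with the
state's intervals by the total state time, pooled over sessions; for
Orientation — which contains no typing — this fraction is trivially close
to 1 and not meaningful, it is reported for completeness only.

## Translator profiling

Session-level IKI samples are compared with the two-sample
Kolmogorov–Smirnov test (asymptotic p-values). A same-translator pair is
"recognized" when `p >= alpha`, a different-translator pair when
`p < alpha`; `alpha` defaults to 0.05 and is exposed. No IKI filtering is
applied by default (an upper truncation can be applied by the caller);
session-level, not translator-pooled, samples enter the pairwise tests.
The RSP–TSP association across translators uses Spearman's rank
correlation with midranks (ms-resolution data ties often); for n ≤ 9 the
two-sided p-value is computed by exact enumeration over all pairings,
beyond that by the asymptotic approximation.

## The synthetic generator

The generator emulates a three-layer production process:

* **Phenomenal layer.** A first-order Markov chain over O/F/H with zero
  diagonal. The default transition matrix is
  `O→(F .86, H .14), F→(O .60, H .40), H→(O .09, F .91)` and sessions
  start in Orientation (first-pass reading).
* **Cognitive layer.** Each F/H visit emits `1 + Poisson(m−1)` Task
  Segments (defaults: F 2.10, H 1.95) separated by pauses drawn uniformly
  from the TSP band. Orientation emits a silence of
  `superpause_min + Exp(o_pause_mean − superpause_min)` (defaults 3000 and
  4838 ms) and no keystrokes.
* **Sensorimotor layer.** Each Task Segment is `1 + Poisson(m−1)` Tasks
  (F 2.20, H 1.15) separated by Respite-band pauses; Task labels are drawn
  from per-state mixtures (F: A/D/C = .81/.08/.11; H: .53/.41/.06) and
  Tasks emit `1 + Poisson(m−1)` keystrokes (F 5.47, H 1.34) over a
  synthetic word stream (word length `1 + Poisson(4)`, `_` as boundary, a
  new source segment every 10 words). Within-word and between-word IKIs
  are lognormal with medians 140 and 203 ms and log-dispersion 0.45. D and
  C Tasks backspace previously typed characters in reverse order; a D/C
  draw with nothing left to delete falls back to an insertion Task.

Defaults mirror a typical student translator profile of the
English-to-Spanish kind: fast unimodal, right-skewed IKI distributions
peaking near 140 ms, Orientation reads of ~5 s, Flow bursts an order of
magnitude larger than Hesitation bursts.

Two calibration decisions matter and are deliberate:

1. **Disjoint pause bands with margins.** The primitive parameters are
   pause *ranges*, not thresholds, so ground truth stays independent of the
   estimators. Within/between-word draws are truncated below `iki_cap`
   (270 ms), Respites live on [330, 550] ms, TSPs on [700, 2800] ms, and
   Orientation pauses start at 3000 ms. The margins are not cosmetic: the
   fitted thresholds are `2*median(WP) ≈ 281 ms` and `3*median(BP) ≈ 609
   ms`, which would fall strictly *inside* bands drawn edge-to-edge — some
   structural pauses would then land below the fitted cutoff and exact
   boundary recovery would be impossible by construction. With margins,
   the fitted RSP lands between the IKI cap and the Respite band, the
   fitted TSP between the Respite and TSP bands, and segmentation
   reproduces the generated boundaries exactly.
2. **Truncated-median calibration.** Truncating a lognormal at `iki_cap`
   drags its median down; the generator therefore solves for the log-scale
   such that the *truncated* law has exactly the configured median. Without
   this, parameter-recovery checks would measure truncation bias rather
   than estimator error.

One structural choice: inserting Tasks always open at a word boundary (the
`_` keystroke comes first), mimicking how typists pause between words
rather than mid-word. This keeps structural pauses out of the WP/BP
samples — except when a pure-deletion Task starts, whose first backspace
removes a letter; that residual contamination is a few percent of the WP
sample and shifts the fitted WP median by ~1–3%, well inside the 5%
recovery tolerance. A Task ending mid-word abandons the word fragment.

What the generator does *not* emulate, hence what a green test does not
establish: no gaze channel (Orientation is silence, not reading
behavior); Hesitation differs from Flow only through its burst sizes,
label mixture and pause scales, not through re-reading dynamics; the word
stream is random letters, so no linguistic structure, syllable effects or
frequency-dependent bigram timing; IKI distributions are stationary within
a session (no fatigue, no warm-up); and no belief updating or planning of
any kind — the generator is a descriptive stochastic process.

## Numerical notes

* Timestamps are integer milliseconds; equal consecutive timestamps are
  legal input (IKI 0), though the generator keeps IKIs ≥ 1 ms.
* The session's first keystroke has no IKI and enters no pause statistic.
* KS2 p-values on ms-rounded data are mildly conservative because of ties;
  the measured type-I error at alpha = 0.05 over 500 same-config session
  pairs is ≈ 0.036, within binomial error of alpha.
* Transition-matrix rows with no observed transitions are reported as
  zero rows, not NaN.
* Cohort generation derives per-session seeds from a master seed via
  `numpy.random.SeedSequence.spawn`, so cohorts are reproducible and
  sessions are independent.

## Known limitations

* The boundary alphabet is surface-level; no language-specific
  tokenization (relevant for, e.g., Arabic clitics) is attempted.
* Multi-character paste events are assumed absent from the canonical
  format.
* HOF annotation quality is taken at face value; no inter-annotator
  machinery exists here.
* SP medians are computed and reported but feed no threshold, matching
  how the framework uses only WP and BP.
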