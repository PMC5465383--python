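# Methods

This note documents the models, defaults and numerical choices behind
`cogbattery`, and what the synthetic-data checks do and do not establish.

## The battery engines

Each engine emits a declarative stimulus specification (JSON-serializable,
schema-versioned) and scores a timestamped event log against it; no
rendering or touch handling is modelled.

**Memory-Word.** Ten study words are drawn without replacement from a word
pool (a bundled 40-word Dutch noun pool by default; any pool of ≥ 20
distinct words is accepted), presented at a fixed pace (default 2 s/word,
configurable), then mixed with ten foils into a seeded-permutation 20-item
recognition list. Scoring counts agreements between the yes/no response
vector and the old/new flags; `n_correct + n_incorrect = 20` always. The
recognition phase is treated as self-paced.

**Trail Making.** Twelve labelled circles per part in a unit square; the
target orders are 1–12, A–L, 1-A-2-B-…-6-F, and 1-Z-2-Y-…-6-U. Centres are
rejection-sampled (default radius 0.05, minimum separation 2.5 radii,
capped at 10,000 draws; an unpackable geometry raises a layout-infeasible
error). Completion time runs from stimulus display to the last correct tap.
Wrong-circle taps never advance the trail; by default they accumulate as
errors (`wrong_tap_policy="error"`), or can be silently ignored
(`"ignore"`) since only total time enters the downstream analyses. Taps
sharing a timestamp collapse to the first (double-touch debounce).

**Stroop.** Thirty items per panel over a configurable colour set (default
red/green/blue/yellow; at least two colours are required or part-3
incongruence is impossible). Part 1: colour words in black ink, correct
answer = the word; part 2: colour blocks, correct = the block colour;
part 3: colour words in a *different* ink, correct = the ink. Every item
offers the full colour set as answer options. Total time runs to the final
response; accuracy feeds the mistake filter in the analysis stage.

**Reaction Time.** Part 1 is simple reaction time (all blue go cues);
part 2 mixes blue with red no-go cues (default blue fraction 0.7). Cue
onsets are uniform over 1–3 s (configurable). Exactly one trial per
administration carries the enlarged startle probe, always on a go trial;
its latency is reported separately (`startle_time_ms`) and excluded from
the ordinary latency mean. Touches on red cues are commission errors;
touches preceding the cue are flagged anticipatory and excluded from the
mean latency.

**Letter-N-Back.** Sequence lengths are fixed at 11/11/15/20 for levels
0–3. Target counts default to roughly 30% of scorable positions
(3/3/4/5). Construction is left-to-right: a planted target copies the
letter n back, a non-target draws from a 19-consonant pool excluding the
letter that would create a match ('X' is reserved for the 0-back target),
so accidental extra targets cannot arise; the finished sequence is
nevertheless re-verified against the n-back definition before it is
returned.

## Calendar and adherence

The default calendar prompts each test four times across a 182-day
follow-up (Memory-Word 1/29/99/169, Trail Making 2/43/113/170, Stroop
3/57/127/171, Reaction Time 4/71/141/172, Letter-N-Back 15/85/155/173).
Custom calendars must keep ≥ 4 strictly increasing offsets per test inside
the follow-up.

"Within one week of the reminder" is implemented as the half-open interval
`[reminder_day, reminder_day + 7)` — unambiguous and directly testable —
with the closed variant `[d, d + 7]` behind `window_closed=True`. A
completed session satisfies at most one reminder (greedy matching in
reminder order); sessions between windows count toward the separate
ever-performed statistic but toward no reminder. Per-participant adherence
averages the per-reminder indicator over all reminders of all tests, so
tests with equally many reminders weigh equally.

## The respondent model

Respondents are statistical agents, not cognitive models. One standard
normal latent ability `a_i` drives everything that should correlate:

* timed smartphone scores:
  `time = base + slope·(attempt−1) − λ·a_i + LogNormal(log s, σ)`, with
  per-test base times (Stroop 20 s, Trail Making 16 s at part 1, plus
  deterministic per-part offsets), ability loading λ = 4 s/SD, noise median
  s = 3 s and shape σ = 0.5. Lognormal noise keeps times positive and
  right-skewed, matching how completion-time distributions behave.
* practice slopes apply to Stroop and Trail Making only (population means
  −0.93 and −1.8 s/attempt, between-participant SD 0.3); accuracy tests and
  reaction latencies are stable across attempts by default, emulating the
  ceiling behaviour expected of cognitively healthy adults.
* conventional baseline scores are affine decreasing in the same ability
  plus independent Gaussian noise, so the cross-instrument rank correlation
  is governed by the noise SDs.
* each reminder in week w is answered with probability `p₀·δ^w`; `p₀` is
  Beta-distributed (mean 0.72, SD 0.22) and δ = 0.99/week, yielding a
  cohort mean adherence near 60% with a slight decline across the four
  occasions. Dropout strikes 8% of participants at a uniform day in
  follow-up. Self-initiated extra sessions arrive Poisson at a
  participant-specific rate (log-normal across participants, median 0.8
  per test), so a small minority accumulates many attempts.
* a small fraction (8%) of participants botch their first Stroop attempt
  (≈35% correct), exercising the ≥-half-correct mistake filter.

These defaults were chosen once as a realistic regime for a motivated
older-adult cohort in a six-month remote-monitoring programme; they are all
overridable through the population config block.

What the simulator deliberately omits: item-level response processes,
forgetting/retention dynamics, time-of-day and device effects, and any
dependence of dropout on performance (dropout is missing-completely-at-
random). Passing tests therefore show that the *pipeline* recovers the
structure it assumes — not that real cohort data satisfy that structure.

## Statistical procedures

**Spearman ρ.** Mid-ranks for ties, pairwise deletion of incomplete pairs,
p-value from the large-sample t approximation
`t = ρ·√((n−2)/(1−ρ²))`; an exact permutation p-value is available for
n ≤ 10. A constant margin raises an undefined-correlation error rather
than returning NaN. The implementation is cross-checked in the test suite
against an O(n²) first-principles mid-rank oracle at 1e-12.

**Validity calibration.** For statistical validation the package provides
a calibrated pair design in which both instruments are `a + σe` with
`σ = √(1/r − 1)` and `r = 2·sin(πρ_s/6)` — the bivariate-normal identity
linking Pearson and Spearman correlation — so the population Spearman of
the conventional/first-attempt pair is set exactly. Mean-of-attempts
scores average independent noise and must correlate more strongly in
expectation; the suite verifies this directionally with a sign test.

**Bland-Altman.** Both instruments are standardized to z-scores over the
matched pairs (sample SD, ddof = 1) because they share no natural scale;
the mean difference is then 0 by construction, and the informative outputs
are the SD of differences and the limits of agreement `±1.96·SD`.

**Learning trend.** The random-intercept/random-slope model is fitted by
REML (ML behind a flag) with an unstructured 2×2 random-effects
covariance, via `statsmodels` MixedLM. The attempt covariate is centred at
the first attempt for interpretability of the intercept. Gradient
optimizers (lbfgs, then cg) are tried first; if convergence is not
reached — typical when a variance component sits on the zero boundary —
the fit is retried with Powell, which handles the boundary reliably. A
non-convergent or non-finite fit raises a fit-failure error; a design in
which every participant has a single attempt raises a degenerate-design
error. The repeat-effect report refits per test part on the subset of
participants with ≥ `min_attempts` attempts (default 9) to probe selective
dropout; subsets below 5 qualifying participants are reported as missing
rather than fitted.

**Missing data.** Correlations use pairwise deletion; the mixed model uses
all available attempts (likelihood-based, valid under
missing-at-random). Mistakes on the conventional instruments are ignored.
The pairing between conventional and smartphone trail parts is a config
mapping (default: numeric ↔ smartphone part 1, alphanumeric ↔ part 3),
since the reversed part 4 has no conventional analogue.

## Problem sizes and determinism

The statistical acceptance checks run 200 Monte-Carlo replicates of a
balanced 150-participant × 6-attempt design for slope recovery (planted
slope −1.8 s/attempt, random-slope SD 0.5, tolerance 3 Monte-Carlo SEs,
plus a Kolmogorov–Smirnov uniformity check of null p-values) and 200
replicates of the n = 146 calibrated validity design (target ρ = 0.5,
tolerance ±0.03 on the replicate mean). The pipeline determinism check
uses a 40-participant cohort and compares artifact bytes across two runs.

All randomness flows through `numpy.random.Generator` seeded explicitly;
the pipeline derives independent per-stage seeds from the global seed with
`SeedSequence.spawn`, and the manifest (seed + effective config + package
version) suffices to reproduce every artifact byte-for-byte.

## Known limitations

* The simulator's adherence process is memoryless given the weekly decay;
  real engagement shows streaks and alarm fatigue.
* The latent-ability model is one-dimensional; real batteries show
  domain-specific factors, so cross-test correlations are overstated.
* Scores for accuracy tests are binomial counts; item-level difficulty and
  speed-accuracy trade-offs are not modelled.
* The trail scorer assumes taps are attributable to circles (no spatial
  decoding); the layout geometry exists so a front end could render it.
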