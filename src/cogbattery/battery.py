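"""Stimulus generation and scoring for the five smartphone cognitive tests.

The battery comprises digital adaptations of classic neuropsychological
instruments: a word-list recognition test (Memory-Word), a four-part Trail
Making test, a three-panel Stroop colour-word test, a two-part go/no-go
Reaction Time test with a single startle probe, and a Letter-N-Back working
memory test at levels 0-3.  Each engine produces a declarative stimulus
specification (no rendering) and scores a timestamped response log against it.

All generators are deterministic under a fixed seed: pass either an integer
seed or a ``numpy.random.Generator``.
"""

from __future__ import annotations

import importlib.resources
import json
import string
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    IncompleteSessionError,
    InvalidInputError,
    LayoutInfeasibleError,
)

SCHEMA_VERSION = 1

#: canonical test identifiers used throughout the package
TEST_IDS = ("memory_word", "tmt", "stroop", "reaction", "nback")

#: sequence length per n-back level (levels 0-3)
NBACK_LENGTHS = {0: 11, 1: 11, 2: 15, 3: 20}
#: default number of planted targets per level (~30% of scorable positions)
NBACK_DEFAULT_TARGETS = {0: 3, 1: 3, 2: 4, 3: 5}
#: consonant pool for n-back letters; 'X' is reserved for the 0-back target
NBACK_LETTER_POOL = "BCDFGHJKLMNPQRSTVWZ"

DEFAULT_COLOR_SET = ("red", "green", "blue", "yellow")
STROOP_N_ITEMS = 30
TRAIL_N_CIRCLES = 12
WORD_STUDY_LEN = 10
WORD_RECOGNITION_LEN = 20


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def load_default_word_pool() -> list[str]:
    """Return the bundled 40-word Dutch noun pool."""
    text = (
        importlib.resources.files("cogbattery")
        .joinpath("data/wordpool.txt")
        .read_text(encoding="utf-8")
    )
    return [w.strip() for w in text.splitlines() if w.strip()]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WordMemoryStimulus:
    """One administration of the Memory-Word test.

    ``study_list`` holds the 10 words presented for memorisation,
    ``recognition_list`` the 20-item yes/no recognition phase (the 10 studied
    words shuffled with 10 foils), and ``is_old[i]`` whether
    ``recognition_list[i]`` was studied.  ``presentation_pace_s`` is the fixed
    per-word display time of the study phase.
    """

    study_list: tuple[str, ...]
    recognition_list: tuple[str, ...]
    is_old: tuple[bool, ...]
    presentation_pace_s: float = 2.0

    def __post_init__(self):
        if len(self.study_list) != WORD_STUDY_LEN:
            raise InvalidInputError("study_list must contain exactly 10 words")
        if len(self.recognition_list) != WORD_RECOGNITION_LEN:
            raise InvalidInputError("recognition_list must contain exactly 20 words")
        if len(set(self.study_list)) != WORD_STUDY_LEN:
            raise InvalidInputError("study_list words must be distinct")
        if len(set(self.recognition_list)) != WORD_RECOGNITION_LEN:
            raise InvalidInputError("recognition_list words must be distinct")
        if len(self.is_old) != WORD_RECOGNITION_LEN:
            raise InvalidInputError("is_old must flag each recognition item")
        study = set(self.study_list)
        for word, old in zip(self.recognition_list, self.is_old):
            if old != (word in study):
                raise InvalidInputError(f"is_old flag inconsistent for {word!r}")
        if sum(self.is_old) != WORD_STUDY_LEN:
            raise InvalidInputError("recognition list must mix 10 old with 10 new words")


@dataclass(frozen=True)
class TrailLayout:
    """A 12-circle trail: target ``labels`` in tap order plus their centres
    (unit-square coordinates)."""

    part: int
    labels: tuple[str, ...]
    positions: tuple[tuple[float, float], ...]
    radius: float = 0.05

    def __post_init__(self):
        if self.part not in (1, 2, 3, 4):
            raise InvalidInputError("trail part must be 1-4")
        if len(self.labels) != TRAIL_N_CIRCLES or len(self.positions) != TRAIL_N_CIRCLES:
            raise InvalidInputError("trail layout requires exactly 12 circles")
        if tuple(self.labels) != tuple(trail_sequence(self.part)):
            raise InvalidInputError("labels do not match the part's target sequence")
        pos = np.asarray(self.positions, dtype=float)
        d = np.sqrt(((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        if (d <= 2 * self.radius).any():
            raise InvalidInputError("circles overlap")


@dataclass(frozen=True)
class StroopItem:
    display_text: str | None  # None renders as a colour block (part 2)
    display_color: str
    correct_answer: str
    answer_options: tuple[str, ...]

    def __post_init__(self):
        if self.correct_answer not in self.answer_options:
            raise InvalidInputError("correct answer must be among the options")


@dataclass(frozen=True)
class StroopPanel:
    """One 30-item Stroop panel.

    Part 1 shows colour names in black ink (read the word), part 2 coloured
    blocks (name the colour), part 3 colour names printed in a conflicting ink
    colour (name the ink — the interference condition).
    """

    part: int
    items: tuple[StroopItem, ...]

    def __post_init__(self):
        if self.part not in (1, 2, 3):
            raise InvalidInputError("stroop part must be 1-3")
        if len(self.items) != STROOP_N_ITEMS:
            raise InvalidInputError("stroop panel requires exactly 30 items")
        for it in self.items:
            if self.part == 1 and it.display_color != "black":
                raise InvalidInputError("part-1 items must be printed in black")
            if self.part == 3 and it.display_text == it.display_color:
                raise InvalidInputError("part-3 items must be incongruent")


@dataclass(frozen=True)
class ReactionTrial:
    cue_onset_ms: float
    target_type: str  # "blue" (go) or "red" (no-go)
    is_startle: bool = False

    def __post_init__(self):
        if self.target_type not in ("blue", "red"):
            raise InvalidInputError("target_type must be 'blue' or 'red'")
        if self.cue_onset_ms < 0:
            raise InvalidInputError("cue onset must be non-negative")


@dataclass(frozen=True)
class ReactionTrialSet:
    """One administration of a Reaction Time part.

    Part 1 is simple reaction time (all go trials); part 2 is go/no-go with a
    mix of blue (go) and red (no-go) cues.  Exactly one trial carries the
    enlarged-stimulus startle probe, always on a go trial.
    """

    part: int
    trials: tuple[ReactionTrial, ...]

    def __post_init__(self):
        if self.part not in (1, 2):
            raise InvalidInputError("reaction part must be 1 or 2")
        if not self.trials:
            raise InvalidInputError("trial set must be non-empty")
        if self.part == 1 and any(t.target_type != "blue" for t in self.trials):
            raise InvalidInputError("part 1 contains only blue targets")
        n_startle = sum(t.is_startle for t in self.trials)
        if n_startle != 1:
            raise InvalidInputError("exactly one startle trial is required")
        if any(t.is_startle and t.target_type != "blue" for t in self.trials):
            raise InvalidInputError("the startle probe must be a blue trial")


@dataclass(frozen=True)
class NBackSequence:
    """A letter sequence for one n-back level with per-position target flags.

    Level 0 targets the fixed letter 'X'; level n >= 1 targets positions whose
    letter repeats the one n steps earlier.
    """

    n_level: int
    letters: tuple[str, ...]
    is_target: tuple[bool, ...]

    def __post_init__(self):
        if self.n_level not in NBACK_LENGTHS:
            raise InvalidInputError("n_level must be 0-3")
        if len(self.letters) != NBACK_LENGTHS[self.n_level]:
            raise InvalidInputError(
                f"level {self.n_level} sequence must have "
                f"{NBACK_LENGTHS[self.n_level]} letters"
            )
        if len(self.is_target) != len(self.letters):
            raise InvalidInputError("is_target must flag each position")
        if tuple(self.is_target) != tuple(nback_scan(self.n_level, self.letters)):
            raise InvalidInputError("is_target inconsistent with the n-back rule")


@dataclass
class TestScore:
    """Scored outcome of one test administration (one part where parts exist).

    Times are seconds for the timed tests (Stroop, TMT) and milliseconds for
    reaction latencies, matching how each is conventionally reported.
    """

    test_id: str
    part: int | None = None
    completion_time_s: float | None = None
    n_correct: int | None = None
    n_incorrect: int | None = None
    n_errors: int | None = None  # wrong-circle taps (TMT)
    latencies_ms: list[float] = field(default_factory=list)
    mean_latency_ms: float | None = None
    startle_time_ms: float | None = None
    n_commission_errors: int | None = None
    n_anticipatory: int | None = None

    def __post_init__(self):
        if self.completion_time_s is not None and self.completion_time_s < 0:
            raise InvalidInputError("completion time must be non-negative")


# ---------------------------------------------------------------------------
# Memory-Word
# ---------------------------------------------------------------------------


def generate_word_memory(
    word_pool: Sequence[str] | None = None,
    rng_seed=None,
    presentation_pace_s: float = 2.0,
) -> WordMemoryStimulus:
    """Draw a 10-word study list and a shuffled 20-item recognition list.

    ``word_pool`` must hold at least 20 distinct words; the bundled pool is
    used when omitted.  The recognition order is a seeded permutation of the
    10 studied words and 10 foils.
    """
    pool = list(word_pool) if word_pool is not None else load_default_word_pool()
    if len(set(pool)) < 2 * WORD_STUDY_LEN:
        raise InvalidInputError("word pool must contain at least 20 distinct words")
    if len(set(pool)) != len(pool):
        pool = list(dict.fromkeys(pool))
    rng = _as_rng(rng_seed)
    chosen = rng.choice(len(pool), size=2 * WORD_STUDY_LEN, replace=False)
    words = [pool[i] for i in chosen]
    study = words[:WORD_STUDY_LEN]
    recognition = list(words)
    rng.shuffle(recognition)
    studied = set(study)
    return WordMemoryStimulus(
        study_list=tuple(study),
        recognition_list=tuple(recognition),
        is_old=tuple(w in studied for w in recognition),
        presentation_pace_s=presentation_pace_s,
    )


def score_word_memory(
    stimulus: WordMemoryStimulus, responses: Sequence[bool]
) -> TestScore:
    """Score yes/no recognition responses; "yes" (True) asserts the word is old."""
    if len(responses) != len(stimulus.recognition_list):
        raise IncompleteSessionError(
            f"expected {len(stimulus.recognition_list)} responses, "
            f"got {len(responses)}"
        )
    n_correct = sum(bool(r) == old for r, old in zip(responses, stimulus.is_old))
    return TestScore(
        test_id="memory_word",
        n_correct=n_correct,
        n_incorrect=len(responses) - n_correct,
    )


# ---------------------------------------------------------------------------
# Trail Making
# ---------------------------------------------------------------------------


def trail_sequence(part: int) -> list[str]:
    """Target sequence for a trail part.

    Part 1: numbers ascending (1..12); part 2: letters ascending (A..L);
    part 3: numbers/letters alternating ascending (1-A-2-B...); part 4:
    numbers ascending, letters descending (1-Z-2-Y...), added to counter the
    ceiling effect in cognitively healthy adults.
    """
    if part == 1:
        return [str(i) for i in range(1, 13)]
    if part == 2:
        return list(string.ascii_uppercase[:12])
    if part == 3:
        seq = []
        for i in range(6):
            seq += [str(i + 1), string.ascii_uppercase[i]]
        return seq
    if part == 4:
        seq = []
        for i in range(6):
            seq += [str(i + 1), string.ascii_uppercase[25 - i]]
        return seq
    raise InvalidInputError("trail part must be 1-4")


def generate_trail_part(
    part: int,
    rng_seed=None,
    radius: float = 0.05,
    min_separation: float | None = None,
    max_attempts: int = 10_000,
) -> TrailLayout:
    """Place the part's 12 labelled circles in the unit square.

    Centres are rejection-sampled so that no two circles come closer than
    ``min_separation`` (default 2.5 radii).  Raises
    :class:`LayoutInfeasibleError` when the geometry cannot be packed within
    ``max_attempts`` draws.
    """
    labels = trail_sequence(part)
    if min_separation is None:
        min_separation = 2.5 * radius
    if radius <= 0 or radius >= 0.5:
        raise LayoutInfeasibleError("circle radius must lie in (0, 0.5)")
    rng = _as_rng(rng_seed)
    lo, hi = radius, 1.0 - radius
    centers: list[np.ndarray] = []
    attempts = 0
    while len(centers) < TRAIL_N_CIRCLES:
        if attempts >= max_attempts:
            raise LayoutInfeasibleError(
                f"could not place 12 circles of radius {radius} with "
                f"separation {min_separation} in {max_attempts} attempts"
            )
        attempts += 1
        cand = rng.uniform(lo, hi, size=2)
        if all(np.linalg.norm(cand - c) > min_separation for c in centers):
            centers.append(cand)
    return TrailLayout(
        part=part,
        labels=tuple(labels),
        positions=tuple((float(c[0]), float(c[1])) for c in centers),
        radius=radius,
    )


def score_trail(
    layout: TrailLayout,
    tap_log: Sequence[tuple[float, int]],
    display_time_ms: float = 0.0,
    wrong_tap_policy: str = "error",
) -> TestScore:
    """Score a trail run from ``(timestamp_ms, circle_index)`` taps.

    The trail advances only on a tap of the next circle in sequence order;
    other taps either accumulate as errors (policy ``"error"``, default) or are
    silently ignored (policy ``"ignore"``).  Duplicate taps sharing a timestamp
    collapse to the first.  Completion time is the last correct tap minus the
    stimulus display time.
    """
    if wrong_tap_policy not in ("error", "ignore"):
        raise InvalidInputError("wrong_tap_policy must be 'error' or 'ignore'")
    times = [t for t, _ in tap_log]
    if any(b < a for a, b in zip(times, times[1:])):
        raise InvalidInputError("tap timestamps must be monotone increasing")
    seen_ts: set[float] = set()
    pointer = 0
    n_errors = 0
    last_correct_ms: float | None = None
    for ts, idx in tap_log:
        if ts in seen_ts:  # same-frame duplicates collapse to the first touch
            continue
        seen_ts.add(ts)
        if not 0 <= idx < TRAIL_N_CIRCLES:
            raise InvalidInputError(f"tap on unknown circle index {idx}")
        if idx == pointer:
            pointer += 1
            last_correct_ms = ts
            if pointer == TRAIL_N_CIRCLES:
                break
        elif wrong_tap_policy == "error":
            n_errors += 1
    if pointer < TRAIL_N_CIRCLES:
        raise IncompleteSessionError(
            f"trail ended after {pointer} of {TRAIL_N_CIRCLES} targets"
        )
    return TestScore(
        test_id="tmt",
        part=layout.part,
        completion_time_s=(last_correct_ms - display_time_ms) / 1000.0,
        n_errors=n_errors,
    )


# ---------------------------------------------------------------------------
# Stroop
# ---------------------------------------------------------------------------


def generate_stroop_panel(
    part: int,
    color_set: Sequence[str] = DEFAULT_COLOR_SET,
    rng_seed=None,
) -> StroopPanel:
    """Generate a 30-item Stroop panel for the given part."""
    colors = list(dict.fromkeys(color_set))
    if len(colors) < 2:
        raise InvalidInputError("color set must contain at least 2 colors")
    if part not in (1, 2, 3):
        raise InvalidInputError("stroop part must be 1-3")
    rng = _as_rng(rng_seed)
    options = tuple(colors)
    items = []
    for _ in range(STROOP_N_ITEMS):
        if part == 1:
            word = colors[rng.integers(len(colors))]
            items.append(StroopItem(word, "black", word, options))
        elif part == 2:
            ink = colors[rng.integers(len(colors))]
            items.append(StroopItem(None, ink, ink, options))
        else:
            word = colors[rng.integers(len(colors))]
            ink = word
            while ink == word:
                ink = colors[rng.integers(len(colors))]
            items.append(StroopItem(word, ink, ink, options))
    return StroopPanel(part=part, items=tuple(items))


def score_stroop(
    panel: StroopPanel,
    responses: Sequence[tuple[str, float]],
    display_time_ms: float = 0.0,
) -> TestScore:
    """Score selected options ``(choice, timestamp_ms)`` against the panel.

    Total time runs from panel display to the final response; accuracy is
    tallied per item against the correct answer.
    """
    if len(responses) != len(panel.items):
        raise IncompleteSessionError(
            f"expected {len(panel.items)} responses, got {len(responses)}"
        )
    n_correct = sum(
        choice == item.correct_answer
        for (choice, _), item in zip(responses, panel.items)
    )
    last_ms = max(ts for _, ts in responses)
    return TestScore(
        test_id="stroop",
        part=panel.part,
        completion_time_s=(last_ms - display_time_ms) / 1000.0,
        n_correct=n_correct,
        n_incorrect=len(panel.items) - n_correct,
    )


# ---------------------------------------------------------------------------
# Reaction Time
# ---------------------------------------------------------------------------


def generate_reaction_trials(
    part: int,
    n_trials: int = 10,
    rng_seed=None,
    blue_fraction: float = 0.7,
    cue_delay_range_s: tuple[float, float] = (1.0, 3.0),
) -> ReactionTrialSet:
    """Generate a go/no-go trial set with one startle probe.

    Part 1 is all-blue (simple RT); part 2 mixes blue go trials with red
    no-go trials at ``blue_fraction``.  Cue onsets are uniform over
    ``cue_delay_range_s``.  The single startle probe lands on a uniformly
    chosen blue trial.
    """
    if part not in (1, 2):
        raise InvalidInputError("reaction part must be 1 or 2")
    if n_trials < 1:
        raise InvalidInputError("n_trials must be >= 1")
    rng = _as_rng(rng_seed)
    lo, hi = cue_delay_range_s
    onsets = rng.uniform(lo * 1000, hi * 1000, size=n_trials)
    if part == 1:
        types = ["blue"] * n_trials
    else:
        types = ["blue" if rng.random() < blue_fraction else "red" for _ in range(n_trials)]
        if "blue" not in types:  # the startle probe needs a go trial
            types[int(rng.integers(n_trials))] = "blue"
    blue_idx = [i for i, t in enumerate(types) if t == "blue"]
    startle = blue_idx[int(rng.integers(len(blue_idx)))]
    trials = tuple(
        ReactionTrial(float(onsets[i]), types[i], is_startle=(i == startle))
        for i in range(n_trials)
    )
    return ReactionTrialSet(part=part, trials=trials)


def score_reaction(
    trials: ReactionTrialSet, touch_log: Mapping[int, float]
) -> TestScore:
    """Score touches keyed by trial index (absolute touch time in ms).

    Latency is touch minus cue onset for touched blue trials.  A negative
    latency marks an anticipatory response and is excluded from the mean; a
    touch on a red trial is a commission error.  The startle trial's latency
    is reported separately and excluded from the ordinary latency mean.
    """
    for idx in touch_log:
        if not 0 <= idx < len(trials.trials):
            raise InvalidInputError(f"touch on unknown trial index {idx}")
    latencies: list[float] = []
    startle_ms: float | None = None
    n_commission = 0
    n_anticipatory = 0
    n_correct = 0
    n_incorrect = 0
    for i, trial in enumerate(trials.trials):
        touched = i in touch_log
        if trial.target_type == "red":
            if touched:
                n_commission += 1
                n_incorrect += 1
            else:
                n_correct += 1
            continue
        if not touched:
            n_incorrect += 1  # missed go trial
            continue
        latency = touch_log[i] - trial.cue_onset_ms
        if latency < 0:
            n_anticipatory += 1
            n_incorrect += 1
            continue
        n_correct += 1
        if trial.is_startle:
            startle_ms = latency
        else:
            latencies.append(latency)
    return TestScore(
        test_id="reaction",
        part=trials.part,
        latencies_ms=latencies,
        mean_latency_ms=float(np.mean(latencies)) if latencies else None,
        startle_time_ms=startle_ms,
        n_commission_errors=n_commission,
        n_anticipatory=n_anticipatory,
        n_correct=n_correct,
        n_incorrect=n_incorrect,
    )


# ---------------------------------------------------------------------------
# Letter-N-Back
# ---------------------------------------------------------------------------


def nback_scan(n_level: int, letters: Sequence[str]) -> list[bool]:
    """Apply the n-back rule to a letter sequence (the scoring definition)."""
    if n_level == 0:
        return [ch == "X" for ch in letters]
    return [i >= n_level and letters[i] == letters[i - n_level] for i in range(len(letters))]


def generate_nback(
    n_level: int,
    rng_seed=None,
    n_targets: int | None = None,
) -> NBackSequence:
    """Generate a letter sequence with exactly ``n_targets`` planted targets.

    Construction is left-to-right: a target position copies the letter n back,
    a non-target draws a letter that breaks the match, so no accidental extra
    targets can arise; the whole sequence is nonetheless re-verified against
    the n-back rule.
    """
    if n_level not in NBACK_LENGTHS:
        raise InvalidInputError("n_level must be 0-3")
    length = NBACK_LENGTHS[n_level]
    if n_targets is None:
        n_targets = NBACK_DEFAULT_TARGETS[n_level]
    n_scorable = length - n_level if n_level >= 1 else length
    if not 0 <= n_targets <= n_scorable:
        raise InvalidInputError(
            f"level {n_level} admits 0-{n_scorable} targets, requested {n_targets}"
        )
    rng = _as_rng(rng_seed)
    eligible = np.arange(n_level if n_level >= 1 else 0, length)
    target_pos = set(rng.choice(eligible, size=n_targets, replace=False).tolist())
    pool = list(NBACK_LETTER_POOL)
    letters: list[str] = []
    if n_level == 0:
        for i in range(length):
            if i in target_pos:
                letters.append("X")
            else:
                letters.append(pool[rng.integers(len(pool))])
    else:
        for i in range(length):
            if i in target_pos:
                letters.append(letters[i - n_level])
            else:
                forbidden = letters[i - n_level] if i >= n_level else None
                ch = pool[rng.integers(len(pool))]
                while ch == forbidden:
                    ch = pool[rng.integers(len(pool))]
                letters.append(ch)
    flags = nback_scan(n_level, letters)
    assert sum(flags) == n_targets, "planted targets corrupted"
    return NBackSequence(
        n_level=n_level, letters=tuple(letters), is_target=tuple(flags)
    )


def score_nback(sequence: NBackSequence, touches: Iterable[int]) -> TestScore:
    """Score screen touches (positions) against the target flags.

    A touch on a target is a hit, on a non-target a false alarm; an untouched
    target is a miss.  ``n_correct`` counts hits plus correct rejections.
    """
    touched = set(touches)
    n = len(sequence.letters)
    for pos in touched:
        if not 0 <= pos < n:
            raise InvalidInputError(f"touched position {pos} out of range")
    hits = sum(1 for i in touched if sequence.is_target[i])
    false_alarms = len(touched) - hits
    n_targets = sum(sequence.is_target)
    misses = n_targets - hits
    correct_rejections = (n - n_targets) - false_alarms
    return TestScore(
        test_id="nback",
        part=sequence.n_level + 1,
        n_correct=hits + correct_rejections,
        n_incorrect=false_alarms + misses,
    )


# ---------------------------------------------------------------------------
# Serialization (schema-versioned JSON, one document per administration)
# ---------------------------------------------------------------------------

_KIND_TO_CLS = {
    "word_memory": WordMemoryStimulus,
    "trail_layout": TrailLayout,
    "stroop_panel": StroopPanel,
    "reaction_trials": ReactionTrialSet,
    "nback_sequence": NBackSequence,
}
_CLS_TO_KIND = {v: k for k, v in _KIND_TO_CLS.items()}


def stimulus_to_dict(stimulus) -> dict:
    kind = _CLS_TO_KIND.get(type(stimulus))
    if kind is None:
        raise InvalidInputError(f"unknown stimulus type {type(stimulus).__name__}")
    return {"schema_version": SCHEMA_VERSION, "kind": kind, "payload": asdict(stimulus)}


def stimulus_from_dict(doc: Mapping) -> object:
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise InvalidInputError(f"unsupported schema version {doc.get('schema_version')}")
    cls = _KIND_TO_CLS.get(doc.get("kind"))
    if cls is None:
        raise InvalidInputError(f"unknown stimulus kind {doc.get('kind')!r}")
    payload = dict(doc["payload"])

    def _tupled(value):
        if isinstance(value, list):
            return tuple(_tupled(v) for v in value)
        if isinstance(value, dict):
            return {k: _tupled(v) for k, v in value.items()}
        return value

    payload = {k: _tupled(v) for k, v in payload.items()}
    if cls is StroopPanel:
        payload["items"] = tuple(StroopItem(**it) for it in payload["items"])
    if cls is ReactionTrialSet:
        payload["trials"] = tuple(ReactionTrial(**tr) for tr in payload["trials"])
    return cls(**payload)


def stimulus_to_json(stimulus) -> str:
    return json.dumps(stimulus_to_dict(stimulus), sort_keys=True)


def stimulus_from_json(text: str):
    return stimulus_from_dict(json.loads(text))


def score_to_dict(score: TestScore) -> dict:
    return {k: v for k, v in asdict(score).items() if v is not None and v != []}
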