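"""Unit and property tests for the five test engines."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st_h

from cogbattery import battery
from cogbattery.battery import (
    generate_nback,
    generate_reaction_trials,
    generate_stroop_panel,
    generate_trail_part,
    generate_word_memory,
    nback_scan,
    score_nback,
    score_reaction,
    score_stroop,
    score_trail,
    score_word_memory,
    stimulus_from_json,
    stimulus_to_json,
    trail_sequence,
)
from cogbattery.errors import (
    IncompleteSessionError,
    InvalidInputError,
    LayoutInfeasibleError,
)

from conftest import nback_oracle


# ---------------------------------------------------------------------------
# Memory-Word
# ---------------------------------------------------------------------------


class TestWordMemory:
    @pytest.mark.parametrize("seed", [0, 1, 42])
    def test_structure(self, seed):
        stim = generate_word_memory(rng_seed=seed)
        assert len(stim.study_list) == 10
        assert len(stim.recognition_list) == 20
        assert sum(stim.is_old) == 10
        assert len(set(stim.recognition_list)) == 20
        old = {w for w, o in zip(stim.recognition_list, stim.is_old) if o}
        assert old == set(stim.study_list)

    def test_minimal_pool_exactly_20(self):
        pool = [f"w{i}" for i in range(20)]
        stim = generate_word_memory(pool, rng_seed=7)
        assert set(stim.recognition_list) == set(pool)

    def test_pool_too_small(self):
        with pytest.raises(InvalidInputError):
            generate_word_memory([f"w{i}" for i in range(19)], rng_seed=0)

    def test_seeded_determinism(self):
        a = generate_word_memory(rng_seed=11)
        b = generate_word_memory(rng_seed=11)
        c = generate_word_memory(rng_seed=12)
        assert a == b
        assert a != c

    def test_perfect_and_yes_sayer(self):
        stim = generate_word_memory(rng_seed=3)
        perfect = score_word_memory(stim, list(stim.is_old))
        assert (perfect.n_correct, perfect.n_incorrect) == (20, 0)
        yes = score_word_memory(stim, [True] * 20)
        assert yes.n_correct == 10  # 10 old accepted, 10 new falsely accepted

    def test_three_flips(self, rng):
        stim = generate_word_memory(rng_seed=5)
        responses = list(stim.is_old)
        for i in rng.choice(20, size=3, replace=False):
            responses[i] = not responses[i]
        # oracle: count agreement positions by enumeration
        expected = sum(r == o for r, o in zip(responses, stim.is_old))
        assert expected == 17
        assert score_word_memory(stim, responses).n_correct == 17

    def test_missing_responses(self):
        stim = generate_word_memory(rng_seed=5)
        with pytest.raises(IncompleteSessionError):
            score_word_memory(stim, [True] * 19)

    @given(st_h.lists(st_h.booleans(), min_size=20, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_correct_incorrect_complement(self, responses):
        stim = generate_word_memory(rng_seed=8)
        score = score_word_memory(stim, responses)
        assert score.n_correct + score.n_incorrect == 20


# ---------------------------------------------------------------------------
# Trail Making
# ---------------------------------------------------------------------------


class TestTrail:
    def test_sequences(self):
        assert trail_sequence(1) == [str(i) for i in range(1, 13)]
        assert trail_sequence(2) == list("ABCDEFGHIJKL")
        assert trail_sequence(3) == ["1", "A", "2", "B", "3", "C", "4", "D", "5", "E", "6", "F"]
        assert trail_sequence(4) == ["1", "Z", "2", "Y", "3", "X", "4", "W", "5", "V", "6", "U"]

    @pytest.mark.parametrize("part", [0, 5, -1])
    def test_bad_part(self, part):
        with pytest.raises(InvalidInputError):
            trail_sequence(part)

    @pytest.mark.parametrize("part", [3, 4])
    def test_alternation(self, part):
        seq = trail_sequence(part)
        numbers = seq[0::2]
        letters = seq[1::2]
        assert numbers == [str(i) for i in range(1, 7)]
        assert len(set(letters)) == 6 and all(c.isalpha() for c in letters)

    def test_layout_generation(self):
        layout = generate_trail_part(3, rng_seed=1)
        assert layout.labels == tuple(trail_sequence(3))
        pos = np.array(layout.positions)
        d = np.sqrt(((pos[:, None] - pos[None, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        assert d.min() > 2 * layout.radius

    def test_layout_determinism(self):
        assert generate_trail_part(2, rng_seed=9) == generate_trail_part(2, rng_seed=9)
        assert generate_trail_part(2, rng_seed=9) != generate_trail_part(2, rng_seed=10)

    def test_infeasible_radius(self):
        with pytest.raises(LayoutInfeasibleError):
            generate_trail_part(1, rng_seed=0, radius=0.4)

    def test_clean_run(self):
        layout = generate_trail_part(1, rng_seed=2)
        taps = [(1000.0 * (i + 1), i) for i in range(12)]
        score = score_trail(layout, taps, display_time_ms=0.0)
        assert score.completion_time_s == pytest.approx(12.0)
        assert score.n_errors == 0

    def test_wrong_taps_counted(self):
        layout = generate_trail_part(1, rng_seed=2)
        taps = [(1000.0 * (i + 1), i) for i in range(12)]
        taps.insert(3, (3500.0, 7))
        taps.insert(8, (7500.0, 11))
        score = score_trail(layout, taps)
        assert score.completion_time_s == pytest.approx(12.0)
        assert score.n_errors == 2

    def test_ignore_policy(self):
        layout = generate_trail_part(1, rng_seed=2)
        taps = [(1000.0 * (i + 1), i) for i in range(12)]
        taps.insert(3, (3500.0, 7))
        score = score_trail(layout, taps, wrong_tap_policy="ignore")
        assert score.n_errors == 0

    def test_duplicate_frame_collapsed(self):
        layout = generate_trail_part(1, rng_seed=2)
        taps = [(1000.0 * (i + 1), i) for i in range(12)]
        taps.insert(1, (1000.0, 5))  # same frame as the first tap: dropped
        score = score_trail(layout, taps)
        assert score.n_errors == 0

    def test_incomplete(self):
        layout = generate_trail_part(1, rng_seed=2)
        taps = [(1000.0 * (i + 1), i) for i in range(11)]
        with pytest.raises(IncompleteSessionError):
            score_trail(layout, taps)


# ---------------------------------------------------------------------------
# Stroop
# ---------------------------------------------------------------------------


class TestStroop:
    @pytest.mark.parametrize("part", [1, 2, 3])
    def test_thirty_items(self, part):
        assert len(generate_stroop_panel(part, rng_seed=0).items) == 30

    def test_part1_black_and_congruent(self):
        panel = generate_stroop_panel(1, rng_seed=1)
        for item in panel.items:
            assert item.display_color == "black"
            assert item.correct_answer == item.display_text

    def test_part2_blocks(self):
        panel = generate_stroop_panel(2, rng_seed=1)
        for item in panel.items:
            assert item.display_text is None
            assert item.correct_answer == item.display_color

    def test_part3_incongruent(self):
        panel = generate_stroop_panel(3, rng_seed=1)
        for item in panel.items:
            assert item.display_text != item.display_color
            assert item.correct_answer == item.display_color
            assert item.correct_answer in item.answer_options

    def test_too_few_colors(self):
        with pytest.raises(InvalidInputError):
            generate_stroop_panel(3, color_set=["red"], rng_seed=0)

    def test_scoring(self):
        panel = generate_stroop_panel(3, rng_seed=4)
        responses = [
            (item.correct_answer, 1500.0 * (i + 1))
            for i, item in enumerate(panel.items)
        ]
        score = score_stroop(panel, responses)
        assert score.n_correct == 30
        assert score.completion_time_s == pytest.approx(45.0)

    def test_mistakes_tallied(self):
        panel = generate_stroop_panel(1, rng_seed=4)
        responses = []
        for i, item in enumerate(panel.items):
            wrong = next(o for o in item.answer_options if o != item.correct_answer)
            responses.append((item.correct_answer if i < 14 else wrong, 1000.0 * i))
        score = score_stroop(panel, responses)
        assert (score.n_correct, score.n_incorrect) == (14, 16)

    def test_empty_responses(self):
        panel = generate_stroop_panel(1, rng_seed=4)
        with pytest.raises(IncompleteSessionError):
            score_stroop(panel, [])


# ---------------------------------------------------------------------------
# Reaction Time
# ---------------------------------------------------------------------------


class TestReaction:
    def test_part1_all_blue(self):
        trials = generate_reaction_trials(1, 10, rng_seed=0)
        assert all(t.target_type == "blue" for t in trials.trials)
        assert len(trials.trials) == 10

    @pytest.mark.parametrize("seed", range(5))
    def test_exactly_one_startle_on_blue(self, seed):
        trials = generate_reaction_trials(2, 10, rng_seed=seed)
        startles = [t for t in trials.trials if t.is_startle]
        assert len(startles) == 1
        assert startles[0].target_type == "blue"

    def test_part2_mix_deterministic(self):
        a = generate_reaction_trials(2, 10, rng_seed=5)
        b = generate_reaction_trials(2, 10, rng_seed=5)
        assert a == b
        types = {t.target_type for t in a.trials}
        assert "blue" in types

    def test_invalid_n_trials(self):
        with pytest.raises(InvalidInputError):
            generate_reaction_trials(1, 0, rng_seed=0)

    def test_latency_subtraction(self):
        trials = battery.ReactionTrialSet(
            part=1,
            trials=(
                battery.ReactionTrial(1000.0, "blue", is_startle=True),
                battery.ReactionTrial(2000.0, "blue"),
            ),
        )
        score = score_reaction(trials, {1: 2350.0})
        assert score.latencies_ms == [350.0]
        assert score.mean_latency_ms == pytest.approx(350.0)

    def test_commission_and_anticipatory(self):
        trials = battery.ReactionTrialSet(
            part=2,
            trials=(
                battery.ReactionTrial(1000.0, "blue", is_startle=True),
                battery.ReactionTrial(2000.0, "red"),
                battery.ReactionTrial(3000.0, "blue"),
            ),
        )
        # touch on red = commission error; touch 20 ms before cue = anticipatory
        score = score_reaction(trials, {0: 1400.0, 1: 2300.0, 2: 2980.0})
        assert score.n_commission_errors == 1
        assert score.n_anticipatory == 1
        assert score.latencies_ms == []  # trial 0 is the startle probe
        assert score.startle_time_ms == pytest.approx(400.0)

    def test_out_of_range_touch(self):
        trials = generate_reaction_trials(1, 3, rng_seed=0)
        with pytest.raises(InvalidInputError):
            score_reaction(trials, {5: 1000.0})


# ---------------------------------------------------------------------------
# Letter-N-Back
# ---------------------------------------------------------------------------


class TestNBack:
    @pytest.mark.parametrize("level,length", [(0, 11), (1, 11), (2, 15), (3, 20)])
    def test_lengths(self, level, length):
        assert len(generate_nback(level, rng_seed=1).letters) == length

    def test_level0_x_rule(self):
        seq = generate_nback(0, rng_seed=2)
        assert all(t == (ch == "X") for ch, t in zip(seq.letters, seq.is_target))

    def test_level2_planted_count_full_scan(self):
        seq = generate_nback(2, rng_seed=3, n_targets=3)
        matches = [
            i for i in range(len(seq.letters))
            if i >= 2 and seq.letters[i] == seq.letters[i - 2]
        ]
        assert len(matches) == 3

    def test_infeasible_target_count(self):
        with pytest.raises(InvalidInputError):
            generate_nback(3, rng_seed=0, n_targets=18)  # only 17 scorable slots

    @pytest.mark.parametrize("level", [0, 1, 2, 3])
    @pytest.mark.parametrize("seed", range(10))
    def test_oracle_equivalence(self, level, seed):
        seq = generate_nback(level, rng_seed=seed)
        assert list(seq.is_target) == nback_oracle(level, seq.letters)

    def test_scoring(self):
        seq = generate_nback(1, rng_seed=4)
        targets = {i for i, t in enumerate(seq.is_target) if t}
        exact = score_nback(seq, targets)
        assert exact.n_incorrect == 0
        nothing = score_nback(seq, set())
        assert nothing.n_incorrect == len(targets)  # every planted target missed
        everything = score_nback(seq, set(range(len(seq.letters))))
        assert everything.n_correct == len(targets)
        assert everything.n_incorrect == len(seq.letters) - len(targets)

    def test_level0_misses(self):
        seq = generate_nback(0, rng_seed=9, n_targets=4)
        score = score_nback(seq, set())
        assert score.n_incorrect == 4

    def test_out_of_range(self):
        seq = generate_nback(0, rng_seed=0)
        with pytest.raises(InvalidInputError):
            score_nback(seq, {99})


# ---------------------------------------------------------------------------
# Serialization and cross-cutting determinism
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "stim",
    [
        generate_word_memory(rng_seed=1),
        generate_trail_part(4, rng_seed=1),
        generate_stroop_panel(3, rng_seed=1),
        generate_reaction_trials(2, 8, rng_seed=1),
        generate_nback(3, rng_seed=1),
    ],
    ids=["word", "trail", "stroop", "reaction", "nback"],
)
def test_json_round_trip(stim):
    recovered = stimulus_from_json(stimulus_to_json(stim))
    assert recovered == stim


@pytest.mark.parametrize(
    "gen",
    [
        lambda s: generate_word_memory(rng_seed=s),
        lambda s: generate_trail_part(3, rng_seed=s),
        lambda s: generate_stroop_panel(2, rng_seed=s),
        lambda s: generate_reaction_trials(2, 10, rng_seed=s),
        lambda s: generate_nback(2, rng_seed=s),
    ],
    ids=["word", "trail", "stroop", "reaction", "nback"],
)
def test_generators_reproducible_and_seed_sensitive(gen):
    assert gen(123) == gen(123)
    assert any(gen(123) != gen(s) for s in (124, 125, 126))
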