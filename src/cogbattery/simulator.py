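"""Synthetic respondents for the smartphone cognitive battery.

The simulator draws a cohort of statistical responders, each defined by a
single latent ability scalar plus engagement parameters, and rolls them
through the reminder calendar.  It emulates the structure the validity and
learning analyses assume:

* one general latent ability drives both the conventional baseline scores and
  the smartphone scores, so the cross-instrument rank correlation is
  controlled by the instrument noise;
* timed tests (Stroop, Trail Making) improve additively with each attempt
  (practice effect); the other tests are stable by default;
* timed-score noise is additive lognormal (completion times are positive and
  right-skewed);
* each reminder is answered with a Bernoulli probability that decays slowly
  per week in study, and participants may drop out early (default 8% over the
  6-month follow-up);
* extra self-initiated sessions beyond the reminders occur at a
  participant-heterogeneous rate, so a minority of frequent users accumulate
  many attempts.

The agents have no cognitive architecture: no forgetting, no drift-diffusion;
they are draws from the statistical model the analyses are built to recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, InvalidInputError
from .scheduler import FOLLOW_UP_DAYS, ReminderSchedule

#: deterministic per-part offsets (s) added to a test's base completion time
PART_OFFSETS_S = {
    "stroop": {1: 0.0, 2: 3.0, 3: 10.0},
    "tmt": {1: 0.0, 2: 3.0, 3: 8.0, 4: 14.0},
}

#: scorable item counts per test part used for accuracy payloads
N_ITEMS = {
    "memory_word": {1: 20},
    "stroop": {1: 30, 2: 30, 3: 30},
    "tmt": {1: 12, 2: 12, 3: 12, 4: 12},
    "reaction": {1: 10, 2: 10},
    "nback": {1: 11, 2: 11, 3: 15, 4: 20},
}

DEFAULT_POPULATION: dict = {
    "ability_sd": 1.0,
    "base_speed_s": {"stroop": 20.0, "tmt": 16.0},
    "base_speed_sd": 3.0,
    "ability_loading_s": 4.0,
    "practice_slope_mean": {"stroop": -0.93, "tmt": -1.8},
    "practice_slope_sd": 0.3,
    "latency_sigma": 0.5,
    "noise_scale_s": 3.0,
    "p_adhere_mean": 0.72,
    "p_adhere_sd": 0.22,
    "adherence_decay": 0.99,
    "dropout_prob": 0.08,
    "mistake_rate_mean": 0.08,
    "mistake_rate_sd": 0.05,
    "p_confused_first": 0.08,
    "base_latency_ms": 450.0,
    "latency_loading_ms": 25.0,
    "extra_rate_median": 0.8,
    "extra_rate_log_sd": 1.0,
}

#: conventional baseline instruments: measure -> (base_s, ability_loading_s, noise_sd_s)
DEFAULT_CONVENTIONAL: dict[str, tuple[float, float, float]] = {
    "stroop_1": (45.0, 5.0, 6.0),
    "stroop_2": (55.0, 5.0, 6.0),
    "stroop_3": (85.0, 8.0, 9.0),
    "tmt_a": (35.0, 7.0, 8.0),
    "tmt_b": (80.0, 12.0, 14.0),
}


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _beta_params(mean: float, sd: float) -> tuple[float, float]:
    if not 0 < mean < 1:
        raise InvalidConfigError(f"beta mean must lie in (0,1), got {mean}")
    var = sd * sd
    if var >= mean * (1 - mean):
        raise InvalidConfigError(f"beta sd {sd} too large for mean {mean}")
    nu = mean * (1 - mean) / var - 1
    return mean * nu, (1 - mean) * nu


def _draw_prob(rng: np.random.Generator, mean: float, sd: float) -> float:
    if sd == 0:
        return float(mean)
    a, b = _beta_params(mean, sd)
    return float(rng.beta(a, b))


@dataclass(frozen=True)
class RespondentProfile:
    """Latent parameters of one simulated participant."""

    participant_id: int
    latent_ability: float
    base_speed_s: Mapping[str, float]  # per timed test, part-1 mean time
    practice_slope: Mapping[str, float]  # s per attempt (<= 0 is learning)
    latency_sd: float  # lognormal sigma of timed-score noise
    p_adhere_0: float
    adherence_decay: float  # multiplicative per week
    dropout_day: float | None
    mistake_rate: float
    base_latency_ms: float = 450.0
    confused_first: bool = False  # first Stroop attempt mostly wrong
    extra_rate: float = 0.0  # expected self-initiated sessions per test

    def __post_init__(self):
        for p in (self.p_adhere_0, self.adherence_decay, self.mistake_rate):
            if not 0 <= p <= 1:
                raise InvalidConfigError("probabilities must lie in [0, 1]")
        if any(v <= 0 for v in self.base_speed_s.values()):
            raise InvalidConfigError("base speeds must be positive")
        if self.dropout_day is not None and not 0 < self.dropout_day <= FOLLOW_UP_DAYS:
            raise InvalidConfigError("dropout_day must lie in (0, 182]")


@dataclass
class SessionRecord:
    """One scored part of one attempt, in analysis-ready long format."""

    participant_id: int
    test_id: str
    part: int
    attempt_index: int  # 1-based, per participant x test
    day: float  # days since baseline
    score: float  # seconds (timed), n_correct (accuracy), ms (reaction)
    n_correct: int | None = None
    n_items: int | None = None
    completed: bool = True

    def to_dict(self) -> dict:
        return asdict(self)


def sessions_to_frame(sessions: Sequence[SessionRecord]) -> pd.DataFrame:
    return pd.DataFrame([s.to_dict() for s in sessions])


def draw_cohort(
    n: int, rng_seed=None, population_config: Mapping | None = None
) -> list[RespondentProfile]:
    """Draw ``n`` respondent profiles from the population distributions."""
    if n < 1:
        raise InvalidInputError("cohort size must be >= 1")
    cfg = dict(DEFAULT_POPULATION)
    cfg.update(population_config or {})
    unknown = set(cfg) - set(DEFAULT_POPULATION)
    if unknown:
        raise InvalidConfigError(f"unknown population keys: {sorted(unknown)}")
    if cfg["ability_sd"] < 0 or cfg["base_speed_sd"] < 0 or cfg["latency_sigma"] < 0:
        raise InvalidConfigError("scale parameters must be non-negative")
    if not 0 < cfg["adherence_decay"] <= 1:
        raise InvalidConfigError("adherence_decay must lie in (0, 1]")
    rng = _as_rng(rng_seed)
    cohort = []
    for pid in range(1, n + 1):
        ability = float(rng.normal(0.0, cfg["ability_sd"]))
        base = {
            t: float(max(rng.normal(m, cfg["base_speed_sd"]), 2.0))
            for t, m in cfg["base_speed_s"].items()
        }
        slope = {
            t: float(rng.normal(m, cfg["practice_slope_sd"]))
            for t, m in cfg["practice_slope_mean"].items()
        }
        dropout = None
        if rng.random() < cfg["dropout_prob"]:
            dropout = float(rng.uniform(1.0, FOLLOW_UP_DAYS))
        if cfg["extra_rate_median"] > 0:
            extra = float(
                cfg["extra_rate_median"]
                * math.exp(rng.normal(0.0, cfg["extra_rate_log_sd"]))
            )
        else:
            extra = 0.0
        cohort.append(
            RespondentProfile(
                participant_id=pid,
                latent_ability=ability,
                base_speed_s=base,
                practice_slope=slope,
                latency_sd=cfg["latency_sigma"],
                p_adhere_0=_draw_prob(rng, cfg["p_adhere_mean"], cfg["p_adhere_sd"])
                if cfg["p_adhere_mean"] < 1
                else 1.0,
                adherence_decay=cfg["adherence_decay"],
                dropout_day=dropout,
                mistake_rate=_draw_prob(
                    rng, cfg["mistake_rate_mean"], cfg["mistake_rate_sd"]
                )
                if cfg["mistake_rate_mean"] > 0
                else 0.0,
                base_latency_ms=cfg["base_latency_ms"],
                confused_first=bool(rng.random() < cfg["p_confused_first"]),
                extra_rate=extra,
            )
        )
    return cohort


def _timed_score(
    profile: RespondentProfile,
    cfg_loading: float,
    noise_scale: float,
    test_id: str,
    part: int,
    attempt: int,
    rng: np.random.Generator,
    practice_tests: Sequence[str],
) -> float:
    base = profile.base_speed_s.get(test_id, 15.0) + PART_OFFSETS_S[test_id][part]
    slope = profile.practice_slope.get(test_id, 0.0) if test_id in practice_tests else 0.0
    noise = float(rng.lognormal(math.log(noise_scale), profile.latency_sd))
    score = base + slope * (attempt - 1) - cfg_loading * profile.latent_ability + noise
    return max(score, 1.0)


def simulate_sessions(
    cohort: Sequence[RespondentProfile],
    schedule: ReminderSchedule,
    rng_seed=None,
    ability_loading_s: float = 4.0,
    noise_scale_s: float = 3.0,
    latency_loading_ms: float = 25.0,
    practice_tests: Sequence[str] = ("stroop", "tmt"),
) -> list[SessionRecord]:
    """Roll the cohort through the reminder calendar.

    Each reminder in week ``w`` is answered with probability
    ``p_adhere_0 * adherence_decay**w``, only before the participant's dropout
    day; answered reminders land 0-3 days after the alert.  Self-initiated
    extra sessions arrive Poisson at the profile's ``extra_rate`` per test.
    Every session is expanded into one :class:`SessionRecord` per test part.
    """
    rng = _as_rng(rng_seed)
    records: list[SessionRecord] = []
    for profile in cohort:
        horizon = profile.dropout_day if profile.dropout_day is not None else FOLLOW_UP_DAYS
        for test_id in schedule.test_ids:
            days: list[float] = []
            for reminder_day in schedule.offsets[test_id]:
                if reminder_day >= horizon:
                    continue
                week = reminder_day // 7
                p = profile.p_adhere_0 * profile.adherence_decay**week
                if rng.random() < p:
                    days.append(float(reminder_day + rng.integers(0, 4)))
            if profile.extra_rate > 0:
                k = int(rng.poisson(profile.extra_rate))
                for _ in range(k):
                    days.append(float(rng.integers(1, int(horizon) + 1)))
            days = sorted(d for d in days if d < horizon)
            for attempt, day in enumerate(days, start=1):
                records.extend(
                    _score_session(
                        profile,
                        test_id,
                        attempt,
                        day,
                        rng,
                        ability_loading_s,
                        noise_scale_s,
                        latency_loading_ms,
                        practice_tests,
                    )
                )
    return records


def _score_session(
    profile: RespondentProfile,
    test_id: str,
    attempt: int,
    day: float,
    rng: np.random.Generator,
    ability_loading_s: float,
    noise_scale_s: float,
    latency_loading_ms: float,
    practice_tests: Sequence[str],
) -> list[SessionRecord]:
    out = []
    pid = profile.participant_id
    if test_id in ("stroop", "tmt"):
        for part, n_items in N_ITEMS[test_id].items():
            score = _timed_score(
                profile,
                ability_loading_s,
                noise_scale_s,
                test_id,
                part,
                attempt,
                rng,
                practice_tests,
            )
            p_ok = 1.0 - profile.mistake_rate
            if test_id == "stroop" and attempt == 1 and profile.confused_first:
                p_ok = 0.35  # mostly-wrong first attempt (misunderstood task)
            n_correct = int(rng.binomial(n_items, p_ok))
            out.append(
                SessionRecord(pid, test_id, part, attempt, day, score, n_correct, n_items)
            )
    elif test_id in ("memory_word", "nback"):
        for part, n_items in N_ITEMS[test_id].items():
            p_ok = float(
                np.clip(
                    1.0 - profile.mistake_rate + 0.02 * profile.latent_ability,
                    0.05,
                    1.0,
                )
            )
            n_correct = int(rng.binomial(n_items, p_ok))
            out.append(
                SessionRecord(
                    pid, test_id, part, attempt, day, float(n_correct), n_correct, n_items
                )
            )
    elif test_id == "reaction":
        for part, n_items in N_ITEMS["reaction"].items():
            noise = float(rng.lognormal(math.log(40.0), profile.latency_sd))
            latency = max(
                profile.base_latency_ms
                - latency_loading_ms * profile.latent_ability
                + noise,
                120.0,
            )
            n_correct = int(rng.binomial(n_items, 1.0 - profile.mistake_rate))
            out.append(
                SessionRecord(pid, test_id, part, attempt, day, latency, n_correct, n_items)
            )
    else:
        raise InvalidInputError(f"unknown test id {test_id!r}")
    return out


def simulate_conventional_baseline(
    cohort: Sequence[RespondentProfile],
    rng_seed=None,
    noise_config: Mapping[str, tuple[float, float, float]] | None = None,
) -> pd.DataFrame:
    """Simulate the paper-and-pencil baseline scores.

    Each measure is a monotone (affine decreasing) function of the same latent
    ability that drives the smartphone scores, plus independent Gaussian
    noise, so the induced cross-instrument rank correlation is governed by the
    noise standard deviations in ``noise_config``
    (measure -> (base_s, ability_loading_s, noise_sd_s)).
    Returns a long DataFrame (participant_id, measure, score).
    """
    if not cohort:
        raise InvalidInputError("cohort must be non-empty")
    cfg = dict(noise_config or DEFAULT_CONVENTIONAL)
    rng = _as_rng(rng_seed)
    rows = []
    for profile in cohort:
        for measure, (base, loading, noise_sd) in cfg.items():
            score = base - loading * profile.latent_ability + rng.normal(0.0, noise_sd)
            rows.append(
                {
                    "participant_id": profile.participant_id,
                    "measure": measure,
                    "score": float(max(score, 1.0)),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Calibrated designs for statistical validation
# ---------------------------------------------------------------------------


def spearman_to_pearson(rho_s: float) -> float:
    """Bivariate-normal conversion: the Pearson correlation that induces a
    population Spearman correlation ``rho_s`` (rho_s = (6/pi)·asin(r/2))."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def noise_sd_for_rho(rho_s: float) -> float:
    """Noise SD sigma such that two instruments ``ability + sigma*e`` (ability
    and e standard normal, independent) have population Spearman ``rho_s``."""
    if not 0 < rho_s < 1:
        raise InvalidInputError("target rho must lie in (0, 1)")
    r = spearman_to_pearson(rho_s)
    return math.sqrt(1.0 / r - 1.0)


def simulate_validity_pairs(
    n: int,
    population_rho: float,
    n_attempts: int = 4,
    rng_seed=None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Draw a conventional score and ``n_attempts`` smartphone attempt scores
    per participant, both ``ability + sigma*e`` with sigma calibrated so the
    conventional/first-attempt population Spearman equals ``population_rho``.

    Per-attempt noise is independent, so the mean over attempts is a less
    noisy ability readout and its correlation with the conventional score
    exceeds the first attempt's in expectation.
    """
    if n < 3:
        raise InvalidInputError("need at least 3 participants")
    rng = _as_rng(rng_seed)
    sigma = noise_sd_for_rho(population_rho)
    ability = rng.normal(0.0, 1.0, size=n)
    conventional = pd.Series(
        ability + sigma * rng.normal(0.0, 1.0, size=n), name="conventional"
    )
    attempts = pd.DataFrame(
        ability[:, None] + sigma * rng.normal(0.0, 1.0, size=(n, n_attempts)),
        columns=[f"attempt_{j + 1}" for j in range(n_attempts)],
    )
    return conventional, attempts


def simulate_learning_data(
    n_participants: int,
    n_attempts: int,
    beta0: float,
    beta1: float,
    sd_intercept: float,
    sd_slope: float,
    sd_resid: float,
    rng_seed=None,
) -> pd.DataFrame:
    """Balanced longitudinal draws from the random-intercept/random-slope model
    ``score = (beta0 + b0_i) + (beta1 + b1_i)·(attempt - 1) + eps`` used for
    parameter-recovery checks of the learning-trend fit."""
    if n_participants < 2 or n_attempts < 2:
        raise InvalidInputError("need >= 2 participants and >= 2 attempts")
    rng = _as_rng(rng_seed)
    b0 = rng.normal(0.0, sd_intercept, size=n_participants)
    b1 = rng.normal(0.0, sd_slope, size=n_participants)
    attempts = np.arange(1, n_attempts + 1)
    rows = []
    for i in range(n_participants):
        eps = rng.normal(0.0, sd_resid, size=n_attempts)
        scores = beta0 + b0[i] + (beta1 + b1[i]) * (attempts - 1) + eps
        for t, s in zip(attempts, scores):
            rows.append(
                {"participant_id": i + 1, "attempt_index": int(t), "score": float(s)}
            )
    return pd.DataFrame(rows)
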