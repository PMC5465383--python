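"""Reminder calendar and adherence computation.

The study protocol sends each participant at least four smartphone reminders
per cognitive test, evenly spread over a 6-month (182-day) follow-up.  The
default calendar reproduces the protocol's day offsets since baseline:

=================  ====================
Memory-Word        days 1, 29, 99, 169
Trail Making       days 2, 43, 113, 170
Stroop             days 3, 57, 127, 171
Reaction Time      days 4, 71, 141, 172
Letter-N-Back      days 15, 85, 155, 173
=================  ====================

Adherence is the fraction of reminders followed by an actual test performance
within one week; by default the window is the half-open interval
``[reminder_day, reminder_day + 7)`` (a closed upper bound is available via
``window_closed=True``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, InvalidInputError

if TYPE_CHECKING:  # pragma: no cover
    from .simulator import SessionRecord

FOLLOW_UP_DAYS = 182

DEFAULT_OFFSETS: dict[str, tuple[int, ...]] = {
    "memory_word": (1, 29, 99, 169),
    "tmt": (2, 43, 113, 170),
    "stroop": (3, 57, 127, 171),
    "reaction": (4, 71, 141, 172),
    "nback": (15, 85, 155, 173),
}


@dataclass(frozen=True)
class ReminderSchedule:
    """Per-test reminder day offsets since baseline plus the adherence window."""

    offsets: Mapping[str, tuple[int, ...]] = field(
        default_factory=lambda: dict(DEFAULT_OFFSETS)
    )
    adherence_window_days: int = 7
    window_closed: bool = False  # closed upper bound [d, d+w] instead of [d, d+w)

    def __post_init__(self):
        if self.adherence_window_days < 1:
            raise InvalidConfigError("adherence window must be at least 1 day")
        for test_id, days in self.offsets.items():
            if len(days) < 4:
                raise InvalidConfigError(
                    f"{test_id}: every test needs at least 4 reminders"
                )
            if any(b <= a for a, b in zip(days, days[1:])):
                raise InvalidConfigError(
                    f"{test_id}: reminder offsets must be strictly increasing"
                )
            if days[0] < 0 or days[-1] > FOLLOW_UP_DAYS:
                raise InvalidConfigError(
                    f"{test_id}: offsets must lie within the {FOLLOW_UP_DAYS}-day follow-up"
                )

    @property
    def test_ids(self) -> tuple[str, ...]:
        return tuple(self.offsets)

    def n_reminders(self, test_id: str) -> int:
        return len(self.offsets[test_id])

    def in_window(self, reminder_day: int, session_day: float) -> bool:
        hi = reminder_day + self.adherence_window_days
        if self.window_closed:
            return reminder_day <= session_day <= hi
        return reminder_day <= session_day < hi


def build_schedule(config: Mapping | None = None) -> ReminderSchedule:
    """Build the reminder schedule; defaults embed the protocol calendar.

    ``config`` may override ``offsets`` (mapping test id -> day list),
    ``adherence_window_days`` and ``window_closed``.
    """
    config = dict(config or {})
    offsets = {
        test: tuple(int(d) for d in days)
        for test, days in dict(config.pop("offsets", DEFAULT_OFFSETS)).items()
    }
    return ReminderSchedule(offsets=offsets, **config)


@dataclass
class AdherenceResult:
    """Adherence per participant and test, with cohort-level summaries.

    ``table`` is a participant x test DataFrame of adherence percentages;
    ``per_participant`` averages each participant's per-reminder indicator
    across all tests; ``per_test_mean``/``per_test_sd`` are cohort summaries.
    """

    table: pd.DataFrame
    n_reminders: dict[str, int]
    per_participant: pd.Series
    per_test_mean: pd.Series
    per_test_sd: pd.Series

    @property
    def cohort_mean_pct(self) -> float:
        return float(self.per_participant.mean())

    @property
    def cohort_sd_pct(self) -> float:
        return float(self.per_participant.std(ddof=1))


def _sessions_frame(sessions) -> pd.DataFrame:
    """Accept a list of SessionRecord-like objects or a long DataFrame."""
    if isinstance(sessions, pd.DataFrame):
        df = sessions
    else:
        df = pd.DataFrame(
            {
                "participant_id": [s.participant_id for s in sessions],
                "test_id": [s.test_id for s in sessions],
                "day": [s.day for s in sessions],
                "completed": [getattr(s, "completed", True) for s in sessions],
            }
        )
    required = {"participant_id", "test_id", "day"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"sessions missing columns: {sorted(missing)}")
    if "completed" in df.columns:
        df = df[df["completed"]]
    return df


def compute_adherence(
    schedule: ReminderSchedule,
    sessions,
    participants: Sequence | None = None,
) -> AdherenceResult:
    """Compute per-participant, per-test adherence to the reminder calendar.

    A reminder is adherent iff at least one completed session of that test
    falls inside its window; each session can satisfy at most one reminder
    (greedy earliest-reminder matching).  Sessions with a test id not in the
    schedule are ignored with a warning.  ``participants`` fixes the
    denominator population (participants without sessions score 0%).
    """
    import warnings

    df = _sessions_frame(sessions)
    unknown = set(df["test_id"]) - set(schedule.test_ids)
    if unknown:
        warnings.warn(f"ignoring sessions with unknown test ids: {sorted(unknown)}")
        df = df[df["test_id"].isin(schedule.test_ids)]
    if participants is None:
        participants = sorted(df["participant_id"].unique())
    rows = {}
    counts = {}  # (pid, test) -> n adherent
    grouped = df.groupby(["participant_id", "test_id"])["day"].apply(sorted).to_dict()
    for pid in participants:
        rows[pid] = {}
        for test_id in schedule.test_ids:
            days = list(grouped.get((pid, test_id), []))
            n_adherent = 0
            for reminder_day in schedule.offsets[test_id]:
                hit = next(
                    (d for d in days if schedule.in_window(reminder_day, d)), None
                )
                if hit is not None:
                    n_adherent += 1
                    days.remove(hit)  # one session satisfies at most one reminder
            counts[(pid, test_id)] = n_adherent
            rows[pid][test_id] = 100.0 * n_adherent / schedule.n_reminders(test_id)
    table = pd.DataFrame.from_dict(rows, orient="index")[list(schedule.test_ids)]
    table.index.name = "participant_id"
    total_reminders = sum(schedule.n_reminders(t) for t in schedule.test_ids)
    per_participant = pd.Series(
        {
            pid: 100.0
            * sum(counts[(pid, t)] for t in schedule.test_ids)
            / total_reminders
            for pid in participants
        },
        name="adherence_pct",
    )
    return AdherenceResult(
        table=table,
        n_reminders={t: schedule.n_reminders(t) for t in schedule.test_ids},
        per_participant=per_participant,
        per_test_mean=table.mean(axis=0),
        per_test_sd=table.std(axis=0, ddof=1),
    )


def ever_performed_fraction(sessions, n_participants: int) -> pd.Series:
    """Fraction of participants who performed each test at least once,
    irrespective of timing relative to the reminders."""
    if n_participants <= 0:
        raise InvalidInputError("n_participants must be positive")
    df = _sessions_frame(sessions)
    counts = df.groupby("test_id")["participant_id"].nunique()
    return (counts / n_participants).reindex(counts.index, fill_value=0.0)


def adherence_over_time(
    schedule: ReminderSchedule, sessions, participants: Sequence | None = None
) -> pd.DataFrame:
    """Cohort adherence percentage per test per reminder occasion (1..k).

    Mirrors the adherence-over-follow-up display: with waning engagement the
    later occasions show lower percentages.
    """
    df = _sessions_frame(sessions)
    df = df[df["test_id"].isin(schedule.test_ids)]
    if participants is None:
        participants = sorted(df["participant_id"].unique())
    n = len(participants)
    grouped = df.groupby(["participant_id", "test_id"])["day"].apply(sorted).to_dict()
    out = {}
    for test_id in schedule.test_ids:
        occ = np.zeros(schedule.n_reminders(test_id))
        for pid in participants:
            days = list(grouped.get((pid, test_id), []))
            for j, reminder_day in enumerate(schedule.offsets[test_id]):
                hit = next(
                    (d for d in days if schedule.in_window(reminder_day, d)), None
                )
                if hit is not None:
                    occ[j] += 1
                    days.remove(hit)
        out[test_id] = 100.0 * occ / max(n, 1)
    frame = pd.DataFrame.from_dict(out, orient="index")
    frame.columns = [f"reminder_{j + 1}" for j in range(frame.shape[1])]
    return frame
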