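"""Study configuration: schema, defaults and loading.

A :class:`StudyConfig` bundles everything a full pipeline run needs — the
reminder calendar, the population the simulator draws from, battery stimulus
defaults, the analysis options and the global seed.  Defaults reproduce the
study protocol (the five-test reminder calendar over a 6-month horizon,
n=151 participants).  Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from .errors import InvalidConfigError
from .scheduler import DEFAULT_OFFSETS
from .simulator import DEFAULT_POPULATION

logger = logging.getLogger("cogbattery")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ScheduleConfig(_Strict):
    offsets: dict[str, list[int]] = Field(
        default_factory=lambda: {t: list(d) for t, d in DEFAULT_OFFSETS.items()}
    )
    adherence_window_days: int = 7
    window_closed: bool = False

    @field_validator("offsets")
    @classmethod
    def _increasing(cls, v):
        for test, days in v.items():
            if any(b <= a for a, b in zip(days, days[1:])):
                raise ValueError(f"{test}: reminder offsets must be strictly increasing")
        return v


class BatteryConfig(_Strict):
    word_pool_path: Optional[str] = None  # None -> bundled pool
    presentation_pace_s: float = 2.0
    nback_targets: dict[int, int] = Field(
        default_factory=lambda: {0: 3, 1: 3, 2: 4, 3: 5}
    )
    stroop_colors: list[str] = Field(
        default_factory=lambda: ["red", "green", "blue", "yellow"]
    )
    reaction_n_trials: int = 10
    reaction_blue_fraction: float = 0.7
    reaction_cue_delay_s: tuple[float, float] = (1.0, 3.0)
    trail_radius: float = 0.05


class AnalysisConfig(_Strict):
    min_attempts: int = 9  # frequent-user threshold for the sensitivity fit
    pairing: dict[str, tuple[str, int]] = Field(
        default_factory=lambda: {
            "stroop_1": ("stroop", 1),
            "stroop_2": ("stroop", 2),
            "stroop_3": ("stroop", 3),
            "tmt_a": ("tmt", 1),
            "tmt_b": ("tmt", 3),
        }
    )
    mistake_threshold: float = 0.5  # minimum fraction correct for the filter


class StudyConfig(_Strict):
    seed: int = 0
    n_participants: int = 151
    schedule: ScheduleConfig = Field(default_factory=ScheduleConfig)
    population: dict = Field(default_factory=dict)  # overrides on the defaults
    battery: BatteryConfig = Field(default_factory=BatteryConfig)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)

    @field_validator("population")
    @classmethod
    def _known_population_keys(cls, v):
        unknown = set(v) - set(DEFAULT_POPULATION)
        if unknown:
            raise ValueError(f"unknown population keys: {sorted(unknown)}")
        return v

    @field_validator("n_participants")
    @classmethod
    def _positive_n(cls, v):
        if v < 1:
            raise ValueError("n_participants must be >= 1")
        return v


def load_config(path=None) -> StudyConfig:
    """Load and validate a YAML/JSON study config; ``None`` gives all defaults.

    An empty file also yields the defaults.  Schema violations raise
    :class:`InvalidConfigError` naming the offending keys.  The effective
    config is echoed to the package logger.
    """
    raw = {}
    if path is not None:
        text = Path(path).read_text(encoding="utf-8")
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise InvalidConfigError(f"config root must be a mapping, got {type(raw)}")
    try:
        cfg = StudyConfig.model_validate(raw)
    except ValidationError as exc:
        offenders = sorted(
            {".".join(str(p) for p in err["loc"]) or "<root>" for err in exc.errors()}
        )
        raise InvalidConfigError(
            f"invalid study config; offending keys: {offenders}"
        ) from exc
    logger.info("effective config: %s", json.dumps(cfg.model_dump(), sort_keys=True, default=str))
    return cfg
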