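"""End-to-end pipeline: simulate -> score -> adherence -> analyze.

One seed drives every stage; a manifest (package version, seed, effective
config, artifact hashes) makes reruns bit-identical and auditable.  Session
logs are JSON lines (one record per line), analysis tables are CSV.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .analysis import (
    bland_altman,
    repeat_effect_report,
    validity_report,
)
from .config import StudyConfig
from .errors import CogBatteryError, InsufficientDataError
from .scheduler import (
    ReminderSchedule,
    adherence_over_time,
    build_schedule,
    compute_adherence,
    ever_performed_fraction,
)
from .simulator import (
    SessionRecord,
    draw_cohort,
    sessions_to_frame,
    simulate_conventional_baseline,
    simulate_sessions,
)

logger = logging.getLogger("cogbattery")


# ---------------------------------------------------------------------------
# Readers / writers (round-trip safe)
# ---------------------------------------------------------------------------


def write_sessions_jsonl(sessions, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in sessions:
            fh.write(json.dumps(rec.to_dict(), sort_keys=True) + "\n")


def read_sessions_jsonl(path) -> list[SessionRecord]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                out.append(SessionRecord(**json.loads(line)))
    return out


def write_sessions_csv(sessions_frame: pd.DataFrame, path) -> None:
    sessions_frame.to_csv(path, index=False)


def read_sessions_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_conventional_csv(conventional: pd.DataFrame, path) -> None:
    conventional.to_csv(path, index=False)


def read_conventional_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# Pipeline stages
# ---------------------------------------------------------------------------


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive independent per-stage seeds from the global seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def simulate_stage(config: StudyConfig, out_dir: Path) -> dict:
    """Draw the cohort, roll it through the calendar, write the raw artifacts."""
    seed_cohort, seed_sessions, seed_conv = _spawn_seeds(config.seed, 3)
    schedule = build_schedule(config.schedule.model_dump())
    cohort = draw_cohort(config.n_participants, seed_cohort, config.population)
    sessions = simulate_sessions(cohort, schedule, seed_sessions)
    conventional = simulate_conventional_baseline(cohort, seed_conv)
    frame = sessions_to_frame(sessions)
    write_sessions_jsonl(sessions, out_dir / "sessions.jsonl")
    write_sessions_csv(frame, out_dir / "sessions.csv")
    write_conventional_csv(conventional, out_dir / "conventional.csv")
    logger.info(
        "simulated %d participants, %d session records", len(cohort), len(sessions)
    )
    return {
        "schedule": schedule,
        "cohort": cohort,
        "sessions": frame,
        "conventional": conventional,
    }


def adherence_stage(
    schedule: ReminderSchedule,
    sessions: pd.DataFrame,
    participants,
    out_dir: Path,
) -> dict:
    """Adherence per participant x test, cohort summaries, ever-performed."""
    result = compute_adherence(schedule, sessions, participants=participants)
    result.table.round(6).to_csv(out_dir / "adherence.csv")
    over_time = adherence_over_time(schedule, sessions, participants=participants)
    ever = ever_performed_fraction(sessions, len(participants))
    summary = {
        "cohort_mean_pct": round(result.cohort_mean_pct, 6),
        "cohort_sd_pct": round(result.cohort_sd_pct, 6),
        "per_test_mean_pct": {
            t: round(float(v), 6) for t, v in result.per_test_mean.items()
        },
        "per_test_sd_pct": {
            t: round(float(v), 6) for t, v in result.per_test_sd.items()
        },
        "ever_performed_pct": {
            t: round(100.0 * float(v), 6) for t, v in ever.items()
        },
        "adherence_over_time_pct": {
            t: [round(float(v), 6) for v in row]
            for t, row in over_time.iterrows()
        },
    }
    (out_dir / "adherence_summary.json").write_text(
        json.dumps(summary, sort_keys=True, indent=2) + "\n", encoding="utf-8"
    )
    logger.info("adherence: cohort mean %.1f%%", result.cohort_mean_pct)
    return {"adherence": result, "summary": summary}


def analysis_stage(
    config: StudyConfig,
    sessions: pd.DataFrame,
    conventional: pd.DataFrame,
    out_dir: Path,
) -> dict:
    """Relative validity, Bland-Altman agreement, learning-trend fits."""
    pairing = config.analysis.pairing
    report = validity_report(conventional, sessions, pairing)
    report.table.round(6).to_csv(out_dir / "validity.csv", index=False)

    agreement_rows = []
    for measure, (test_id, part) in pairing.items():
        sub = sessions[(sessions["test_id"] == test_id) & (sessions["part"] == part)]
        firsts = sub[sub["attempt_index"] == 1].set_index("participant_id")["score"]
        conv = conventional[conventional["measure"] == measure].set_index(
            "participant_id"
        )["score"]
        merged = pd.concat({"c": conv, "s": firsts}, axis=1, join="inner").dropna()
        ba = bland_altman(merged["c"], merged["s"])
        agreement_rows.append(
            {
                "measure": measure,
                "n": len(merged),
                "mean_difference": ba.mean_difference,
                "sd_difference": ba.sd_difference,
                "loa_lower": ba.limits_of_agreement[0],
                "loa_upper": ba.limits_of_agreement[1],
            }
        )
    pd.DataFrame(agreement_rows).round(6).to_csv(
        out_dir / "agreement.csv", index=False
    )

    timed = sessions[sessions["test_id"].isin(["stroop", "tmt"])]
    subset_insufficient = False
    try:
        trends = repeat_effect_report(timed, min_attempts=config.analysis.min_attempts)
    except InsufficientDataError:
        subset_insufficient = True
        trends = repeat_effect_report(timed, min_attempts=1)
    trend_doc = {
        "min_attempts": config.analysis.min_attempts,
        "subset_insufficient": subset_insufficient,
        "fits": json.loads(trends.round(6).to_json(orient="records")),
    }
    (out_dir / "trends.json").write_text(
        json.dumps(trend_doc, sort_keys=True, indent=2) + "\n", encoding="utf-8"
    )
    return {"validity": report, "agreement": agreement_rows, "trends": trends}


def run_pipeline(config: StudyConfig, out_dir, plots: bool = False) -> dict:
    """Execute simulate -> adherence -> analyze under the config's seed.

    Writes all artifacts plus ``manifest.json`` into ``out_dir``.  On any
    stage failure a ``_FAILED`` marker naming the stage is left beside the
    partial artifacts and the error is re-raised.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise CogBatteryError(f"output directory not writable: {exc}") from exc

    stage = "simulate"
    try:
        sim = simulate_stage(config, out_dir)
        participants = [p.participant_id for p in sim["cohort"]]
        stage = "adherence"
        adherence_stage(sim["schedule"], sim["sessions"], participants, out_dir)
        stage = "analyze"
        analysis_stage(config, sim["sessions"], sim["conventional"], out_dir)
        if plots:
            stage = "plots"
            from .analysis import plot_adherence_over_time

            plot_adherence_over_time(
                adherence_over_time(
                    sim["schedule"], sim["sessions"], participants=participants
                ),
                out_dir / "adherence.png",
            )
    except Exception as exc:
        (out_dir / "_FAILED").write_text(
            f"stage: {stage}\nerror: {exc}\n", encoding="utf-8"
        )
        raise

    artifacts = sorted(
        p.name
        for p in out_dir.iterdir()
        if p.is_file() and p.name not in ("manifest.json", "_FAILED")
    )
    manifest = {
        "package": "cogbattery",
        "version": __version__,
        "seed": config.seed,
        "config": config.model_dump(mode="json"),
        "artifacts": {name: _sha256(out_dir / name) for name in artifacts},
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=2, default=str) + "\n",
        encoding="utf-8",
    )
    return manifest
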