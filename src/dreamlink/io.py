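"""Interchange formats: hypnogram/trial CSV, event-log JSON, run configs,
and loaders for the packaged published-table fixtures."""

from __future__ import annotations

import dataclasses
import json
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .codec import Direction, Muscle
from .consensus import TaskKind, TrialRecord
from .psg_sim import (
    STAGES,
    AnswerSignalTruth,
    Confidence,
    EventLog,
    Hypnogram,
    MuscleSignalTruth,
    RaterJudgment,
)
from .edf import export_edf, import_edf  # re-exported: spec io surface

__all__ = [
    "read_hypnogram",
    "write_hypnogram",
    "export_edf",
    "import_edf",
    "event_log_to_json",
    "event_log_from_json",
    "read_trials",
    "write_trials",
    "load_table1",
    "load_table2",
    "load_control_trials",
    "load_control_outcomes",
    "load_sham_facial",
    "RunConfig",
    "load_config",
]

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# Hypnograms (CSV: epoch_index, scorer1..scorerN[, truth])
# ---------------------------------------------------------------------------


def write_hypnogram(hyp: Hypnogram, path: PathLike) -> None:
    cols = {"epoch_index": range(hyp.n_epochs)}
    for i, track in enumerate(hyp.scorers, start=1):
        cols[f"scorer{i}"] = list(track)
    if hyp.truth is not None:
        cols["truth"] = list(hyp.truth)
    pd.DataFrame(cols).to_csv(path, index=False)


def read_hypnogram(path: PathLike) -> Hypnogram:
    df = pd.read_csv(path)
    scorer_cols = [c for c in df.columns if c.startswith("scorer")]
    if not scorer_cols:
        raise ValueError(f"{path}: no scorer columns found")
    for col in scorer_cols + (["truth"] if "truth" in df.columns else []):
        for row_idx, token in enumerate(df[col]):
            if token not in STAGES:
                raise ValueError(
                    f"{path}: unknown stage {token!r} in column {col}, row {row_idx}"
                )
    scorers = tuple(tuple(df[c]) for c in scorer_cols)
    truth = tuple(df["truth"]) if "truth" in df.columns else None
    return Hypnogram(scorers, truth=truth)


# ---------------------------------------------------------------------------
# Event logs (JSON)
# ---------------------------------------------------------------------------


def event_log_to_json(log: EventLog, path: Optional[PathLike] = None) -> str:
    def _sig(s):
        d = dataclasses.asdict(s)
        if "directions" in d:
            d["directions"] = "".join(x.value for x in s.directions)
        if "muscle" in d and d["muscle"] is not None:
            d["muscle"] = s.muscle.value
        return d

    payload = {
        "stimuli": [dataclasses.asdict(e) for e in log.stimuli],
        "answers": [_sig(s) for s in log.answers],
        "muscle_answers": [_sig(s) for s in log.muscle_answers],
        "lucidity": [_sig(s) for s in log.lucidity],
        "arousals": list(log.arousals),
    }
    text = json.dumps(payload, indent=2, sort_keys=True, default=str)
    if path is not None:
        Path(path).write_text(text)
    return text


def event_log_from_json(source: PathLike) -> EventLog:
    payload = json.loads(Path(source).read_text())

    def _eye(d):
        return AnswerSignalTruth(
            stimulus_index=d["stimulus_index"],
            onset_s=d["onset_s"],
            directions=tuple(Direction(c) for c in d["directions"]),
            amplitude_uv=d["amplitude_uv"],
            kind=d.get("kind", "answer"),
        )

    muscles = tuple(
        MuscleSignalTruth(
            d["stimulus_index"], d["onset_s"], Muscle(d["muscle"]),
            d["contraction_count"], d["amplitude_uv"],
        )
        for d in payload.get("muscle_answers", [])
    )
    return EventLog(
        stimuli=(),
        answers=tuple(_eye(d) for d in payload.get("answers", [])),
        muscle_answers=muscles,
        lucidity=tuple(_eye(d) for d in payload.get("lucidity", [])),
        arousals=tuple(payload.get("arousals", [])),
    )


# ---------------------------------------------------------------------------
# Trials (CSV, one row per trial)
# ---------------------------------------------------------------------------

_NONE_TOKEN = "NONE"


def write_trials(trials: list[TrialRecord], path: PathLike) -> None:
    rows = []
    for t in trials:
        row: dict = {
            "trial_id": t.trial_id,
            "task": t.task.value,
            "team_design": t.team_design,
            "expected": t.expected_count if t.expected_count is not None else _NONE_TOKEN,
            "expected_muscle": t.expected_muscle.value if t.expected_muscle else "",
            "svld": t.svld,
        }
        for i, j in enumerate(t.judgments, start=1):
            row[f"count{i}"] = j.count if j.count is not None else _NONE_TOKEN
            row[f"conf{i}"] = j.confidence.value
            row[f"muscle{i}"] = j.muscle.value if j.muscle else ""
        for i, s in enumerate(t.stage_labels, start=1):
            row[f"stage{i}"] = s
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_trials(path: PathLike) -> list[TrialRecord]:
    df = pd.read_csv(path, keep_default_na=False)
    trials = []
    for _, row in df.iterrows():
        judgments = []
        for i in range(1, 5):
            raw = str(row[f"count{i}"])
            count = None if raw == _NONE_TOKEN else int(float(raw))
            muscle = Muscle(row[f"muscle{i}"]) if row.get(f"muscle{i}") else None
            judgments.append(
                RaterJudgment(i - 1, count, muscle, Confidence(row[f"conf{i}"]))
            )
        expected_raw = str(row["expected"])
        trials.append(
            TrialRecord(
                trial_id=str(row["trial_id"]),
                task=TaskKind(row["task"]),
                expected_count=None if expected_raw == _NONE_TOKEN else int(float(expected_raw)),
                judgments=tuple(judgments),
                stage_labels=(str(row["stage1"]), str(row["stage2"]), str(row["stage3"])),
                svld=str(row["svld"]).lower() in ("true", "1"),
                team_design=str(row.get("team_design", "")),
                expected_muscle=Muscle(row["expected_muscle"]) if row.get("expected_muscle") else None,
            )
        )
    return trials


# ---------------------------------------------------------------------------
# Packaged published-table fixtures
# ---------------------------------------------------------------------------


def _fixture(name: str) -> pd.DataFrame:
    with resources.files("dreamlink.data").joinpath(name).open("r") as f:
        return pd.read_csv(f)


def load_table1() -> pd.DataFrame:
    """Per-team session funnel: TWC sessions, REM sessions, SVLD sessions, trials."""
    return _fixture("table1_sessions.csv")


def load_table2() -> pd.DataFrame:
    """Per-team/task outcome counts for gated two-way-communication trials."""
    return _fixture("table2_trial_outcomes.csv")


def load_control_trials() -> pd.DataFrame:
    """Per-team counts of non-lucid REM control attempts."""
    return _fixture("control_trials.csv")


def load_control_outcomes() -> pd.DataFrame:
    """Aggregate outcomes of the non-lucid REM control attempts."""
    return _fixture("control_outcomes.csv")


def load_sham_facial() -> pd.DataFrame:
    """Sham-marker control of the facial task: markers added, contractions seen."""
    return _fixture("sham_facial.csv")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


class TimingOverrides(BaseModel):
    model_config = ConfigDict(extra="forbid")
    dot_ms: float = 300.0
    dash_ms: float = 900.0
    intra_gap_ms: float = 300.0
    char_gap_ms: float = 3000.0
    answer_window_s: float = 20.0


class DetectorConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    k_mad: float = 2.5
    refractory_s: float = 0.3
    smooth_s: float = 0.1
    baseline_s: float = 60.0
    max_train_gap_s: float = 2.0


class SimulatorConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    signal_to_background_ratio: float = 3.0
    rater_p_correct: float = 1.0
    scorer_confusion_p: float = 0.0
    duration_s: float = 120.0


class RunConfig(BaseModel):
    """Schema-validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    design: str = "usa_tlr"
    seed: int = 0
    timing: TimingOverrides = Field(default_factory=TimingOverrides)
    detector: DetectorConfig = Field(default_factory=DetectorConfig)
    simulator: SimulatorConfig = Field(default_factory=SimulatorConfig)
    out_dir: str = "dreamlink_out"


def load_config(path: PathLike) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig(**raw)
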