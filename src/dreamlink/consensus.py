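"""Trial classification by multi-rater consensus, with REM gating.

A trial carries four judgments (three independent raters plus the original
experimenter rating). Only high-confidence judgments count; the agreement
thresholds stay absolute (at least 3 of the 4, or 2 no-response raters), so
low-confidence abstentions can only push a trial toward AMBIGUOUS.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

from .codec import Direction, Muscle
from .psg_sim import Confidence, EventLog, Hypnogram, RaterJudgment

__all__ = [
    "GateStatus",
    "OutcomeCategory",
    "Outcome",
    "TaskKind",
    "TrialRecord",
    "gate_trial",
    "classify_eye_trial",
    "classify_facial_trial",
    "classify_trial",
    "detect_svld",
]


class GateStatus(str, Enum):
    INCLUDED = "INCLUDED"
    EXCLUDED_NOT_REM = "EXCLUDED_NOT_REM"
    EXCLUDED_NOT_SVLD = "EXCLUDED_NOT_SVLD"


class OutcomeCategory(str, Enum):
    CORRECT = "CORRECT"
    INCORRECT = "INCORRECT"
    AMBIGUOUS = "AMBIGUOUS"
    NO_RESPONSE = "NO_RESPONSE"


class TaskKind(str, Enum):
    MATH = "MATH"
    COUNT_TACTILE = "COUNT_TACTILE"
    SOUND_DISC = "SOUND_DISC"
    LIGHT_DISC = "LIGHT_DISC"
    SEMANTIC = "SEMANTIC"
    YES_NO = "YES_NO"


@dataclass(frozen=True)
class Outcome:
    category: OutcomeCategory
    gate: GateStatus

    @property
    def counted(self) -> bool:
        return self.gate is GateStatus.INCLUDED


@dataclass(frozen=True)
class TrialRecord:
    trial_id: str
    task: TaskKind
    expected_count: Optional[int]
    judgments: tuple[RaterJudgment, ...]
    stage_labels: tuple[str, str, str]
    svld: bool
    team_design: str = ""
    expected_muscle: Optional[Muscle] = None

    def __post_init__(self) -> None:
        if len(self.judgments) != 4:
            raise ValueError("a trial carries exactly 4 judgments")


def gate_trial(stage_labels: Sequence[str], svld: bool) -> GateStatus:
    """Admit a trial iff >=2 of 3 scorers called REM and the session is SVLD."""
    if len(stage_labels) != 3:
        raise ValueError(f"expected 3 scorer labels, got {len(stage_labels)}")
    n_rem = sum(1 for s in stage_labels if s == "REM")
    if n_rem < 2:
        return GateStatus.EXCLUDED_NOT_REM
    if not svld:
        return GateStatus.EXCLUDED_NOT_SVLD
    return GateStatus.INCLUDED


def _usable_counts(judgments: Sequence[RaterJudgment]) -> list[Optional[int]]:
    return [j.count for j in judgments if j.confidence is Confidence.HIGH]


def classify_eye_trial(
    expected: int, judgments: Sequence[RaterJudgment]
) -> OutcomeCategory:
    """Four-way classification of an eye-movement trial.

    Cascade: CORRECT (>=3 agree the count matched), INCORRECT (>=3 agree on
    one other count), NO_RESPONSE (>=3 saw no signal), then the ambiguous
    clauses (>=3 saw a response without count agreement, or 2 saw none);
    anything left is AMBIGUOUS.
    """
    if len(judgments) != 4:
        raise ValueError("exactly 4 judgments required")
    counts = _usable_counts(judgments)
    tally = Counter(counts)
    n_none = tally.get(None, 0)

    if tally.get(expected, 0) >= 3:
        return OutcomeCategory.CORRECT
    for value, k in tally.items():
        if value is not None and value != expected and k >= 3:
            return OutcomeCategory.INCORRECT
    if n_none >= 3:
        return OutcomeCategory.NO_RESPONSE
    # >=3 saw a response but disagreed on count, or 2 saw none, or no rule fits
    return OutcomeCategory.AMBIGUOUS


def classify_facial_trial(
    expected_muscle: Muscle,
    judgments: Sequence[RaterJudgment],
    expected_count: int = 2,
) -> OutcomeCategory:
    """Facial-muscle variant: majority over (muscle, count) tuples.

    CORRECT when >=3 agree the expected muscle contracted the expected number
    of times (twice), INCORRECT when >=3 agree the wrong muscle contracted
    twice, NO_RESPONSE when >=3 saw no contraction; a count other than two or
    any disagreement yields AMBIGUOUS.
    """
    if len(judgments) != 4:
        raise ValueError("exactly 4 judgments required")
    usable = [j for j in judgments if j.confidence is Confidence.HIGH]
    tuples = [(j.muscle, j.count) if j.count is not None else None for j in usable]
    tally = Counter(tuples)
    other = Muscle.CORRUGATOR if expected_muscle is Muscle.ZYGOMATIC else Muscle.ZYGOMATIC

    if tally.get((expected_muscle, expected_count), 0) >= 3:
        return OutcomeCategory.CORRECT
    if tally.get((other, expected_count), 0) >= 3:
        return OutcomeCategory.INCORRECT
    if tally.get(None, 0) >= 3:
        return OutcomeCategory.NO_RESPONSE
    return OutcomeCategory.AMBIGUOUS


def classify_trial(trial: TrialRecord) -> Outcome:
    """Gate then classify one trial; excluded trials keep their gate status."""
    gate = gate_trial(trial.stage_labels, trial.svld)
    if trial.expected_muscle is not None and trial.task is not TaskKind.COUNT_TACTILE:
        category = classify_facial_trial(trial.expected_muscle, trial.judgments)
    else:
        if trial.expected_count is None:
            raise ValueError("eye/tactile-count trial needs an expected count")
        category = classify_eye_trial(trial.expected_count, trial.judgments)
    return Outcome(category, gate)


DEFAULT_LUCIDITY_PATTERN = (
    Direction.L, Direction.R, Direction.L, Direction.R, Direction.L, Direction.R,
)


def detect_svld(
    event_log: EventLog,
    hypnogram: Optional[Hypnogram] = None,
    pattern: tuple[Direction, ...] = DEFAULT_LUCIDITY_PATTERN,
    require_rem: bool = True,
    before_s: Optional[float] = None,
) -> bool:
    """Signal-verified lucid dreaming: did a lucidity train occur (in REM)?

    True iff the log contains a lucidity signal matching the team's
    pre-arranged pattern whose onset epoch was scored REM by a majority of
    scorers (when ``require_rem`` and a hypnogram are given), optionally
    before a cutoff time.
    """
    for sig in event_log.lucidity:
        if tuple(sig.directions) != tuple(pattern):
            continue
        if before_s is not None and sig.onset_s > before_s:
            continue
        if require_rem and hypnogram is not None:
            labels = hypnogram.labels_at(sig.onset_s)
            n_rem = sum(1 for s in labels if s == "REM")
            if n_rem < (len(labels) // 2 + 1):
                continue
        return True
    return False
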