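"""Session designs: problem generation and timed stimulus scheduling.

Four designs are modeled: spoken math with counted-LR answers during
cue-triggered lucidity (USA, Netherlands), Morse-coded math over tones or
lights with gaze answers across a full night (Germany), and blocked spoken
words answered with facial-muscle codes during daytime naps (France).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Iterable, Optional, Sequence, Union

import numpy as np

from .codec import CodeKind, TimingParams, encode_morse, pulse_train, train_duration_ms

__all__ = [
    "Operator",
    "ProblemScheme",
    "Modality",
    "SessionDesign",
    "Problem",
    "StimulusEvent",
    "StimulusSchedule",
    "FrenchSession",
    "GermanHooks",
    "GermanNightConfig",
    "GermanNightResult",
    "SessionState",
    "generate_problem",
    "schedule_tlr_cues",
    "schedule_french_session",
    "run_german_night",
]

RngLike = Union[int, np.random.Generator]


def _rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


class Operator(str, Enum):
    PLUS = "PLUS"
    MINUS = "MINUS"


class ProblemScheme(str, Enum):
    USA_1_4 = "USA_1_4"          # spoken problems, solutions 1-4
    DE_FULL_0_9 = "DE_FULL_0_9"  # Morse problems, operands and solutions 0-9
    DE_SIMPLE_2_5 = "DE_SIMPLE_2_5"  # LR-count fallback, solutions 2-5
    NL = "NL"                    # spoken problems, counted-LR answers


class Modality(str, Enum):
    TONE = "TONE"
    LIGHT = "LIGHT"
    SPOKEN = "SPOKEN"
    TACTILE = "TACTILE"
    WORD = "WORD"


class SessionDesign(str, Enum):
    USA_TLR = "USA_TLR"
    DE_NIGHT = "DE_NIGHT"
    FR_BLOCKS = "FR_BLOCKS"
    NL_TLR = "NL_TLR"


_SOLUTION_RANGE = {
    ProblemScheme.USA_1_4: (1, 4),
    ProblemScheme.DE_FULL_0_9: (0, 9),
    ProblemScheme.DE_SIMPLE_2_5: (2, 5),
    ProblemScheme.NL: (1, 4),
}


@dataclass(frozen=True)
class Problem:
    operand_a: int
    operator: Operator
    operand_b: int
    solution: int
    scheme: ProblemScheme

    def __post_init__(self) -> None:
        expected = (
            self.operand_a + self.operand_b
            if self.operator is Operator.PLUS
            else self.operand_a - self.operand_b
        )
        if self.solution != expected:
            raise ValueError("solution does not match operands")
        lo, hi = _SOLUTION_RANGE[self.scheme]
        if not lo <= self.solution <= hi:
            raise ValueError(f"solution {self.solution} outside [{lo},{hi}] for {self.scheme.value}")
        if not (0 <= self.operand_a <= 9 and 0 <= self.operand_b <= 9):
            raise ValueError("operands must be in 0-9")

    @property
    def text(self) -> str:
        op = "plus" if self.operator is Operator.PLUS else "minus"
        return f"{self.operand_a} {op} {self.operand_b}"


def generate_problem(scheme: ProblemScheme, rng_seed: RngLike) -> Problem:
    """Draw a random arithmetic problem satisfying the scheme's constraints.

    Rejection sampling over operands 0-9 and both operators; deterministic
    given the seed.
    """
    rng = _rng(rng_seed)
    lo, hi = _SOLUTION_RANGE[scheme]
    while True:
        a = int(rng.integers(0, 10))
        b = int(rng.integers(0, 10))
        op = Operator.PLUS if rng.integers(0, 2) == 0 else Operator.MINUS
        sol = a + b if op is Operator.PLUS else a - b
        if lo <= sol <= hi:
            return Problem(a, op, b, sol, scheme)


@dataclass(frozen=True)
class StimulusEvent:
    onset_s: float
    modality: Modality
    payload: str
    intensity_level: int = 1
    expected_answer: Optional[int] = None
    code_kind: Optional[CodeKind] = None
    duration_s: float = 0.0


@dataclass(frozen=True)
class StimulusSchedule:
    events: tuple[StimulusEvent, ...]
    session_design: SessionDesign

    def __post_init__(self) -> None:
        onsets = [e.onset_s for e in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("stimulus onsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.events)


def schedule_tlr_cues(
    rem_onset_s: float,
    rem_duration_s: float,
    design: SessionDesign,
    rng_seed: RngLike = 0,
    max_cues: int = 10,
    arousal_windows: Sequence[tuple[float, float]] = (),
) -> StimulusSchedule:
    """Lay targeted-lucidity-reactivation cues over one REM period.

    USA design: ~30-s inter-cue intervals (uniform +/- 2 s jitter); NL design:
    uniform 10-15 s intervals. At most ``max_cues`` cues; cues falling inside
    an arousal window are suppressed (cueing pauses, then resumes).
    """
    if design not in (SessionDesign.USA_TLR, SessionDesign.NL_TLR):
        raise ValueError(f"TLR cueing undefined for design {design.value}")
    rng = _rng(rng_seed)
    events: list[StimulusEvent] = []
    t = rem_onset_s
    end = rem_onset_s + rem_duration_s
    while len(events) < max_cues:
        if design is SessionDesign.USA_TLR:
            gap = 30.0 + rng.uniform(-2.0, 2.0)
        else:
            gap = rng.uniform(10.0, 15.0)
        t += gap
        if t >= end:
            break
        if any(a <= t < b for a, b in arousal_windows):
            continue
        events.append(
            StimulusEvent(onset_s=t, modality=Modality.TONE, payload="TLR_CUE")
        )
    return StimulusSchedule(tuple(events), design)


@dataclass(frozen=True)
class FrenchSession:
    """Blocked word-stimulation plan: the schedule plus its OFF periods."""

    schedule: StimulusSchedule
    off_periods: tuple[tuple[float, float], ...]
    total_span_s: float


_FRENCH_WORDS = ("up", "down", "mixed")


def schedule_french_session(
    rng_seed: RngLike = 0,
    n_blocks: int = 10,
    stimuli_per_block: int = 6,
    isi_s: float = 10.0,
    jitter_s: float = 1.0,
    off_s: float = 60.0,
    start_s: float = 60.0,
) -> FrenchSession:
    """Build the blocked semantic-task session.

    Default: 10 blocks of 6 randomly chosen words at ~10-s intervals,
    separated by 1-min OFF periods, starting 1 min into the nap; the whole
    stimulation session spans ~20 min.
    """
    rng = _rng(rng_seed)
    block_span = stimuli_per_block * isi_s
    events: list[StimulusEvent] = []
    off_periods: list[tuple[float, float]] = []
    for k in range(n_blocks):
        block_start = start_s + k * (block_span + off_s)
        for j in range(stimuli_per_block):
            word = _FRENCH_WORDS[int(rng.integers(0, len(_FRENCH_WORDS)))]
            jit = rng.uniform(-jitter_s, jitter_s) if j > 0 else 0.0
            events.append(
                StimulusEvent(
                    onset_s=block_start + j * isi_s + jit,
                    modality=Modality.WORD,
                    payload=word,
                )
            )
        if k < n_blocks - 1:
            off_periods.append((block_start + block_span, block_start + block_span + off_s))
    total_span = n_blocks * block_span + (n_blocks - 1) * off_s
    return FrenchSession(
        StimulusSchedule(tuple(events), SessionDesign.FR_BLOCKS),
        tuple(off_periods),
        total_span_s=total_span,
    )


# ---------------------------------------------------------------------------
# German full-night state machine
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimEyeSignal:
    time_s: float
    kind: str  # "lucidity" | "answer"
    value: Optional[int] = None


@dataclass
class GermanHooks:
    """Simulated physiology streams driving the night scheduler.

    ``stage_at(t)`` returns the current stage label; ``arousal_at(t)`` flags
    micro-arousals; ``eye_signals`` lists volitional signals with onset times.
    """

    duration_s: float
    stage_at: Callable[[float], str]
    arousal_at: Callable[[float], bool] = lambda t: False
    eye_signals: Sequence[SimEyeSignal] = ()


@dataclass(frozen=True)
class GermanNightConfig:
    timing: TimingParams = TimingParams()
    tick_s: float = 0.1
    stable_rem_s: float = 300.0
    signal_timeout_s: float = 120.0
    scheme: ProblemScheme = ProblemScheme.DE_FULL_0_9
    stop_after_answer: bool = True
    tone_hz: tuple[int, int] = (470, 600)
    led_colors: tuple[str, str] = ("red", "green")


@dataclass
class SessionState:
    stage: str = "W"
    lucidity_signaled: bool = False
    arousal: bool = False
    last_signal_time_s: Optional[float] = None
    rem_entry_time_s: Optional[float] = None
    intensity_level: int = 0


@dataclass
class GermanNightResult:
    schedule: StimulusSchedule
    trace: list[tuple[float, str]]
    awakenings: list[float]
    problems: list[Problem]


def run_german_night(
    sim_hooks: GermanHooks, rng_seed: RngLike, config: GermanNightConfig = GermanNightConfig()
) -> GermanNightResult:
    """Drive the night protocol against simulated streams.

    Per REM period: a stimulation modality (tones or lights) is drawn at REM
    entry; Morse math problems start after 5 min of stable REM, or
    immediately after a lucidity signal. Stimulus intensity increments for
    each new problem; tone frequency / LED color alternate per problem.
    Stimulation stops on arousal or non-REM; 2 min after the last eye signal
    without an awakening, the sleeper is awoken (logged).
    """
    rng = _rng(rng_seed)
    cfg = config
    tick = cfg.tick_s
    events: list[StimulusEvent] = []
    problems: list[Problem] = []
    trace: list[tuple[float, str]] = []
    awakenings: list[float] = []
    state = SessionState()

    signals = sorted(sim_hooks.eye_signals, key=lambda s: s.time_s)
    sig_idx = 0
    modality = Modality.TONE
    # end of the problem currently being presented (stimulus + answer window)
    busy_until = -1.0
    problem_count_this_period = 0

    n_ticks = int(round(sim_hooks.duration_s / tick))
    for i in range(n_ticks):
        t = i * tick
        stage = sim_hooks.stage_at(t)
        arousal = bool(sim_hooks.arousal_at(t))

        if stage != state.stage:
            trace.append((t, f"stage:{stage}"))
            if stage == "REM":
                state.rem_entry_time_s = t
                problem_count_this_period = 0
                state.intensity_level = 0
                state.lucidity_signaled = False
                modality = Modality.TONE if rng.integers(0, 2) == 0 else Modality.LIGHT
                trace.append((t, f"modality:{modality.value}"))
            else:
                state.rem_entry_time_s = None
                busy_until = -1.0  # stimulation stops on non-REM
            state.stage = stage

        if arousal and not state.arousal:
            trace.append((t, "arousal"))
            busy_until = -1.0  # stimulation stops on arousal
            state.rem_entry_time_s = t if stage == "REM" else None
        state.arousal = arousal

        # consume eye signals occurring at or before this tick
        while sig_idx < len(signals) and signals[sig_idx].time_s <= t:
            sig = signals[sig_idx]
            sig_idx += 1
            state.last_signal_time_s = sig.time_s
            trace.append((sig.time_s, f"signal:{sig.kind}"))
            if sig.kind == "lucidity":
                state.lucidity_signaled = True
            elif sig.kind == "answer" and cfg.stop_after_answer:
                busy_until = -1.0  # stop current problem, move on

        # awaken on signal-free timeout
        if (
            state.last_signal_time_s is not None
            and t - state.last_signal_time_s >= cfg.signal_timeout_s
        ):
            awakenings.append(t)
            trace.append((t, "awaken"))
            state.last_signal_time_s = None
            state.lucidity_signaled = False
            busy_until = -1.0
            continue

        # present a new problem when eligible
        if stage == "REM" and not arousal and t >= busy_until:
            stable = (
                state.rem_entry_time_s is not None
                and t - state.rem_entry_time_s >= cfg.stable_rem_s
            )
            if stable or state.lucidity_signaled:
                problem = generate_problem(cfg.scheme, rng)
                problems.append(problem)
                state.intensity_level += 1
                seq = encode_morse(problem.text)
                dur_s = train_duration_ms(pulse_train(seq, cfg.timing)) / 1000.0
                alt = problem_count_this_period % 2
                payload = (
                    f"morse:{problem.text}|tone:{cfg.tone_hz[alt]}Hz"
                    if modality is Modality.TONE
                    else f"morse:{problem.text}|led:{cfg.led_colors[alt]}"
                )
                events.append(
                    StimulusEvent(
                        onset_s=t,
                        modality=modality,
                        payload=payload,
                        intensity_level=state.intensity_level,
                        expected_answer=problem.solution,
                        code_kind=CodeKind.MORSE_GAZE
                        if cfg.scheme is ProblemScheme.DE_FULL_0_9
                        else CodeKind.LR_COUNT,
                        duration_s=dur_s,
                    )
                )
                trace.append((t, f"problem:{problem.text}@{state.intensity_level}"))
                problem_count_this_period += 1
                busy_until = t + dur_s + cfg.timing.answer_window_s

    return GermanNightResult(
        StimulusSchedule(tuple(events), SessionDesign.DE_NIGHT), trace, awakenings, problems
    )
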