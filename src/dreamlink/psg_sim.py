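"""Synthetic polysomnography with ground-truth embedded answer signals.

Renders an 8-channel record (3 EEG, 2 horizontal EOG, chin EMG, corrugator
and zygomatic EMG) with REM-like background activity, plus hypnograms from
up to three imperfect scorers and simulated per-trial rater judgments.

Background model (qualitative only, parameters exposed): band-limited noise
per channel; spontaneous saccades arrive as a Poisson process and are mostly
common-mode across the two EOG channels (oblique/vertical movements), while
embedded volitional signals are large and fully mirrored (opposite polarity
on EOG_L vs EOG_R) so their differential amplitude stands far above
background.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Sequence, Union

import numpy as np
from scipy import signal as sps

from .codec import CodeKind, Direction, Muscle, encode_answer
from .protocol import StimulusSchedule

__all__ = [
    "CHANNELS",
    "STAGES",
    "Confidence",
    "PsgParams",
    "PsgRecord",
    "Hypnogram",
    "AnswerPlanItem",
    "LucidityPlanItem",
    "AnswerSignalTruth",
    "MuscleSignalTruth",
    "EventLog",
    "RaterJudgment",
    "RaterParams",
    "simulate_hypnogram",
    "render_record",
    "simulate_raters",
    "simulate_facial_raters",
]

RngLike = Union[int, np.random.Generator]

CHANNELS = ("EEG_F", "EEG_C", "EEG_O", "EOG_L", "EOG_R", "EMG_chin", "EMG_corr", "EMG_zyg")
STAGES = ("W", "N1", "N2", "N3", "REM")


def _rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


class Confidence(str, Enum):
    HIGH = "HIGH"
    MODERATE = "MODERATE"
    LOW = "LOW"


@dataclass(frozen=True)
class PsgParams:
    """Generative parameters; amplitudes in microvolts."""

    rate: int = 500
    eog_noise_uv: float = 10.0
    saccade_amp_uv: float = 40.0
    saccade_rate_rem_hz: float = 0.2
    saccade_rate_other_hz: float = 0.05
    saccade_conjugacy: tuple[float, float] = (0.8, 0.98)
    signal_to_background_ratio: float = 3.0
    eeg_noise_uv: float = 20.0
    chin_wake_uv: float = 15.0
    chin_rem_uv: float = 2.0
    chin_twitch_rate_hz: float = 0.02
    facial_noise_uv: float = 2.0
    facial_burst_uv: float = 60.0
    movement_s: float = 0.5          # one volitional eye movement (ramp-hold-return)
    movement_gap_s: float = 0.2
    burst_s: float = 0.3
    burst_gap_s: float = 0.5
    calibration_uv: float = 100.0


#: Display-filter conventions per channel family (Hz).
BAND_SETTINGS = {
    "EEG": (0.3, 15.0),
    "EOG": (0.3, 15.0),
    "EMG": (10.0, 100.0),
}


@dataclass
class PsgRecord:
    data: dict[str, np.ndarray]
    rate: int = 500
    band_settings: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(BAND_SETTINGS)
    )
    calibration_uv: float = 100.0

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        lengths = {len(v) for v in self.data.values()}
        if len(lengths) > 1:
            raise ValueError("all channels must have equal length")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.data.values()))) if self.data else 0

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate


@dataclass(frozen=True)
class Hypnogram:
    """Per-scorer 30-s epoch stage tracks, optionally with the true sequence."""

    scorers: tuple[tuple[str, ...], ...]
    truth: Optional[tuple[str, ...]] = None
    epoch_s: int = 30

    def __post_init__(self) -> None:
        if len(self.scorers) > 3:
            raise ValueError("at most 3 scorer tracks")
        lengths = {len(s) for s in self.scorers}
        if len(lengths) > 1:
            raise ValueError("scorer tracks must have equal length")
        for track in self.scorers:
            for st in track:
                if st not in STAGES:
                    raise ValueError(f"unknown stage {st!r}")

    @property
    def n_epochs(self) -> int:
        return len(self.scorers[0]) if self.scorers else 0

    def epoch_of(self, t_s: float) -> int:
        # epochs are half-open [30k, 30k+30)
        return int(t_s // self.epoch_s)

    def labels_at(self, t_s: float) -> tuple[str, ...]:
        k = self.epoch_of(t_s)
        return tuple(track[k] for track in self.scorers)


def simulate_hypnogram(
    mode: str = "normal",
    duration_min: float = 120.0,
    rem_latency_min: float = 68.0,
    rem_period_min: float = 20.0,
    cycle_min: float = 90.0,
    confusion_p: float = 0.0,
    n_scorers: int = 3,
    seed: RngLike = 0,
) -> Hypnogram:
    """Generate a plausible stage sequence and noisy scorer tracks.

    ``normal`` mode descends through N1/N2/N3 and reaches REM after
    ``rem_latency_min`` (default 68 min); ``narcolepsy`` mode enters REM
    within ~2 epochs of a daytime nap. Each scorer reproduces the true stage
    per epoch except with probability ``confusion_p``, in which case a
    uniformly random different stage is recorded.
    """
    rng = _rng(seed)
    n_epochs = max(1, int(round(duration_min * 60 / 30)))
    truth: list[str] = []
    if mode == "narcolepsy":
        # sleep-onset REM: brief wake, then REM for most of the nap
        for k in range(n_epochs):
            if k < 2:
                truth.append("W" if k == 0 else "REM")
            elif k < 2 + int(rem_period_min * 2):
                truth.append("REM")
            else:
                truth.append("N1" if k % 4 == 0 else "N2")
    elif mode == "normal":
        rem_lat_ep = int(rem_latency_min * 2)
        rem_len_ep = int(rem_period_min * 2)
        cycle_ep = int(cycle_min * 2)
        for k in range(n_epochs):
            if k < 2:
                truth.append("W")
            elif k < rem_lat_ep:
                frac = (k - 2) / max(1, rem_lat_ep - 2)
                truth.append("N1" if frac < 0.1 else ("N2" if frac < 0.5 else "N3"))
            else:
                pos = (k - rem_lat_ep) % cycle_ep
                truth.append("REM" if pos < rem_len_ep else "N2")
    else:
        raise ValueError(f"unknown hypnogram mode {mode!r}")

    scorers = []
    for _ in range(n_scorers):
        track = []
        for st in truth:
            if confusion_p > 0 and rng.random() < confusion_p:
                others = [s for s in STAGES if s != st]
                track.append(others[int(rng.integers(0, len(others)))])
            else:
                track.append(st)
        scorers.append(tuple(track))
    return Hypnogram(tuple(scorers), truth=tuple(truth))


# ---------------------------------------------------------------------------
# Record rendering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnswerPlanItem:
    """What the simulated dreamer does after one scheduled stimulus.

    ``kind``: "hit" renders the planned signal at full volitional amplitude,
    "miss" renders nothing, "distort" renders the sequence at background
    amplitude (indistinguishable from spontaneous movements).
    """

    stimulus_index: int
    kind: str = "hit"
    value: Optional[int] = None
    code_kind: CodeKind = CodeKind.LR_COUNT
    latency_s: float = 3.0
    muscle: Optional[Muscle] = None
    contraction_count: Optional[int] = None
    directions: Optional[tuple[Direction, ...]] = None


@dataclass(frozen=True)
class LucidityPlanItem:
    onset_s: float
    directions: tuple[Direction, ...] = (
        Direction.L, Direction.R, Direction.L, Direction.R, Direction.L, Direction.R,
    )


@dataclass(frozen=True)
class AnswerSignalTruth:
    stimulus_index: Optional[int]
    onset_s: float
    directions: tuple[Direction, ...]
    amplitude_uv: float
    kind: str = "answer"  # "answer" | "lucidity"


@dataclass(frozen=True)
class MuscleSignalTruth:
    stimulus_index: int
    onset_s: float
    muscle: Muscle
    contraction_count: int
    amplitude_uv: float


@dataclass
class EventLog:
    stimuli: tuple = ()
    answers: tuple[AnswerSignalTruth, ...] = ()
    muscle_answers: tuple[MuscleSignalTruth, ...] = ()
    lucidity: tuple[AnswerSignalTruth, ...] = ()
    arousals: tuple[float, ...] = ()


def _bandpass(x: np.ndarray, lo: float, hi: float, rate: int) -> np.ndarray:
    nyq = rate / 2
    sos = sps.butter(2, [lo / nyq, min(hi / nyq, 0.99)], btype="band", output="sos")
    return sps.sosfiltfilt(sos, x)


def _band_noise(rng: np.random.Generator, n: int, lo: float, hi: float, rate: int) -> np.ndarray:
    """Band-limited unit-variance noise (rescaled after filtering)."""
    x = _bandpass(rng.standard_normal(n), lo, hi, rate)
    sd = x.std()
    return x / sd if sd > 0 else x


def _eye_movement_template(direction: Direction, params: PsgParams, rate: int) -> np.ndarray:
    """Ramp-hold-return deflection; positive lobe = leftward by convention."""
    ramp = int(0.1 * rate)
    hold = int((params.movement_s - 0.2) * rate)
    tmpl = np.concatenate(
        [np.linspace(0, 1, ramp), np.ones(hold), np.linspace(1, 0, ramp)]
    )
    return tmpl if direction is Direction.L else -tmpl


def _saccade_template(rate: int) -> np.ndarray:
    n = int(0.25 * rate)
    return np.hanning(n)


def _stage_array(hypnogram: Optional[Hypnogram], n: int, rate: int) -> np.ndarray:
    """Per-sample true stage labels; all-REM when no hypnogram is given."""
    stages = np.full(n, "REM", dtype="<U3")
    if hypnogram is not None and hypnogram.truth is not None:
        per_epoch = hypnogram.epoch_s * rate
        for k, st in enumerate(hypnogram.truth):
            stages[k * per_epoch : (k + 1) * per_epoch] = st
    return stages


def render_record(
    schedule: StimulusSchedule,
    answer_plan: Sequence[AnswerPlanItem],
    params: PsgParams = PsgParams(),
    seed: RngLike = 0,
    hypnogram: Optional[Hypnogram] = None,
    lucidity_plan: Sequence[LucidityPlanItem] = (),
    duration_s: Optional[float] = None,
) -> tuple[PsgRecord, EventLog]:
    """Render the full multichannel record plus its exact ground truth.

    Every plan item must reference a stimulus present in the schedule.
    """
    rng = _rng(seed)
    p = params
    rate = p.rate
    for item in answer_plan:
        if not 0 <= item.stimulus_index < len(schedule.events):
            raise ValueError(f"answer plan references missing stimulus {item.stimulus_index}")

    if duration_s is None:
        last = max(
            [e.onset_s + e.duration_s for e in schedule.events] + [it.onset_s for it in lucidity_plan],
            default=0.0,
        )
        duration_s = max(60.0, last + 30.0)
    if hypnogram is not None:
        duration_s = max(duration_s, hypnogram.n_epochs * hypnogram.epoch_s)
    n = int(round(duration_s * rate))
    stage = _stage_array(hypnogram, n, rate)

    data: dict[str, np.ndarray] = {}

    # EEG: band-limited noise; alpha bump in W (occipital), theta in REM
    t_axis = np.arange(n) / rate
    for ch in ("EEG_F", "EEG_C", "EEG_O"):
        x = _band_noise(rng, n, *BAND_SETTINGS["EEG"], rate) * p.eeg_noise_uv
        if ch == "EEG_O":
            x = x + 8.0 * np.sin(2 * np.pi * 10 * t_axis + rng.uniform(0, 2 * np.pi)) * (
                stage == "W"
            )
        x = x + 5.0 * np.sin(2 * np.pi * 5 * t_axis + rng.uniform(0, 2 * np.pi)) * (
            stage == "REM"
        )
        data[ch] = x

    # EOG background: noise plus mostly-common-mode spontaneous saccades
    eog_l = _band_noise(rng, n, *BAND_SETTINGS["EOG"], rate) * p.eog_noise_uv
    eog_r = _band_noise(rng, n, *BAND_SETTINGS["EOG"], rate) * p.eog_noise_uv
    sac = _saccade_template(rate)
    i = 0
    while i < n:
        rate_hz = p.saccade_rate_rem_hz if stage[i] == "REM" else p.saccade_rate_other_hz
        gap = rng.exponential(1.0 / rate_hz) if rate_hz > 0 else np.inf
        i += int(gap * rate)
        if i + len(sac) >= n:
            break
        amp = rng.uniform(0.5, 1.0) * p.saccade_amp_uv * (1 if rng.random() < 0.5 else -1)
        rho = rng.uniform(*p.saccade_conjugacy)
        eog_l[i : i + len(sac)] += amp * sac
        eog_r[i : i + len(sac)] += amp * rho * sac

    # chin EMG: atonia in REM, tone in wake, sparse twitches
    chin_sd = np.where(stage == "W", p.chin_wake_uv, np.where(stage == "REM", p.chin_rem_uv, 5.0))
    chin = _band_noise(rng, n, *BAND_SETTINGS["EMG"], rate) * chin_sd
    n_twitch = rng.poisson(p.chin_twitch_rate_hz * duration_s)
    for _ in range(n_twitch):
        j = int(rng.integers(0, max(1, n - int(0.2 * rate))))
        chin[j : j + int(0.2 * rate)] += _band_noise(rng, int(0.2 * rate), 10, 100, rate) * 20.0

    corr = _band_noise(rng, n, *BAND_SETTINGS["EMG"], rate) * p.facial_noise_uv
    zyg = _band_noise(rng, n, *BAND_SETTINGS["EMG"], rate) * p.facial_noise_uv

    # embedded volitional signals
    answers: list[AnswerSignalTruth] = []
    muscle_answers: list[MuscleSignalTruth] = []
    vol_amp = p.signal_to_background_ratio * p.saccade_amp_uv

    def _write_eye_sequence(onset_s: float, directions: tuple[Direction, ...], amp: float) -> None:
        # movements at or below background amplitude are ordinary saccades,
        # not maximal horizontal scans: rendered common-mode like background
        mirrored = amp > p.saccade_amp_uv
        t0 = onset_s
        for d in directions:
            tmpl = _eye_movement_template(d, p, rate) * amp
            j = int(round(t0 * rate))
            if j + len(tmpl) > n:
                break
            eog_l[j : j + len(tmpl)] += tmpl
            if mirrored:
                eog_r[j : j + len(tmpl)] -= tmpl
            else:
                eog_r[j : j + len(tmpl)] += tmpl * rng.uniform(*p.saccade_conjugacy)
            t0 += p.movement_s + p.movement_gap_s

    for item in answer_plan:
        if item.kind == "miss":
            continue
        stim = schedule.events[item.stimulus_index]
        onset = stim.onset_s + item.latency_s
        if item.muscle is not None:
            count = item.contraction_count if item.contraction_count is not None else 2
            target = zyg if item.muscle is Muscle.ZYGOMATIC else corr
            amp = p.facial_burst_uv if item.kind == "hit" else p.facial_noise_uv
            t0 = onset
            for _ in range(count):
                j = int(round(t0 * rate))
                m = int(p.burst_s * rate)
                if j + m > n:
                    break
                target[j : j + m] += np.abs(_band_noise(rng, m, 10, 100, rate)) * amp * np.hanning(m)
                t0 += p.burst_s + p.burst_gap_s
            muscle_answers.append(
                MuscleSignalTruth(item.stimulus_index, onset, item.muscle, count, amp)
            )
        else:
            if item.directions is not None:
                directions = item.directions
            elif item.value is not None:
                directions = encode_answer(item.value, item.code_kind).directions
            else:
                raise ValueError("eye answer plan item needs value or directions")
            amp = vol_amp if item.kind == "hit" else p.saccade_amp_uv
            _write_eye_sequence(onset, directions, amp)
            answers.append(AnswerSignalTruth(item.stimulus_index, onset, directions, amp))

    lucidity: list[AnswerSignalTruth] = []
    for luc in lucidity_plan:
        _write_eye_sequence(luc.onset_s, luc.directions, vol_amp)
        lucidity.append(
            AnswerSignalTruth(None, luc.onset_s, luc.directions, vol_amp, kind="lucidity")
        )

    data["EOG_L"] = eog_l
    data["EOG_R"] = eog_r
    data["EMG_chin"] = chin
    data["EMG_corr"] = corr
    data["EMG_zyg"] = zyg
    record = PsgRecord(
        {ch: data[ch] for ch in CHANNELS}, rate=rate, calibration_uv=p.calibration_uv
    )
    log = EventLog(
        stimuli=tuple(schedule.events),
        answers=tuple(answers),
        muscle_answers=tuple(muscle_answers),
        lucidity=tuple(lucidity),
    )
    return record, log


# ---------------------------------------------------------------------------
# Simulated raters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RaterJudgment:
    rater_id: int
    count: Optional[int]
    muscle: Optional[Muscle] = None
    confidence: Confidence = Confidence.HIGH


@dataclass(frozen=True)
class RaterParams:
    p_correct: float = 1.0
    p_false_alarm: float = 0.0
    p_none_given_error: float = 0.3
    confidence_probs: tuple[float, float, float] = (1.0, 0.0, 0.0)  # HIGH, MODERATE, LOW


def _draw_confidence(params: RaterParams, rng: np.random.Generator) -> Confidence:
    u = rng.random()
    p_high, p_mod, _ = params.confidence_probs
    if u < p_high:
        return Confidence.HIGH
    if u < p_high + p_mod:
        return Confidence.MODERATE
    return Confidence.LOW


def simulate_raters(
    truth_count: Optional[int],
    confusion_params: RaterParams = RaterParams(),
    n_raters: int = 4,
    seed: RngLike = 0,
) -> list[RaterJudgment]:
    """Draw independent rater counts around the true signal count.

    Each rater reports the truth with ``p_correct``; otherwise NONE with
    ``p_none_given_error`` or a miscount of +/-1. Absent signals elicit a
    false-alarm count with ``p_false_alarm``.
    """
    rng = _rng(seed)
    cp = confusion_params
    out = []
    for rid in range(n_raters):
        if truth_count is None:
            count = int(rng.integers(1, 5)) if rng.random() < cp.p_false_alarm else None
        elif rng.random() < cp.p_correct:
            count = truth_count
        elif rng.random() < cp.p_none_given_error:
            count = None
        else:
            count = max(1, truth_count + (1 if rng.random() < 0.5 else -1))
        out.append(RaterJudgment(rid, count, confidence=_draw_confidence(cp, rng)))
    return out


def simulate_facial_raters(
    truth: Optional[tuple[Muscle, int]],
    confusion_params: RaterParams = RaterParams(),
    n_raters: int = 4,
    seed: RngLike = 0,
) -> list[RaterJudgment]:
    """Facial variant: raters report (muscle, contraction count) or NONE."""
    rng = _rng(seed)
    cp = confusion_params
    out = []
    for rid in range(n_raters):
        if truth is None:
            if rng.random() < cp.p_false_alarm:
                muscle = Muscle.ZYGOMATIC if rng.random() < 0.5 else Muscle.CORRUGATOR
                out.append(
                    RaterJudgment(rid, int(rng.integers(1, 4)), muscle, _draw_confidence(cp, rng))
                )
            else:
                out.append(RaterJudgment(rid, None, None, _draw_confidence(cp, rng)))
            continue
        muscle, count = truth
        if rng.random() < cp.p_correct:
            out.append(RaterJudgment(rid, count, muscle, _draw_confidence(cp, rng)))
        elif rng.random() < cp.p_none_given_error:
            out.append(RaterJudgment(rid, None, None, _draw_confidence(cp, rng)))
        else:
            if rng.random() < 0.5:  # wrong muscle
                other = Muscle.CORRUGATOR if muscle is Muscle.ZYGOMATIC else Muscle.ZYGOMATIC
                out.append(RaterJudgment(rid, count, other, _draw_confidence(cp, rng)))
            else:  # miscount
                out.append(
                    RaterJudgment(
                        rid, max(1, count + (1 if rng.random() < 0.5 else -1)),
                        muscle, _draw_confidence(cp, rng),
                    )
                )
    return out
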