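"""Automated stand-in for human signal raters.

Eye-movement signals are detected on the differential EOG channel
(EOG_L - EOG_R): volitional full-scan movements are mirrored across the two
channels, so the difference doubles their amplitude while cancelling
common-mode background. Facial-muscle contractions are counted from a moving
RMS envelope of the corresponding EMG channel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .codec import (
    MALFORMED,
    CodeKind,
    Direction,
    EyeDirectionSequence,
    decode_gaze_morse,
    decode_lr_count,
)
from .psg_sim import Muscle, PsgRecord

__all__ = [
    "EyeSignalEvent",
    "DetectionResult",
    "DetectorThresholds",
    "EmgThresholds",
    "detect_eye_movements",
    "group_trains",
    "count_answer",
    "detect_contractions",
]


@dataclass(frozen=True)
class EyeSignalEvent:
    onset_s: float
    direction: Direction
    peak_uv: float


@dataclass(frozen=True)
class DetectorThresholds:
    """Operationalized detection parameters (the paper's raters used eyeballs)."""

    k_mad: float = 2.5          # threshold = k * robust SD of baseline differential
    refractory_s: float = 0.3
    smooth_s: float = 0.25
    baseline_s: float = 60.0
    max_train_gap_s: float = 2.0


@dataclass(frozen=True)
class EmgThresholds:
    rms_window_s: float = 0.05
    k_baseline: float = 4.0
    merge_gap_s: float = 0.25
    baseline_s: float = 60.0


@dataclass(frozen=True)
class DetectionResult:
    events: tuple[EyeSignalEvent, ...]
    trains: tuple[tuple[EyeSignalEvent, ...], ...]
    decoded: Union[int, str, None]
    window: tuple[float, float]


def _robust_sd(x: np.ndarray) -> float:
    med = np.median(x)
    return 1.4826 * float(np.median(np.abs(x - med)))


def detect_eye_movements(
    record: PsgRecord,
    window: tuple[float, float],
    thresholds: DetectorThresholds = DetectorThresholds(),
) -> list[EyeSignalEvent]:
    """Detect lateralized eye movements inside a response window.

    The amplitude threshold is ``k_mad`` times the MAD-based robust SD of the
    raw differential signal over the ``baseline_s`` seconds preceding the
    window (falling back to the window itself near record start). Peaks are
    found on a lightly smoothed differential, separated by the refractory
    period, and labeled L (positive) or R (negative) by polarity.
    """
    start_s, end_s = window
    rate = record.rate
    if start_s < 0 or end_s > record.duration_s or end_s <= start_s:
        raise ValueError(f"window {window} outside record of {record.duration_s:.1f} s")
    d = record.data["EOG_L"] - record.data["EOG_R"]

    b0 = int(max(0, (start_s - thresholds.baseline_s)) * rate)
    b1 = int(start_s * rate)
    baseline = d[b0:b1] if b1 - b0 >= rate else d[int(start_s * rate) : int(end_s * rate)]
    if baseline.size == 0 or not np.any(baseline):
        return []
    thr = thresholds.k_mad * _robust_sd(baseline)
    if thr == 0:
        return []

    smooth_n = max(1, int(thresholds.smooth_s * rate))
    ds = uniform_filter1d(d, size=smooth_n)
    i0, i1 = int(start_s * rate), int(end_s * rate)
    seg = ds[i0:i1]
    peaks, props = find_peaks(
        np.abs(seg), height=thr, distance=max(1, int(thresholds.refractory_s * rate))
    )
    events = [
        EyeSignalEvent(
            onset_s=(i0 + pk) / rate,
            direction=Direction.L if seg[pk] > 0 else Direction.R,
            peak_uv=float(abs(seg[pk])),
        )
        for pk in peaks
    ]
    return events


def group_trains(
    events: Sequence[EyeSignalEvent], max_gap_s: float = 2.0
) -> list[list[EyeSignalEvent]]:
    """Split a time-ordered event list into trains at gaps exceeding the limit."""
    trains: list[list[EyeSignalEvent]] = []
    for ev in sorted(events, key=lambda e: e.onset_s):
        if trains and ev.onset_s - trains[-1][-1].onset_s <= max_gap_s:
            trains[-1].append(ev)
        else:
            trains.append([ev])
    return trains


def count_answer(
    events: Sequence[EyeSignalEvent],
    code_kind: CodeKind,
    answer_window: Optional[tuple[float, float]] = None,
    max_gap_s: float = 2.0,
    min_relative_amp: float = 0.5,
) -> Union[int, str, None]:
    """Group detected movements into a train and decode it as an answer.

    Volitional trains are amplitude-homogeneous, so train members weaker than
    ``min_relative_amp`` times the train's median peak are discarded as
    background intrusions before decoding. Returns the decoded count
    (LR_COUNT) or character (MORSE_GAZE), the codec sentinels for
    undecodable trains, or None when no events were detected.
    """
    evs = list(events)
    if answer_window is not None:
        evs = [e for e in evs if answer_window[0] <= e.onset_s <= answer_window[1]]
    if not evs:
        return None
    train = group_trains(evs, max_gap_s)[0]
    med = float(np.median([e.peak_uv for e in train]))
    train = [e for e in train if e.peak_uv >= min_relative_amp * med]
    dirs = tuple(e.direction for e in train)
    seq = EyeDirectionSequence(dirs, code_kind)
    if code_kind is CodeKind.LR_COUNT:
        return decode_lr_count(seq)
    return decode_gaze_morse(seq)


_MUSCLE_CHANNEL = {Muscle.CORRUGATOR: "EMG_corr", Muscle.ZYGOMATIC: "EMG_zyg"}


def detect_contractions(
    record: PsgRecord,
    muscle: Muscle,
    window: tuple[float, float],
    thresholds: EmgThresholds = EmgThresholds(),
) -> int:
    """Count contraction bursts of one facial muscle inside a window.

    Bursts are runs of the moving-RMS envelope above ``k_baseline`` times the
    median baseline envelope, merged across sub-``merge_gap_s`` gaps.
    """
    channel = _MUSCLE_CHANNEL.get(muscle)
    if channel is None or channel not in record.data:
        raise ValueError(f"record has no channel for muscle {muscle}")
    start_s, end_s = window
    rate = record.rate
    if start_s < 0 or end_s > record.duration_s or end_s <= start_s:
        raise ValueError(f"window {window} outside record")
    x = record.data[channel]
    rms_n = max(1, int(thresholds.rms_window_s * rate))
    env = np.sqrt(uniform_filter1d(x.astype(float) ** 2, size=rms_n))

    b0 = int(max(0, start_s - thresholds.baseline_s) * rate)
    b1 = int(start_s * rate)
    baseline = env[b0:b1] if b1 - b0 >= rate else env[int(start_s * rate) : int(end_s * rate)]
    base_level = float(np.median(baseline)) if baseline.size else 0.0
    if base_level == 0:
        base_level = float(np.median(env)) or 1e-9
    thr = thresholds.k_baseline * base_level

    i0, i1 = int(start_s * rate), int(end_s * rate)
    above = env[i0:i1] > thr
    if not above.any():
        return 0
    # merge gaps shorter than merge_gap_s, then count runs
    idx = np.flatnonzero(above)
    gaps = np.diff(idx)
    return int(1 + np.sum(gaps > thresholds.merge_gap_s * rate))
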