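import numpy as np
import pytest

from dreamlink.codec import CodeKind
from dreamlink.detect import count_answer, detect_eye_movements
from dreamlink.protocol import (
    Modality,
    SessionDesign,
    StimulusEvent,
    StimulusSchedule,
)
from dreamlink.psg_sim import AnswerPlanItem, PsgParams, render_record


def empty_schedule() -> StimulusSchedule:
    return StimulusSchedule((), SessionDesign.USA_TLR)


def spoken_math_schedule(onsets, expected) -> StimulusSchedule:
    events = tuple(
        StimulusEvent(t, Modality.SPOKEN, "math", expected_answer=v,
                      code_kind=CodeKind.LR_COUNT)
        for t, v in zip(onsets, expected)
    )
    return StimulusSchedule(events, SessionDesign.USA_TLR)


def run_recovery_batch(n_trials: int, seed: int, ratio: float = 3.0,
                       trials_per_record: int = 20):
    """End-to-end batches: render spoken-math trials, detect, decode.

    Returns (expected, decoded) pairs across all trials.
    """
    rng = np.random.default_rng(seed)
    pairs = []
    n_records = int(np.ceil(n_trials / trials_per_record))
    for r in range(n_records):
        k = min(trials_per_record, n_trials - r * trials_per_record)
        onsets = [70.0 + 30.0 * i for i in range(k)]
        expected = [int(rng.integers(1, 5)) for _ in range(k)]
        schedule = spoken_math_schedule(onsets, expected)
        plan = [
            AnswerPlanItem(i, "hit", expected[i], CodeKind.LR_COUNT, latency_s=3.0)
            for i in range(k)
        ]
        params = PsgParams(signal_to_background_ratio=ratio)
        record, _ = render_record(
            schedule, plan, params, seed=int(rng.integers(0, 2**31)),
            duration_s=onsets[-1] + 40.0,
        )
        for i, t in enumerate(onsets):
            events = detect_eye_movements(record, (t, t + 20.0))
            decoded = count_answer(events, CodeKind.LR_COUNT)
            pairs.append((expected[i], decoded))
    return pairs


@pytest.fixture(scope="session")
def recovery_pairs_default():
    return run_recovery_batch(60, seed=11, ratio=3.0)
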