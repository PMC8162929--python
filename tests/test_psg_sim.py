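import numpy as np
import pytest

from dreamlink.codec import CodeKind, Direction, Muscle
from dreamlink.protocol import Modality, SessionDesign, StimulusEvent, StimulusSchedule
from dreamlink.psg_sim import (
    CHANNELS,
    AnswerPlanItem,
    Confidence,
    Hypnogram,
    LucidityPlanItem,
    PsgParams,
    RaterParams,
    render_record,
    simulate_facial_raters,
    simulate_hypnogram,
    simulate_raters,
)

from conftest import empty_schedule, spoken_math_schedule


class TestHypnogram:
    def test_narcolepsy_rapid_rem(self):
        hyp = simulate_hypnogram("narcolepsy", duration_min=20, seed=1)
        first_rem = hyp.truth.index("REM")
        assert first_rem <= 2

    def test_normal_rem_latency(self):
        hyp = simulate_hypnogram("normal", duration_min=120, rem_latency_min=68, seed=1)
        first_rem = hyp.truth.index("REM")
        assert first_rem == 68 * 2

    def test_zero_confusion_scorers_match_truth(self):
        hyp = simulate_hypnogram("normal", duration_min=60, confusion_p=0.0, seed=2)
        for track in hyp.scorers:
            assert track == hyp.truth

    def test_confusion_rate_binomial(self):
        hyp = simulate_hypnogram(
            "normal", duration_min=5000, confusion_p=0.1, n_scorers=1, seed=3
        )
        disagree = np.mean([a != b for a, b in zip(hyp.scorers[0], hyp.truth)])
        assert disagree == pytest.approx(0.1, abs=0.01)

    def test_epoch_halfopen_convention(self):
        hyp = Hypnogram((("REM", "W"),), truth=("REM", "W"))
        assert hyp.epoch_of(29.999) == 0
        assert hyp.epoch_of(30.0) == 1

    def test_unequal_tracks_rejected(self):
        with pytest.raises(ValueError):
            Hypnogram((("REM",), ("REM", "W")))

    def test_unknown_stage_rejected(self):
        with pytest.raises(ValueError):
            Hypnogram((("R1",),))


class TestRenderRecord:
    def test_all_miss_plan_empty_event_log(self):
        schedule = spoken_math_schedule([70.0], [2])
        plan = [AnswerPlanItem(0, "miss", 2)]
        _, log = render_record(schedule, plan, seed=1, duration_s=100.0)
        assert log.answers == ()

    def test_answer_onset_and_directions(self):
        schedule = spoken_math_schedule([70.0], [2])
        plan = [AnswerPlanItem(0, "hit", 2, CodeKind.LR_COUNT, latency_s=3.0)]
        _, log = render_record(schedule, plan, seed=1, duration_s=100.0)
        sig = log.answers[0]
        assert sig.onset_s == pytest.approx(73.0)
        assert sig.directions == (Direction.L, Direction.R, Direction.L, Direction.R)

    def test_plan_referencing_missing_stimulus_rejected(self):
        schedule = spoken_math_schedule([70.0], [2])
        with pytest.raises(ValueError):
            render_record(schedule, [AnswerPlanItem(5, "hit", 2)], seed=1)

    def test_channels_and_rate(self):
        record, _ = render_record(empty_schedule(), [], seed=1, duration_s=60.0)
        assert tuple(record.data.keys()) == CHANNELS
        assert record.rate == 500
        assert record.calibration_uv == 100.0
        assert record.n_samples == 60 * 500

    @pytest.mark.parametrize("seed", range(20))
    def test_embedded_amplitude_ratio(self, seed):
        """Peak |EOG| inside signal windows >= 3x 95th pct of background."""
        schedule = spoken_math_schedule([70.0], [3])
        plan = [AnswerPlanItem(0, "hit", 3, CodeKind.LR_COUNT, latency_s=2.0)]
        record, log = render_record(schedule, plan, seed=seed, duration_s=110.0)
        eog = record.data["EOG_L"]
        rate = record.rate
        sig = log.answers[0]
        i0 = int(sig.onset_s * rate)
        i1 = int((sig.onset_s + 5.0) * rate)
        peak = np.max(np.abs(eog[i0:i1]))
        background = np.abs(eog[: int(60 * rate)])
        assert peak >= 3.0 * np.percentile(background, 95)

    def test_determinism(self):
        schedule = spoken_math_schedule([70.0], [2])
        plan = [AnswerPlanItem(0, "hit", 2)]
        r1, l1 = render_record(schedule, plan, seed=42, duration_s=90.0)
        r2, l2 = render_record(schedule, plan, seed=42, duration_s=90.0)
        for ch in CHANNELS:
            assert np.array_equal(r1.data[ch], r2.data[ch])
        assert l1.answers == l2.answers

    def test_answer_signals_map_to_schedule(self):
        schedule = spoken_math_schedule([70.0, 100.0, 130.0], [1, 2, 3])
        plan = [AnswerPlanItem(i, "hit", i + 1) for i in range(3)]
        _, log = render_record(schedule, plan, seed=2, duration_s=170.0)
        indices = [s.stimulus_index for s in log.answers]
        assert indices == [0, 1, 2]

    def test_chin_atonia_rem_vs_wake(self):
        """Chin-EMG RMS lower in REM than wake, over >= 100 epochs."""
        n_ep = 120
        stages = tuple("REM" if k % 2 == 0 else "W" for k in range(n_ep))
        hyp = Hypnogram((stages,) * 3, truth=stages)
        params = PsgParams(rate=100)  # cheap rate; invariant is rate-free
        record, _ = render_record(
            empty_schedule(), [], params, seed=3, hypnogram=hyp,
            duration_s=n_ep * 30.0,
        )
        chin = record.data["EMG_chin"]
        per_epoch = 30 * params.rate
        rms = [
            np.sqrt(np.mean(chin[k * per_epoch:(k + 1) * per_epoch] ** 2))
            for k in range(n_ep)
        ]
        rem_rms = np.mean([r for k, r in enumerate(rms) if stages[k] == "REM"])
        wake_rms = np.mean([r for k, r in enumerate(rms) if stages[k] == "W"])
        assert rem_rms < wake_rms

    def test_lucidity_plan_recorded(self):
        _, log = render_record(
            empty_schedule(), [], seed=4, duration_s=90.0,
            lucidity_plan=[LucidityPlanItem(onset_s=40.0)],
        )
        assert len(log.lucidity) == 1
        assert log.lucidity[0].kind == "lucidity"
        assert len(log.lucidity[0].directions) == 6

    def test_facial_plan_renders_bursts(self):
        schedule = StimulusSchedule(
            (StimulusEvent(70.0, Modality.WORD, "up"),), SessionDesign.FR_BLOCKS
        )
        plan = [AnswerPlanItem(0, "hit", muscle=Muscle.ZYGOMATIC,
                               contraction_count=2, latency_s=2.0)]
        record, log = render_record(schedule, plan, seed=5, duration_s=100.0)
        assert log.muscle_answers[0].contraction_count == 2
        zyg = record.data["EMG_zyg"]
        rate = record.rate
        in_sig = np.abs(zyg[int(72.0 * rate):int(74.0 * rate)]).max()
        base = np.abs(zyg[: int(60 * rate)]).max()
        assert in_sig > 3 * base


class TestSimulateRaters:
    def test_perfect_raters(self):
        judgments = simulate_raters(2, RaterParams(p_correct=1.0), seed=1)
        assert [j.count for j in judgments] == [2, 2, 2, 2]
        assert all(j.confidence is Confidence.HIGH for j in judgments)

    def test_true_none_no_false_alarms(self):
        judgments = simulate_raters(None, RaterParams(p_false_alarm=0.0), seed=1)
        assert all(j.count is None for j in judgments)

    def test_agreement_binomial(self):
        judgments = simulate_raters(
            3, RaterParams(p_correct=0.8), n_raters=10_000, seed=2
        )
        agree = np.mean([j.count == 3 for j in judgments])
        assert agree == pytest.approx(0.8, abs=0.01)

    def test_deterministic(self):
        a = simulate_raters(2, RaterParams(p_correct=0.7), seed=9)
        b = simulate_raters(2, RaterParams(p_correct=0.7), seed=9)
        assert a == b

    def test_facial_perfect(self):
        judgments = simulate_facial_raters((Muscle.ZYGOMATIC, 2), seed=1)
        assert all(j.muscle is Muscle.ZYGOMATIC and j.count == 2 for j in judgments)

    def test_facial_none(self):
        judgments = simulate_facial_raters(None, seed=1)
        assert all(j.count is None for j in judgments)
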