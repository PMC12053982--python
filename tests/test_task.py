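"""Go/NoGo scheduling, trial timelines and behavioral scoring."""

import numpy as np
import pytest

from dancedsp import (
    EmptySummaryError,
    IncompleteTrialError,
    InvalidInputError,
    StepResponse,
    TimingTemplate,
    TrialSpec,
    block_summary,
    schedule_block,
    schedule_session,
    score_trial,
    step_response_times,
    trial_timeline,
)
from dancedsp.sequences import DanceSequence, rotate_sequence
from dancedsp.task import FEEDBACK_GOOD, FEEDBACK_TOO_EARLY


class TestScheduleBlock:
    def test_default_block_composition(self, base_pair):
        block = schedule_block(base_pair, seed=1)
        assert len(block.trials) == 52
        assert block.n_go == 48
        assert block.n_nogo == 4
        assert round(block.go_fraction() * 100) == 92

    def test_go_counts_balanced_between_sequences(self, base_pair):
        block = schedule_block(base_pair, seed=2)
        a, b = base_pair
        per_seq = {a.to_string(): 0, b.to_string(): 0}
        for t in block.trials:
            if t.is_go:
                per_seq[t.sequence.to_string()] += 1
        assert per_seq[a.to_string()] == per_seq[b.to_string()] == 24

    def test_nogo_trials_alternate_sequences(self, base_pair):
        block = schedule_block(base_pair, n_go_per_seq=4, n_nogo=4, seed=3)
        nogo_seqs = sorted(
            t.sequence.to_string() for t in block.trials if not t.is_go
        )
        a, b = (s.to_string() for s in base_pair)
        assert nogo_seqs == sorted([a, a, b, b])

    def test_all_go_block(self, base_pair):
        block = schedule_block(base_pair, n_nogo=0, seed=4)
        assert len(block.trials) == 48 and block.n_nogo == 0

    def test_same_seed_same_order(self, base_pair):
        b1 = schedule_block(base_pair, seed=99)
        b2 = schedule_block(base_pair, seed=99)
        assert [
            (t.sequence.to_string(), t.is_go) for t in b1.trials
        ] == [(t.sequence.to_string(), t.is_go) for t in b2.trials]

    def test_go_fraction_formula(self, base_pair):
        block = schedule_block(base_pair, n_go_per_seq=10, n_nogo=5, seed=5)
        assert block.go_fraction() == pytest.approx(20 / 25)

    def test_trial_indices_unique(self, base_pair):
        block = schedule_block(base_pair, seed=6)
        idx = [t.trial_index for t in block.trials]
        assert idx == list(range(52))


class TestScheduleSession:
    def test_default_session_step_arithmetic(self, base_pair, novel_pair):
        session = schedule_session(base_pair, novel_pair, seed=7)
        assert len(session.blocks) == 6
        assert session.total_go_steps() == 1728

    def test_training_plus_test_block_count(self, base_pair, novel_pair):
        session = schedule_session(base_pair, novel_pair, n_training=8, seed=8)
        assert len(session.blocks) == 10

    def test_test_phase_counterbalanced_by_parity(self, base_pair, novel_pair):
        even = schedule_session(base_pair, novel_pair, participant_index=0, seed=9)
        odd = schedule_session(base_pair, novel_pair, participant_index=1, seed=9)
        assert [b.familiarity for b in even.test_blocks] == ["familiar", "novel"]
        assert [b.familiarity for b in odd.test_blocks] == ["novel", "familiar"]

    def test_novel_pair_overlapping_training_warns(self, base_pair):
        rotated = (rotate_sequence(base_pair[0], 2), base_pair[1])
        with pytest.warns(UserWarning, match="rotation of a trained"):
            schedule_session(base_pair, rotated, seed=10)

    def test_step_count_scales_with_block_layout(self, base_pair, novel_pair):
        session = schedule_session(
            base_pair, novel_pair, n_training=2, n_test=1, n_go_per_seq=5, seed=11
        )
        assert session.total_go_steps() == 3 * 2 * 5 * 6


class TestTrialTimeline:
    def test_six_step_cue_onset(self, base_pair):
        trial = TrialSpec(0, base_pair[0], is_go=True)
        events = trial_timeline(trial)
        assert events[0] == ("FIXATION", 0)
        assert events[-1] == ("CUE_GO", 7000)

    def test_three_step_cue_onset(self):
        trial = TrialSpec(0, DanceSequence.from_string("LRU"), is_go=False)
        events = trial_timeline(trial)
        assert events[-1] == ("CUE_NOGO", 4750)

    def test_stimulus_onsets_spaced_by_duration(self, base_pair):
        trial = TrialSpec(0, base_pair[0], is_go=True)
        stim = [t for label, t in trial_timeline(trial) if label.startswith("STIM")]
        assert stim == [1000 + 750 * i for i in range(6)]

    def test_template_fields_must_be_positive(self):
        with pytest.raises(InvalidInputError):
            TimingTemplate(fixation_ms=0)


def _responses(seq, cue, rts_ms):
    t = cue
    out = []
    for d, rt in zip(seq, rts_ms):
        t += rt / 1000.0
        out.append(StepResponse(d, t))
    return out


class TestScoring:
    def test_all_correct_trial(self, base_pair):
        trial = TrialSpec(0, base_pair[0], is_go=True)
        res = score_trial(trial, _responses(base_pair[0], 10.0, [500] + [300] * 5), 10.0)
        assert res.feedback == FEEDBACK_GOOD
        assert res.per_step_correct == [True] * 6
        assert not res.too_early
        assert res.step_rts_ms == pytest.approx([500, 300, 300, 300, 300, 300])

    def test_response_before_cue_is_too_early(self, base_pair):
        trial = TrialSpec(0, base_pair[0], is_go=True)
        resp = [StepResponse(base_pair[0].steps[0], 9.9)]
        res = score_trial(trial, resp, 10.0)
        assert res.too_early
        assert res.feedback == FEEDBACK_TOO_EARLY
        assert res.per_step_correct == [] and res.step_rts_ms == []

    def test_wrong_steps_listed_one_based(self, base_pair):
        seq = base_pair[0]
        wrong = list(seq.steps)
        wrong[1] = rotate_sequence(DanceSequence((wrong[1],)), 1).steps[0]
        wrong[4] = rotate_sequence(DanceSequence((wrong[4],)), 1).steps[0]
        resp = _responses(DanceSequence(tuple(wrong)), 10.0, [400] * 6)
        res = score_trial(TrialSpec(0, seq, is_go=True), resp, 10.0)
        assert res.per_step_correct == [True, False, True, True, False, True]
        assert res.feedback == "Wrong steps: 2,5"

    def test_nogo_with_response_voided(self, base_pair):
        trial = TrialSpec(0, base_pair[0], is_go=False)
        res = score_trial(trial, [StepResponse(base_pair[0].steps[0], 12.0)], 10.0)
        assert res.too_early and res.feedback == FEEDBACK_TOO_EARLY

    def test_clean_nogo_has_no_feedback(self, base_pair):
        res = score_trial(TrialSpec(0, base_pair[0], is_go=False), [], 10.0)
        assert not res.too_early and res.feedback == ""

    def test_incomplete_go_trial_raises(self, base_pair):
        trial = TrialSpec(0, base_pair[0], is_go=True)
        resp = _responses(base_pair[0], 10.0, [400] * 6)[:4]
        with pytest.raises(IncompleteTrialError):
            score_trial(trial, resp, 10.0)


class TestStepResponseTimes:
    def test_first_step_from_cue_then_interstep_intervals(self, base_pair):
        resp = _responses(base_pair[0], 10.0, [500, 300, 300, 300, 300, 300])
        assert step_response_times(resp, 10.0) == pytest.approx(
            [500, 300, 300, 300, 300, 300]
        )

    def test_equal_timestamps_rejected(self, base_pair):
        s = base_pair[0].steps
        resp = [StepResponse(s[0], 10.5), StepResponse(s[1], 10.5)]
        with pytest.raises(InvalidInputError):
            step_response_times(resp, 10.0)


class TestBlockSummary:
    def _block(self, base_pair, n=48, n_wrong=0):
        out = []
        seq = base_pair[0]
        for i in range(n):
            trial = TrialSpec(i, seq, is_go=True)
            if i < n_wrong:
                steps = list(seq.steps)
                steps[0] = rotate_sequence(DanceSequence((steps[0],)), 1).steps[0]
                resp = _responses(DanceSequence(tuple(steps)), 10.0, [300] * 6)
            else:
                resp = _responses(seq, 10.0, [300] * 6)
            out.append(score_trial(trial, resp, 10.0))
        return out

    def test_constant_rt_block(self, base_pair):
        mean_rt, mistake_pct = block_summary(self._block(base_pair))
        assert mean_rt == pytest.approx(300.0)
        assert mistake_pct == 0.0

    def test_single_error_of_48(self, base_pair):
        _, mistake_pct = block_summary(self._block(base_pair, n_wrong=1))
        assert mistake_pct == pytest.approx(100 / 48)

    def test_empty_input_raises(self):
        with pytest.raises(EmptySummaryError):
            block_summary([])
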