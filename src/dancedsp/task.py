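"""Go/NoGo trial scheduling and behavioral scoring for the dance DSP task.

A block interleaves Go trials (the participant reproduces the just-shown
sequence by stepping) with rare NoGo trials (execution is withheld),
separating sequence preparation from execution.  Defaults follow the
standard design: 24 Go trials per sequence (48 total) plus 4 NoGo trials
per block, a 30 s break halfway through each block, 4 training blocks and
2 test blocks (one familiar, one novel) per session, with 3 min breaks
between blocks and a 10 min break after the fourth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .errors import EmptySummaryError, IncompleteTrialError, InvalidInputError
from .sequences import DanceSequence, StepDirection, rotate_sequence

#: Bit-exact feedback strings shown to participants.
FEEDBACK_GOOD = "Good"
FEEDBACK_TOO_EARLY = "Too early!"
FEEDBACK_END = "This is the end of the session"


@dataclass(frozen=True)
class TimingTemplate:
    """Within-trial event durations, in milliseconds.

    fixation_ms
        Central cross lights up at trial start.
    stimulus_ms
        Each placeholder lights up in turn for this long.
    pre_cue_ms
        Blank interval between the last stimulus and the Go/NoGo cue.
    nogo_wait_ms
        Wait after a NoGo cue before the next trial.
    feedback_ms
        Feedback display after a completed Go trial.
    """

    fixation_ms: int = 1000
    stimulus_ms: int = 750
    pre_cue_ms: int = 1500
    nogo_wait_ms: int = 3000
    feedback_ms: int = 1000

    def __post_init__(self) -> None:
        for name in ("fixation_ms", "stimulus_ms", "pre_cue_ms", "nogo_wait_ms", "feedback_ms"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be a positive number of ms")


@dataclass(frozen=True)
class TrialSpec:
    """One scheduled trial: which sequence, Go or NoGo, and its context."""

    trial_index: int
    sequence: DanceSequence
    is_go: bool
    phase: str = "training"  # "training" | "test"
    familiarity: str = "familiar"  # "familiar" | "novel"


@dataclass
class BlockSchedule:
    """An ordered list of trials with the block's break structure."""

    trials: List[TrialSpec]
    midblock_break_after: int = 24
    midblock_break_s: float = 30.0
    seed: int = 0
    block_index: int = 0
    phase: str = "training"
    familiarity: str = "familiar"

    @property
    def n_go(self) -> int:
        return sum(t.is_go for t in self.trials)

    @property
    def n_nogo(self) -> int:
        return len(self.trials) - self.n_go

    def go_fraction(self) -> float:
        return self.n_go / len(self.trials)


@dataclass
class SessionSchedule:
    """Training blocks followed by test blocks, with between-block breaks."""

    training_blocks: List[BlockSchedule]
    test_blocks: List[BlockSchedule]
    interblock_break_s: float = 180.0
    long_break_after_block: int = 4
    long_break_s: float = 600.0

    @property
    def blocks(self) -> List[BlockSchedule]:
        return list(self.training_blocks) + list(self.test_blocks)

    def total_go_steps(self) -> int:
        return sum(len(t.sequence) for b in self.blocks for t in b.trials if t.is_go)


@dataclass(frozen=True)
class StepResponse:
    """One registered step: which mat direction, and when (recording clock)."""

    direction: StepDirection
    timestamp_s: float


@dataclass
class TrialResult:
    """Scored outcome of one trial.

    For too-early trials (or clean NoGo trials) the per-step lists are
    empty; otherwise they have one entry per sequence step.
    """

    trial: TrialSpec
    responses: List[StepResponse]
    per_step_correct: List[bool]
    too_early: bool
    step_rts_ms: List[float]
    feedback: str
    cue_time_s: float = float("nan")
    block_index: int = -1

    @property
    def is_accurate(self) -> bool:
        """Complete Go trial with every step correct."""
        return (
            self.trial.is_go
            and not self.too_early
            and len(self.per_step_correct) > 0
            and all(self.per_step_correct)
        )


def schedule_block(
    pair: Tuple[DanceSequence, DanceSequence],
    n_go_per_seq: int = 24,
    n_nogo: int = 4,
    seed: int = 0,
    *,
    block_index: int = 0,
    phase: str = "training",
    familiarity: str = "familiar",
    midblock_break_after: int = 24,
    midblock_break_s: float = 30.0,
) -> BlockSchedule:
    """Randomize one block: n_go_per_seq Go trials of each sequence + NoGo trials.

    The full multiset of trials is shuffled once with a seeded generator, so
    an identical seed yields a byte-identical schedule.  NoGo trials
    alternate which of the pair's sequences they display.
    """
    if n_go_per_seq < 1:
        raise InvalidInputError("n_go_per_seq must be >= 1")
    if n_nogo < 0:
        raise InvalidInputError("n_nogo must be >= 0")
    seq_a, seq_b = pair
    protos: List[Tuple[DanceSequence, bool]] = []
    protos += [(seq_a, True)] * n_go_per_seq
    protos += [(seq_b, True)] * n_go_per_seq
    protos += [(pair[i % 2], False) for i in range(n_nogo)]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(protos))
    trials = [
        TrialSpec(
            trial_index=i,
            sequence=protos[j][0],
            is_go=protos[j][1],
            phase=phase,
            familiarity=familiarity,
        )
        for i, j in enumerate(order)
    ]
    return BlockSchedule(
        trials=trials,
        midblock_break_after=midblock_break_after,
        midblock_break_s=midblock_break_s,
        seed=seed,
        block_index=block_index,
        phase=phase,
        familiarity=familiarity,
    )


def schedule_session(
    pair: Tuple[DanceSequence, DanceSequence],
    novel_pair: Tuple[DanceSequence, DanceSequence],
    n_training: int = 4,
    n_test: int = 2,
    participant_index: int = 0,
    seed: int = 0,
    *,
    n_go_per_seq: int = 24,
    n_nogo: int = 4,
    interblock_break_s: float = 180.0,
    long_break_after_block: int = 4,
    long_break_s: float = 600.0,
) -> SessionSchedule:
    """Assemble a full session: training blocks, then counterbalanced test blocks.

    Test blocks alternate familiar/novel sequences; even participant indices
    see the familiar block first, odd indices the novel block first.  A
    novel pair overlapping any rotation of the trained pair triggers a
    warning (positional transfer would be confounded).
    """
    trained_rotations = {
        rotate_sequence(s, k).to_string() for s in pair for k in range(4)
    }
    for s in novel_pair:
        if s.to_string() in trained_rotations:
            warnings.warn(
                f"novel sequence {s.to_string()} is a rotation of a trained sequence",
                stacklevel=2,
            )
    rng = np.random.default_rng(seed)
    block_seeds = rng.integers(0, 2**31 - 1, size=n_training + n_test)
    common = dict(n_go_per_seq=n_go_per_seq, n_nogo=n_nogo)
    training = [
        schedule_block(
            pair, seed=int(block_seeds[b]), block_index=b, phase="training", **common
        )
        for b in range(n_training)
    ]
    familiar_first = participant_index % 2 == 0
    test = []
    for j in range(n_test):
        familiar = (j % 2 == 0) == familiar_first
        test.append(
            schedule_block(
                pair if familiar else novel_pair,
                seed=int(block_seeds[n_training + j]),
                block_index=n_training + j,
                phase="test",
                familiarity="familiar" if familiar else "novel",
                **common,
            )
        )
    return SessionSchedule(
        training_blocks=training,
        test_blocks=test,
        interblock_break_s=interblock_break_s,
        long_break_after_block=long_break_after_block,
        long_break_s=long_break_s,
    )


def trial_timeline(
    trial: TrialSpec, tmpl: TimingTemplate = TimingTemplate()
) -> List[Tuple[str, int]]:
    """Within-trial event onsets in ms from trial start.

    Fixation at 0, stimulus i at fixation + i*stimulus duration, and the
    Go/NoGo cue after the pre-cue interval.  For the default template and a
    6-step sequence the cue lands at 1000 + 6*750 + 1500 = 7000 ms.
    """
    events: List[Tuple[str, int]] = [("FIXATION", 0)]
    t = tmpl.fixation_ms
    for i in range(len(trial.sequence)):
        events.append((f"STIM_{i + 1}", t))
        t += tmpl.stimulus_ms
    t += tmpl.pre_cue_ms
    events.append(("CUE_GO" if trial.is_go else "CUE_NOGO", t))
    return events


def step_response_times(
    result_or_responses: Union[TrialResult, Sequence[StepResponse]],
    cue_time_s: float,
) -> List[float]:
    """Step-level response times in ms.

    The first step is timed from the Go cue; each later step from the
    previous step (inter-step interval) — the standard DSP convention.
    """
    if isinstance(result_or_responses, TrialResult):
        responses = result_or_responses.responses
    else:
        responses = list(result_or_responses)
    times = [r.timestamp_s for r in responses]
    prev = cue_time_s
    rts = []
    for t in times:
        if t <= prev:
            raise InvalidInputError("response timestamps must be strictly increasing")
        rts.append((t - prev) * 1000.0)
        prev = t
    return rts


def score_trial(
    trial: TrialSpec,
    responses: Sequence[StepResponse],
    cue_time_s: float,
) -> TrialResult:
    """Score one trial against its sequence.

    Any response before the Go cue — or any response at all on a NoGo
    trial — marks the trial too-early and voids it.  Otherwise each step
    is compared element-wise with the target sequence and feedback lists
    the 1-based indices of wrong steps.
    """
    responses = list(responses)
    n = len(trial.sequence)
    if not trial.is_go:
        if responses:
            return TrialResult(trial, responses, [], True, [], FEEDBACK_TOO_EARLY,
                               cue_time_s=cue_time_s)
        return TrialResult(trial, [], [], False, [], "", cue_time_s=cue_time_s)
    if any(r.timestamp_s < cue_time_s for r in responses):
        return TrialResult(trial, responses, [], True, [], FEEDBACK_TOO_EARLY,
                           cue_time_s=cue_time_s)
    if len(responses) < n:
        raise IncompleteTrialError(
            f"trial {trial.trial_index}: {len(responses)} responses for a "
            f"{n}-step sequence"
        )
    responses = responses[:n]
    correct = [r.direction == s for r, s in zip(responses, trial.sequence)]
    rts = step_response_times(responses, cue_time_s)
    if all(correct):
        feedback = FEEDBACK_GOOD
    else:
        wrong = [str(i + 1) for i, ok in enumerate(correct) if not ok]
        feedback = "Wrong steps: " + ",".join(wrong)
    return TrialResult(trial, responses, correct, False, rts, feedback,
                       cue_time_s=cue_time_s)


def block_summary(results: Sequence[TrialResult]) -> Tuple[float, float]:
    """End-of-block feedback numbers: (mean step RT in ms, mistake %).

    Mean RT is over the step-level RTs of accurate trials; mistake % counts
    Go trials with at least one wrong step or a too-early response.
    """
    go = [r for r in results if r.trial.is_go]
    completed = [r for r in go if not r.too_early and r.step_rts_ms]
    if not completed:
        raise EmptySummaryError("no completed Go trials to summarize")
    accurate = [r for r in completed if all(r.per_step_correct)]
    if accurate:
        mean_rt = float(np.mean([rt for r in accurate for rt in r.step_rts_ms]))
    else:
        mean_rt = float("nan")
    mistakes = sum(
        1 for r in go if r.too_early or (r.per_step_correct and not all(r.per_step_correct))
    )
    mistake_pct = 100.0 * mistakes / len(go)
    return mean_rt, mistake_pct
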