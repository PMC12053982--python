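"""Center-of-mass kinematics: velocity, acceleration, per-step summaries.

The center of mass (CoM) displacement trace (x = left-right, y =
forward-back, z = vertical) is differentiated with central differences and
segmented with the same cue/step marker windows the EEG analysis uses, so
behavioral, neural and kinematic step-level measures line up.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set

import numpy as np

from .errors import EmptySummaryError, InvalidInputError
from .streams import MarkerStream, SignalStream

AXES = ("x", "y", "z")


@dataclass
class CoMTrace:
    """CoM displacement over time: (3, n_times) metres, axes x/y/z."""

    times_s: np.ndarray
    displacement_m: np.ndarray
    fs_hz: float = 100.0

    def __post_init__(self) -> None:
        self.displacement_m = np.asarray(self.displacement_m, dtype=float)
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.fs_hz <= 0:
            raise InvalidInputError("fs_hz must be positive")
        if self.displacement_m.shape != (3, self.times_s.shape[0]):
            raise InvalidInputError("displacement must be (3, n_times)")
        if not np.isfinite(self.displacement_m).all():
            raise InvalidInputError("displacement contains non-finite values")

    @classmethod
    def from_stream(cls, stream: SignalStream) -> "CoMTrace":
        if stream.samples.shape[0] != 3:
            raise InvalidInputError("CoM stream must have exactly 3 channels (x,y,z)")
        return cls(
            times_s=stream.times_s,
            displacement_m=stream.samples,
            fs_hz=stream.fs_hz,
        )


@dataclass
class SequenceKinematics:
    """Kinematic summary of one sequence execution."""

    trial_index: int
    mean_velocity_mps: np.ndarray  # (3,)
    mean_abs_velocity_mps: np.ndarray  # (3,)
    peak_speed_mps: float
    per_step_mean_velocity: np.ndarray  # (n_steps, 3)
    per_step_mean_abs_velocity: np.ndarray  # (n_steps, 3)
    step_durations_s: np.ndarray  # (n_steps,)
    block: int = -1


def com_velocity(trace: CoMTrace) -> np.ndarray:
    """Per-axis velocity (m/s): central differences, one-sided at the ends.

    Second-order accurate on smooth traces; exact for linear ramps.
    """
    if trace.displacement_m.shape[1] < 3:
        raise InvalidInputError("need at least 3 samples to differentiate")
    return np.gradient(trace.displacement_m, trace.times_s, axis=1)


def com_acceleration(trace: CoMTrace) -> np.ndarray:
    """Per-axis acceleration (m/s²) by differentiating the velocity."""
    vel = com_velocity(trace)
    return np.gradient(vel, trace.times_s, axis=1)


def segment_sequence(
    trace: CoMTrace,
    markers: MarkerStream,
    trial_index: int,
    sequence_length: int = 6,
) -> Optional[SequenceKinematics]:
    """Per-step and whole-sequence velocity summary for one Go trial.

    Step windows are the same half-open cue/step segments as the EEG
    analysis: [cue, step1), [step1, step2), ..., [step5, step6).  The
    whole-sequence mean is the duration-weighted mean of the per-step
    means; peak speed is the maximum Euclidean norm of the velocity over
    the execution span.  Returns None (with a log entry) when the trial's
    markers are missing.
    """
    ms = markers.for_trial(trial_index)
    cues = [m for m in ms if m.label == "CUE_GO"]
    steps = sorted(
        (m for m in ms if m.label.startswith("STEP_")), key=lambda m: m.timestamp_s
    )
    if not cues or len(steps) < sequence_length:
        import logging

        logging.getLogger(__name__).info(
            "trial %d skipped in kinematics: missing markers", trial_index
        )
        return None
    steps = steps[:sequence_length]
    edges = [cues[0].timestamp_s] + [m.timestamp_s for m in steps]
    fs = trace.fs_hz
    t0 = trace.times_s[0]
    idx = [int(np.floor((e - t0) * fs + 0.5)) for e in edges]
    idx = [int(np.clip(i, 0, trace.displacement_m.shape[1])) for i in idx]
    vel = com_velocity(trace)
    per_step = np.zeros((sequence_length, 3))
    per_step_abs = np.zeros((sequence_length, 3))
    durations = np.zeros(sequence_length)
    for k in range(sequence_length):
        seg = vel[:, idx[k] : idx[k + 1]]
        if seg.shape[1] == 0:
            seg = vel[:, min(idx[k], vel.shape[1] - 1)][:, None]
        per_step[k] = seg.mean(axis=1)
        per_step_abs[k] = np.abs(seg).mean(axis=1)
        durations[k] = edges[k + 1] - edges[k]
    span = vel[:, idx[0] : idx[-1]]
    mean_vel = span.mean(axis=1)
    mean_abs = np.abs(span).mean(axis=1)
    peak = float(np.linalg.norm(span, axis=0).max())
    return SequenceKinematics(
        trial_index=trial_index,
        mean_velocity_mps=mean_vel,
        mean_abs_velocity_mps=mean_abs,
        peak_speed_mps=peak,
        per_step_mean_velocity=per_step,
        per_step_mean_abs_velocity=per_step_abs,
        step_durations_s=durations,
        block=cues[0].block,
    )


@dataclass
class BlockKinematics:
    """Across-trial kinematic averages for one block."""

    block: int
    n_trials: int
    mean_velocity_mps: np.ndarray  # (3,)
    sd_velocity_mps: np.ndarray  # (3,)
    mean_abs_velocity_mps: np.ndarray  # (3,)
    mean_peak_speed_mps: float


def block_kinematics(
    per_trial: Sequence[SequenceKinematics],
    block: int,
    accurate_trials: Optional[Set[int]] = None,
) -> BlockKinematics:
    """Mean and SD of sequence-level CoM velocity across a block's trials.

    By default restricted to the trial indices in ``accurate_trials``
    (mirroring the behavioral convention of averaging accurate sequence
    trials only); pass None to include every segmented trial.
    """
    rows = [k for k in per_trial if k.block == block or block < 0]
    if accurate_trials is not None:
        rows = [k for k in rows if k.trial_index in accurate_trials]
    if not rows:
        raise EmptySummaryError(f"no valid trials for block {block}")
    mv = np.stack([k.mean_velocity_mps for k in rows])
    ma = np.stack([k.mean_abs_velocity_mps for k in rows])
    return BlockKinematics(
        block=block,
        n_trials=len(rows),
        mean_velocity_mps=mv.mean(axis=0),
        sd_velocity_mps=mv.std(axis=0, ddof=0),
        mean_abs_velocity_mps=ma.mean(axis=0),
        mean_peak_speed_mps=float(np.mean([k.peak_speed_mps for k in rows])),
    )
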