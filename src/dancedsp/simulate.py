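"""Synthetic multimodal sessions with known ground truth.

The generator emulates the three recordings of a dance DSP session on one
shared clock:

* behavior — step responses whose RTs follow an exponential learning curve
  (asymptote + gain * exp(-decay * trial)) with Gaussian noise, and
  independent per-step errors;
* EEG — per-channel theta oscillations (random phase per channel) whose
  amplitude is scaled during each cue/step segment by sqrt(1 + ERD/S / 100)
  — power-correct, so the programmed per-step ERD/S percentages are exact
  in expectation — plus 1/f ("pink") broadband noise;
* center-of-mass kinematics — per-step out-and-back cubic smoothstep
  excursions along the stepped direction, sampled at the motion-capture
  rate.

Everything is driven by one seed; identical seeds give bit-identical
sessions.  The defaults emulate the published pilot conditions: 500 Hz
22-channel EEG, 100 Hz kinematics, and an RT curve whose session mean is
~358 ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import InvalidInputError
from .sequences import StepDirection
from .streams import EventMarker, MarkerStream, SignalStream
from .task import (
    SessionSchedule,
    StepResponse,
    TimingTemplate,
    TrialResult,
    score_trial,
    trial_timeline,
)


def _default_com_displacement() -> Dict[StepDirection, Tuple[float, float, float]]:
    # x: left-right, y: forward-back, z: vertical; metres per step excursion.
    return {
        StepDirection.LEFT: (-0.30, 0.0, 0.03),
        StepDirection.RIGHT: (0.30, 0.0, 0.03),
        StepDirection.UP: (0.0, 0.30, 0.03),
        StepDirection.DOWN: (0.0, -0.30, 0.03),
    }


@dataclass
class SimParams:
    """Ground-truth generative parameters for a synthetic session.

    RT curve: step RT for the t-th Go trial of the session is
    ``rt_asymptote_ms + rt_gain_ms * exp(-rt_decay_per_trial * t)`` plus
    Gaussian noise (SD ``rt_noise_sd_ms``), truncated above 50 ms.

    ``erds_per_step_pct`` holds the programmed theta ERD/S percentage for
    each cue/step segment (negative = desynchronization).  The theta-band
    SNR implied by the defaults (10 uV oscillation vs 7 uV pink noise) is
    approximately 3.
    """

    rt_asymptote_ms: float = 300.0
    rt_gain_ms: float = 280.0
    rt_decay_per_trial: float = 0.025
    rt_noise_sd_ms: float = 50.0
    error_prob: float = 0.05
    eeg_fs_hz: float = 500.0
    kin_fs_hz: float = 100.0
    n_channels: int = 22
    theta_freq_hz: float = 6.0
    baseline_theta_amp_uv: float = 10.0
    erds_per_step_pct: Tuple[float, ...] = (-30.0, -20.0, -10.0, 10.0, 20.0, 30.0)
    pink_noise_sd_uv: float = 7.0
    com_step_displacement_m: Dict[StepDirection, Tuple[float, float, float]] = field(
        default_factory=_default_com_displacement
    )
    com_excursion_s: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rt_decay_per_trial < 0:
            raise InvalidInputError("rt_decay_per_trial must be >= 0")
        if not 0.0 <= self.error_prob <= 1.0:
            raise InvalidInputError("error_prob must be in [0, 1]")
        if self.eeg_fs_hz <= 0 or self.kin_fs_hz <= 0:
            raise InvalidInputError("sampling rates must be positive")
        if not 4.0 <= self.theta_freq_hz <= 8.0:
            raise InvalidInputError("theta_freq_hz must lie in the 4-8 Hz band")
        if any(e <= -100.0 for e in self.erds_per_step_pct):
            raise InvalidInputError("ERD/S percentages must exceed -100")

    def theta_band_snr(self) -> float:
        """Approximate theta-band amplitude SNR of the EEG model.

        Pink noise carries only part of its variance in 4-8 Hz; with the
        1/f spectrum flattened below 1 Hz the band fraction of the noise SD
        is sqrt((ln 8 - ln 4) / (1 + ln(f_nyq))).
        """
        f_nyq = self.eeg_fs_hz / 2.0
        frac = math.sqrt(math.log(2.0) / (1.0 + math.log(f_nyq)))
        signal_rms = self.baseline_theta_amp_uv / math.sqrt(2.0)
        noise_band_rms = self.pink_noise_sd_uv * frac
        return signal_rms / noise_band_rms


@dataclass
class BehaviorSim:
    """Simulated behavior: scored trials plus the session's marker stream."""

    results_by_block: List[List[TrialResult]]
    markers: MarkerStream
    duration_s: float

    @property
    def all_results(self) -> List[TrialResult]:
        return [r for block in self.results_by_block for r in block]


@dataclass
class SyntheticSession:
    """A complete synthetic recording with its generative truth."""

    schedule: SessionSchedule
    behavior: BehaviorSim
    eeg: SignalStream
    kinematics: SignalStream
    markers: MarkerStream
    truth: SimParams


def _child_rngs(seed: int, n: int) -> List[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_behavior(
    schedule: SessionSchedule,
    params: SimParams,
    tmpl: TimingTemplate = TimingTemplate(),
    rng: Optional[np.random.Generator] = None,
) -> BehaviorSim:
    """Play a schedule through the generative behavior model.

    Builds the session timeline (trial phases, mid-block and between-block
    breaks), draws step RTs from the learning curve, flips each step to a
    wrong direction with ``error_prob``, scores every trial, and emits the
    marker stream (block boundaries, cues, one step marker per response).
    """
    if rng is None:
        rng = _child_rngs(params.seed, 3)[0]
    markers: List[EventMarker] = []
    results_by_block: List[List[TrialResult]] = []
    t = 0.0
    go_counter = 0
    blocks = schedule.blocks
    for bi, block in enumerate(blocks):
        markers.append(EventMarker("BLOCK_START", t, block=block.block_index))
        block_results: List[TrialResult] = []
        for pos, trial in enumerate(block.trials):
            if pos == block.midblock_break_after and pos > 0:
                t += block.midblock_break_s
            timeline = trial_timeline(trial, tmpl)
            cue_label, cue_ms = timeline[-1]
            cue_t = t + cue_ms / 1000.0
            gidx = _global_index(blocks, bi, pos)
            markers.append(
                EventMarker(cue_label, cue_t, trial_index=gidx, block=block.block_index)
            )
            if trial.is_go:
                curve = params.rt_asymptote_ms + params.rt_gain_ms * math.exp(
                    -params.rt_decay_per_trial * go_counter
                )
                rts = curve + rng.normal(0.0, params.rt_noise_sd_ms, len(trial.sequence))
                rts = np.maximum(rts, 50.0)
                stamps = cue_t + np.cumsum(rts) / 1000.0
                responses = []
                for k, (target, ts) in enumerate(zip(trial.sequence, stamps)):
                    direction = target
                    if rng.random() < params.error_prob:
                        others = [d for d in StepDirection if d is not target]
                        direction = others[int(rng.integers(len(others)))]
                    responses.append(StepResponse(direction, float(ts)))
                    markers.append(
                        EventMarker(
                            f"STEP_{k + 1}", float(ts),
                            trial_index=gidx, block=block.block_index,
                        )
                    )
                result = score_trial(trial, responses, cue_t)
                t = float(stamps[-1]) + tmpl.feedback_ms / 1000.0
                go_counter += 1
            else:
                result = score_trial(trial, [], cue_t)
                t = cue_t + tmpl.nogo_wait_ms / 1000.0
            result.cue_time_s = cue_t
            result.block_index = block.block_index
            block_results.append(result)
        markers.append(EventMarker("BLOCK_END", t, block=block.block_index))
        results_by_block.append(block_results)
        if bi < len(blocks) - 1:
            if bi + 1 == schedule.long_break_after_block:
                t += schedule.long_break_s
            else:
                t += schedule.interblock_break_s
    return BehaviorSim(
        results_by_block=results_by_block,
        markers=MarkerStream(markers),
        duration_s=t,
    )


def _global_index(blocks, block_pos: int, trial_pos: int) -> int:
    return sum(len(b.trials) for b in blocks[:block_pos]) + trial_pos


def pink_noise(
    n: int, fs_hz: float, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Spectrally shaped 1/f noise with the requested standard deviation.

    White Gaussian noise is shaped by 1/sqrt(f) in the frequency domain
    (power spectral density proportional to 1/f), flattened below 1 Hz to
    keep the variance finite, then rescaled to ``sd``.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs_hz)
    shape = 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n)
    s = x.std()
    if s > 0:
        x *= sd / s
    return x


def simulate_eeg(
    behavior: BehaviorSim,
    params: SimParams,
    rng: Optional[np.random.Generator] = None,
) -> SignalStream:
    """Synthesize the EEG stream implied by the behavioral timeline.

    Each channel carries a theta sinusoid with a channel-specific phase.
    On every complete Go trial the oscillation amplitude is scaled by
    sqrt(1 + ERD/S_k / 100) between consecutive markers of segment k
    (cue -> step 1, step 1 -> step 2, ...), matching the segmentation the
    analysis uses, so the programmed percentages are the exact expected
    band-power changes.
    """
    if rng is None:
        rng = _child_rngs(params.seed, 3)[1]
    fs = params.eeg_fs_hz
    n = int(math.ceil((behavior.duration_s + 1.0) * fs))
    t = np.arange(n) / fs

    envelope = np.ones(n)
    for result in behavior.all_results:
        if not result.trial.is_go or result.too_early or not result.responses:
            continue
        edges = [result.cue_time_s] + [r.timestamp_s for r in result.responses]
        for k in range(len(edges) - 1):
            e = params.erds_per_step_pct[k % len(params.erds_per_step_pct)]
            i0 = int(math.floor(edges[k] * fs + 0.5))
            i1 = int(math.floor(edges[k + 1] * fs + 0.5))
            envelope[i0:i1] = math.sqrt(1.0 + e / 100.0)

    samples = np.empty((params.n_channels, n))
    omega = 2.0 * math.pi * params.theta_freq_hz
    for ch in range(params.n_channels):
        phase = rng.uniform(0.0, 2.0 * math.pi)
        sig = params.baseline_theta_amp_uv * np.sin(omega * t + phase) * envelope
        sig += pink_noise(n, fs, params.pink_noise_sd_uv, rng)
        samples[ch] = sig
    return SignalStream(
        name="eeg",
        channel_labels=[f"EEG{c + 1:02d}" for c in range(params.n_channels)],
        fs_hz=fs,
        start_time_s=0.0,
        samples=samples,
    )


def _smoothstep(v: np.ndarray) -> np.ndarray:
    return 3.0 * v**2 - 2.0 * v**3


def simulate_com(
    behavior: BehaviorSim,
    params: SimParams,
    rng: Optional[np.random.Generator] = None,
) -> SignalStream:
    """Synthesize the center-of-mass displacement stream (x, y, z).

    Every response adds an out-and-back excursion along its direction's
    displacement vector: a cubic smoothstep ramp of duration T ending at
    the response timestamp, mirrored back to centre over the following T,
    with T = min(com_excursion_s, neighbouring inter-response intervals).
    Peak speed of the ramp is 1.5 * |displacement| / T.
    """
    fs = params.kin_fs_hz
    n = int(math.ceil((behavior.duration_s + 1.0) * fs))
    t = np.arange(n) / fs
    disp = np.zeros((3, n))
    for result in behavior.all_results:
        if not result.trial.is_go or result.too_early or not result.responses:
            continue
        stamps = [result.cue_time_s] + [r.timestamp_s for r in result.responses]
        for k, resp in enumerate(result.responses):
            prev_gap = stamps[k + 1] - stamps[k]
            next_gap = (
                stamps[k + 2] - stamps[k + 1]
                if k + 2 < len(stamps)
                else params.com_excursion_s
            )
            T = min(params.com_excursion_s, prev_gap, next_gap)
            if T <= 0:
                continue
            vec = np.array(params.com_step_displacement_m[resp.direction])
            tc = resp.timestamp_s
            out = (t >= tc - T) & (t < tc)
            back = (t >= tc) & (t <= tc + T)
            bump = np.zeros(n)
            bump[out] = _smoothstep((t[out] - (tc - T)) / T)
            bump[back] = 1.0 - _smoothstep((t[back] - tc) / T)
            disp += vec[:, None] * bump[None, :]
    return SignalStream(
        name="com",
        channel_labels=["x", "y", "z"],
        fs_hz=fs,
        start_time_s=0.0,
        samples=disp,
    )


def simulate_session(
    schedule: SessionSchedule,
    params: SimParams,
    tmpl: TimingTemplate = TimingTemplate(),
) -> SyntheticSession:
    """Generate the full multimodal session (behavior, EEG, CoM, markers)."""
    rng_beh, rng_eeg, rng_com = _child_rngs(params.seed, 3)
    behavior = simulate_behavior(schedule, params, tmpl, rng=rng_beh)
    eeg = simulate_eeg(behavior, params, rng=rng_eeg)
    com = simulate_com(behavior, params, rng=rng_com)
    return SyntheticSession(
        schedule=schedule,
        behavior=behavior,
        eeg=eeg,
        kinematics=com,
        markers=behavior.markers,
        truth=params,
    )
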