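"""Synchronized multistream recordings and marker-defined epoching.

A session is recorded as independent streams (EEG at 500 Hz, center-of-mass
kinematics at 100 Hz) plus an event-marker stream emitted by the stimulus
script.  All streams share one clock up to a constant per-stream offset.
Epochs are variable-length by design: each covers exactly the time one
sequence execution took (Go cue to last step), extended by a 200 ms
pre-cue baseline window and 100 ms of padding on both sides.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .errors import InvalidInputError
from .task import BlockSchedule, SessionSchedule

logger = logging.getLogger(__name__)

#: Closed marker vocabulary.
MARKER_PATTERN = re.compile(
    r"^(BLOCK_START|BLOCK_END|CUE_GO|CUE_NOGO|STEP_\d+)$"
)


@dataclass
class SignalStream:
    """A regularly sampled multichannel signal on the recording clock."""

    name: str
    channel_labels: List[str]
    fs_hz: float
    start_time_s: float
    samples: np.ndarray  # (n_channels, n_times)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs_hz <= 0:
            raise InvalidInputError("fs_hz must be positive")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise InvalidInputError("channel labels must be unique")
        if self.samples.ndim != 2 or self.samples.shape[0] != len(self.channel_labels):
            raise InvalidInputError(
                "samples must be (n_channels, n_times) matching channel_labels"
            )

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def times_s(self) -> np.ndarray:
        return self.start_time_s + np.arange(self.n_times) / self.fs_hz

    @property
    def end_time_s(self) -> float:
        return self.start_time_s + (self.n_times - 1) / self.fs_hz

    def index_of(self, t_s: float) -> int:
        """Nearest-sample index of time ``t_s`` (error <= half a sample period)."""
        return int(np.floor((t_s - self.start_time_s) * self.fs_hz + 0.5))

    def copy_with(self, samples: np.ndarray) -> "SignalStream":
        return replace(self, samples=samples, channel_labels=list(self.channel_labels))


@dataclass(frozen=True)
class EventMarker:
    """One labelled event on the shared clock."""

    label: str
    timestamp_s: float
    trial_index: int = -1
    block: int = -1

    def __post_init__(self) -> None:
        if not MARKER_PATTERN.match(self.label):
            raise InvalidInputError(f"marker label outside vocabulary: {self.label!r}")


class MarkerStream:
    """An ordered stream of event markers.

    Timestamps are expected non-decreasing; a disordered stream is accepted
    (so it can be inspected and reported by :func:`validate_markers`) unless
    ``strict=True``.
    """

    def __init__(
        self,
        markers: Iterable[EventMarker],
        name: str = "markers",
        strict: bool = False,
    ) -> None:
        self.name = name
        self.markers: List[EventMarker] = list(markers)
        ts = [m.timestamp_s for m in self.markers]
        self.monotonic = all(b >= a for a, b in zip(ts, ts[1:]))
        if strict and not self.monotonic:
            raise InvalidInputError("marker timestamps must be non-decreasing")

    def __len__(self) -> int:
        return len(self.markers)

    def __iter__(self):
        return iter(self.markers)

    def with_label(self, label: str) -> List[EventMarker]:
        return [m for m in self.markers if m.label == label]

    def for_trial(self, trial_index: int) -> List[EventMarker]:
        return [m for m in self.markers if m.trial_index == trial_index]

    def by_trial(self) -> Dict[int, List[EventMarker]]:
        out: Dict[int, List[EventMarker]] = {}
        for m in self.markers:
            if m.trial_index >= 0:
                out.setdefault(m.trial_index, []).append(m)
        return out

    def shifted(self, offset_s: float) -> "MarkerStream":
        return MarkerStream(
            (replace(m, timestamp_s=m.timestamp_s + offset_s) for m in self.markers),
            name=self.name,
        )


@dataclass
class Recording:
    """Streams and markers mapped onto one common clock."""

    streams: Dict[str, SignalStream]
    markers: MarkerStream


def align_streams(
    streams: Sequence[SignalStream],
    markers: MarkerStream,
    clock_offsets: Optional[Dict[str, float]] = None,
) -> Recording:
    """Map every stream and the marker stream onto a common clock.

    ``clock_offsets`` gives the constant offset (seconds) to *add* to each
    stream's native timestamps, keyed by stream name; the marker stream's
    offset is keyed by its own name (default ``"markers"``).  Markers that
    fall outside the span of every aligned stream raise an orphan-marker
    warning.
    """
    clock_offsets = clock_offsets or {}
    aligned: Dict[str, SignalStream] = {}
    for s in streams:
        off = clock_offsets.get(s.name, 0.0)
        aligned[s.name] = replace(
            s,
            start_time_s=s.start_time_s + off,
            channel_labels=list(s.channel_labels),
        )
    m_aligned = markers.shifted(clock_offsets.get(markers.name, 0.0))
    orphans = [
        m
        for m in m_aligned
        if not any(
            s.start_time_s <= m.timestamp_s <= s.end_time_s for s in aligned.values()
        )
    ]
    if orphans:
        warnings.warn(
            f"{len(orphans)} marker(s) fall outside every stream's span "
            f"(first: {orphans[0].label} at {orphans[0].timestamp_s:.3f} s)",
            stacklevel=2,
        )
    return Recording(streams=aligned, markers=m_aligned)


@dataclass
class Epoch:
    """One sequence execution's multichannel segment.

    ``cue_offset_s`` is the Go cue's position relative to the epoch start
    (``t0_s``); ``step_offsets_s`` are the step-marker times relative to
    the cue.  The baseline window is expressed relative to the cue.
    """

    trial_index: int
    data: np.ndarray  # (n_channels, n_times) over the nominal epoch span
    fs_hz: float
    t0_s: float
    cue_offset_s: float
    step_offsets_s: List[float]
    pad_s: float = 0.1
    baseline_window_s: Tuple[float, float] = (-0.2, 0.0)
    channel_labels: List[str] = field(default_factory=list)
    block: int = -1
    #: Real recording samples flanking the epoch (may be empty).  Carried so
    #: time-frequency transforms can run on genuine signal instead of a
    #: synthetic boundary extension; always cropped from any result.
    context_pre: Optional[np.ndarray] = None
    context_post: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        offs = list(self.step_offsets_s)
        if any(b <= a for a, b in zip(offs, offs[1:])):
            raise InvalidInputError("step offsets must be strictly increasing")
        if self.pad_s < 0:
            raise InvalidInputError("pad_s must be >= 0")
        if not self.baseline_window_s[0] < self.baseline_window_s[1] <= 0:
            raise InvalidInputError("baseline window must precede the cue")

    @property
    def n_steps(self) -> int:
        return len(self.step_offsets_s)

    @property
    def times_rel_cue_s(self) -> np.ndarray:
        return np.arange(self.data.shape[1]) / self.fs_hz - self.cue_offset_s


def epoch_sample_count(duration_s: float, fs_hz: float) -> int:
    """Number of samples spanning ``duration_s`` at ``fs_hz`` (nearest integer).

    A 6 s execution at 500 Hz gives 3000 samples; executions in practice
    span roughly 1-6 s, i.e. about 500-3000 samples.
    """
    if duration_s <= 0:
        raise InvalidInputError("duration_s must be positive")
    if fs_hz <= 0:
        raise InvalidInputError("fs_hz must be positive")
    return int(np.floor(duration_s * fs_hz + 0.5))


def extract_sequence_epochs(
    stream: SignalStream,
    markers: MarkerStream,
    sequence_length: int = 6,
    pad_s: float = 0.1,
    baseline_s: float = 0.2,
    context_s: float = 1.0,
) -> List[Epoch]:
    """Cut one variable-length epoch per complete Go trial.

    Each epoch spans [cue - pad - baseline, last step + pad], mapped to
    sample indices by nearest-sample rounding (half-open windows).  Up to
    ``context_s`` of surrounding recording is attached on each side (for
    edge-free wavelet transforms; never part of the epoch proper).  NoGo
    trials and trials with missing step markers are skipped with a logged
    reason.
    """
    epochs: List[Epoch] = []
    for trial_index, ms in sorted(markers.by_trial().items()):
        cues = [m for m in ms if m.label == "CUE_GO"]
        if not cues:
            continue  # NoGo or non-trial markers
        cue = cues[0]
        steps = sorted(
            (m for m in ms if m.label.startswith("STEP_")),
            key=lambda m: m.timestamp_s,
        )
        if len(steps) < sequence_length:
            logger.info(
                "trial %d skipped: %d of %d step markers",
                trial_index, len(steps), sequence_length,
            )
            continue
        steps = steps[:sequence_length]
        start = cue.timestamp_s - pad_s - baseline_s
        end = steps[-1].timestamp_s + pad_s
        i0 = stream.index_of(start)
        n = epoch_sample_count(end - start, stream.fs_hz)
        if i0 < 0 or i0 + n > stream.n_times:
            logger.info("trial %d skipped: epoch outside recording span", trial_index)
            continue
        t0 = stream.start_time_s + i0 / stream.fs_hz
        ctx = int(np.floor(context_s * stream.fs_hz + 0.5))
        pre0 = max(i0 - ctx, 0)
        post1 = min(i0 + n + ctx, stream.n_times)
        epochs.append(
            Epoch(
                trial_index=trial_index,
                data=stream.samples[:, i0 : i0 + n].copy(),
                fs_hz=stream.fs_hz,
                t0_s=t0,
                cue_offset_s=cue.timestamp_s - t0,
                step_offsets_s=[m.timestamp_s - cue.timestamp_s for m in steps],
                pad_s=pad_s,
                baseline_window_s=(-baseline_s, 0.0),
                channel_labels=list(stream.channel_labels),
                block=cue.block,
                context_pre=stream.samples[:, pre0:i0].copy(),
                context_post=stream.samples[:, i0 + n : post1].copy(),
            )
        )
    return epochs


@dataclass
class MarkerReport:
    """Report of marker completeness against a schedule (report-only)."""

    complete_trials: List[int]
    incomplete_trials: Dict[int, str]
    orphan_markers: int
    duplicate_markers: int
    monotonic: bool

    @property
    def all_complete(self) -> bool:
        return not self.incomplete_trials


def validate_markers(
    markers: MarkerStream, schedule: SessionSchedule
) -> MarkerReport:
    """Check every scheduled trial has its full marker complement.

    A Go trial needs one cue plus one step marker per sequence step; a NoGo
    trial needs the cue only.  Markers whose trial index is not in the
    schedule count as orphans; repeated labels within a trial as duplicates.
    """
    ts = [m.timestamp_s for m in markers]
    monotonic = all(b >= a for a, b in zip(ts, ts[1:]))

    by_trial: Dict[int, List[EventMarker]] = {}
    for m in markers:
        if m.trial_index >= 0:
            by_trial.setdefault(m.trial_index, []).append(m)

    complete: List[int] = []
    incomplete: Dict[int, str] = {}
    scheduled: Dict[int, Tuple[bool, int]] = {}
    # Trials are indexed globally in marker streams (cumulative across blocks).
    gidx = 0
    for block in schedule.blocks:
        for t in block.trials:
            scheduled[gidx] = (t.is_go, len(t.sequence))
            gidx += 1

    duplicates = 0
    for idx, (is_go, seqlen) in scheduled.items():
        ms = by_trial.get(idx, [])
        labels = [m.label for m in ms]
        duplicates += len(labels) - len(set(labels))
        cues = [l for l in labels if l.startswith("CUE_")]
        nsteps = sum(1 for l in labels if l.startswith("STEP_"))
        if not cues:
            incomplete[idx] = "missing cue marker"
        elif is_go and nsteps < seqlen:
            incomplete[idx] = f"{nsteps} of {seqlen} step markers"
        else:
            complete.append(idx)
    orphans = sum(
        1 for m in markers if m.trial_index >= 0 and m.trial_index not in scheduled
    )
    return MarkerReport(
        complete_trials=complete,
        incomplete_trials=incomplete,
        orphan_markers=orphans,
        duplicate_markers=duplicates,
        monotonic=monotonic,
    )
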