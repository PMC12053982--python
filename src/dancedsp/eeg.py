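"""Theta ERD/S analysis of variable-length sequence-execution epochs.

Pipeline per epoch: zero-phase 0.3-30 Hz bandpass and average reference on
the continuous stream, Morlet wavelet power at 4-8 Hz, trimming of the
100 ms anti-edge padding, fixed-bin time normalization of the execution
span to 300 datapoints, reduction to six per-step bins, and

    ERD/S (%) = (P_timepoint - P_baseline) / P_baseline * 100

against the mean theta power in the 200 ms window before the Go cue.

Time normalization is the device that makes epochs of different durations
comparable: rather than warping samples, the execution span is covered by
equally spaced bins and each bin is replaced by its mean, so every epoch
reduces to the same number of datapoints while per-step structure is
retained (bins are aligned to the cue/step segments by default).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .errors import InvalidInputError
from .streams import Epoch, SignalStream

logger = logging.getLogger(__name__)

THETA_FREQS_HZ: Tuple[float, ...] = (4.0, 5.0, 6.0, 7.0, 8.0)


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase band-pass description (default 0.3-30 Hz)."""

    low_hz: float = 0.3
    high_hz: float = 30.0
    order: int = 4

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise InvalidInputError("need 0 < low_hz < high_hz")


@dataclass
class ThetaPower:
    """Band-average theta power over time for every channel (µV²).

    ``times_s`` are relative to the Go cue; ``power`` is (n_channels,
    n_times) and non-negative everywhere.
    """

    channel_labels: List[str]
    times_s: np.ndarray
    power: np.ndarray
    fs_hz: float

    def for_channel(self, label: str) -> np.ndarray:
        return self.power[self.channel_labels.index(label)]


@dataclass
class StepThetaProfile:
    """Per-step theta ERD/S percentages for one channel."""

    participant: str
    block: int
    channel: str
    erds_pct: List[float]

    def __post_init__(self) -> None:
        if any(e <= -100.0 for e in self.erds_pct):
            raise InvalidInputError("ERD/S percentages must exceed -100")


def bandpass(stream: SignalStream, spec: FilterSpec = FilterSpec()) -> SignalStream:
    """Zero-phase Butterworth band-pass; removes DC, preserves shape."""
    if stream.fs_hz <= 2.0 * spec.high_hz:
        raise InvalidInputError(
            f"sampling rate {stream.fs_hz} Hz too low for a {spec.high_hz} Hz band edge"
        )
    sos = butter(
        spec.order, [spec.low_hz, spec.high_hz], btype="bandpass",
        fs=stream.fs_hz, output="sos",
    )
    return stream.copy_with(sosfiltfilt(sos, stream.samples, axis=1))


def average_reference(stream: SignalStream) -> SignalStream:
    """Re-reference to the cross-channel mean (channel sum becomes ~0)."""
    if stream.samples.shape[0] < 2:
        raise InvalidInputError("average reference needs at least 2 channels")
    return stream.copy_with(stream.samples - stream.samples.mean(axis=0, keepdims=True))


def artifact_removal_hook(
    stream: SignalStream,
    method: Union[str, Callable[[SignalStream], SignalStream]] = "none",
) -> SignalStream:
    """Pluggable artifact-removal stage.

    ``"none"`` (the default) passes the stream through untouched; a
    callable is delegated to (e.g. an ICA-based cleaner).  Component-based
    artifact removal itself is out of scope here.
    """
    if callable(method):
        logger.info("artifact removal: delegating to %r", getattr(method, "__name__", method))
        return method(stream)
    if method == "none":
        logger.info("artifact removal: none")
        return stream
    raise InvalidInputError(f"unknown artifact-removal method: {method!r}")


@lru_cache(maxsize=8)
def _band_power_calibration(
    fs_hz: float, freqs: Tuple[float, ...], n_cycles: float
) -> float:
    """Scale turning mne's Morlet band power into physical µV² units.

    Computed so that a unit-amplitude sinusoid at the band centre yields a
    band-average power of 0.5 (= A²/2 for A = 1).
    """
    from mne.time_frequency import tfr_array_morlet

    f0 = float(np.median(freqs))
    dur = max(4.0 * n_cycles / min(freqs), 2.0)
    n = int(dur * fs_hz)
    t = np.arange(n) / fs_hz
    sig = np.sin(2.0 * np.pi * f0 * t)[None, None, :]
    p = tfr_array_morlet(
        sig, sfreq=fs_hz, freqs=np.asarray(freqs), n_cycles=n_cycles,
        output="power", verbose=False,
    )[0, 0]
    mid = p[:, n // 4 : 3 * n // 4].mean()
    return 0.5 / float(mid)


def morlet_theta_power(
    epoch: Epoch,
    freqs_hz: Sequence[float] = THETA_FREQS_HZ,
    n_cycles: float = 5.0,
    trim: bool = True,
) -> ThetaPower:
    """Band-average Morlet wavelet power of one epoch, in µV².

    The signal under the wavelet is extended beyond the epoch span by real
    surrounding recording where the epoch carries it (the preferred,
    edge-free case) and by reflection otherwise, so the wavelet never runs
    off the data; the extension is cropped from the result.  Finally the
    epoch's anti-edge padding is trimmed away, leaving the baseline window
    plus the execution span.
    """
    from mne.time_frequency import tfr_array_morlet

    freqs = tuple(float(f) for f in freqs_hz)
    fs = epoch.fs_hz
    n = epoch.data.shape[1]
    if n / fs < 1.0 / min(freqs):
        raise InvalidInputError(
            "epoch shorter than one period of the slowest analysis wavelet"
        )
    # 5 sigma_t of the slowest wavelet covers mne's full wavelet support.
    sigma_t = n_cycles / (2.0 * np.pi * min(freqs))
    half = int(np.ceil(5.0 * sigma_t * fs))
    pre = epoch.context_pre if epoch.context_pre is not None else np.empty((epoch.data.shape[0], 0))
    post = epoch.context_post if epoch.context_post is not None else np.empty((epoch.data.shape[0], 0))
    extended = np.concatenate([pre, epoch.data, post], axis=1)
    left = half - pre.shape[1]
    right = half - post.shape[1]
    padded = np.pad(
        extended, ((0, 0), (max(left, 0), max(right, 0))), mode="reflect"
    )
    power = tfr_array_morlet(
        padded[None], sfreq=fs, freqs=np.asarray(freqs), n_cycles=n_cycles,
        output="power", verbose=False,
    )[0]
    start = max(left, 0) + pre.shape[1]
    band = power.mean(axis=1)[:, start : start + n]
    band = band * _band_power_calibration(fs, freqs, n_cycles)
    times = np.arange(n) / fs - epoch.cue_offset_s
    if trim:
        k = int(np.floor(epoch.pad_s * fs + 0.5))
        band = band[:, k : n - k] if k > 0 else band
        times = times[k : n - k] if k > 0 else times
    return ThetaPower(
        channel_labels=list(epoch.channel_labels)
        or [f"ch{i}" for i in range(band.shape[0])],
        times_s=times,
        power=band,
        fs_hz=fs,
    )


def baseline_power(
    theta: ThetaPower, window_s: Tuple[float, float] = (-0.2, 0.0)
) -> np.ndarray:
    """Mean band power per channel over a pre-cue window (relative to cue)."""
    w0, w1 = window_s
    if w1 <= w0:
        raise InvalidInputError("empty baseline window")
    half_dt = 0.5 / theta.fs_hz
    if w0 < theta.times_s[0] - half_dt or w1 > theta.times_s[-1] + half_dt:
        raise InvalidInputError("baseline window lies outside the epoch")
    mask = (theta.times_s >= w0) & (theta.times_s < w1)
    if not mask.any():
        raise InvalidInputError("baseline window contains no samples")
    return theta.power[:, mask].mean(axis=1)


def _bin_means(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Reduce the last axis of ``x`` to ``n_bins`` equally spaced bin means.

    Bin edges are equally spaced over the sample span; a sample belongs to
    the bin containing its midpoint, with ties assigned to the lower bin.
    If there are fewer samples than bins, empty bins take the value of the
    nearest sample (with a warning).
    """
    n = x.shape[-1]
    if n < 1:
        raise InvalidInputError("cannot bin an empty segment")
    if n_bins < 1:
        raise InvalidInputError("n_bins must be >= 1")
    j = np.arange(n)
    q = n_bins * (2 * j + 1)  # 2*n*B * midpoint position
    b = q // (2 * n)
    b[q % (2 * n) == 0] -= 1
    b = np.clip(b, 0, n_bins - 1)
    counts = np.bincount(b, minlength=n_bins).astype(float)
    flat = x.reshape(-1, n)
    sums = np.zeros((flat.shape[0], n_bins))
    np.add.at(sums, (slice(None), b), flat)
    empty = counts == 0
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} empty bin(s): segment shorter than one sample "
            "per bin; filled with nearest-sample values",
            stacklevel=2,
        )
        centers = (np.flatnonzero(empty) + 0.5) * n / n_bins - 0.5
        nearest = np.clip(np.floor(centers + 0.5).astype(int), 0, n - 1)
        sums[:, empty] = flat[:, nearest]
        counts[empty] = 1.0
    out = sums / counts
    return out.reshape(x.shape[:-1] + (n_bins,))


def time_normalize(
    values: np.ndarray,
    times_s: np.ndarray,
    edges_s: Sequence[float],
    n_bins: int = 300,
    mode: str = "per_step",
) -> np.ndarray:
    """Reduce a variable-length series to exactly ``n_bins`` datapoints.

    ``edges_s`` are the segment boundaries on the series' time axis — for
    the default cue anchoring, [cue, step1, ..., step6].  In ``per_step``
    mode each of the ``len(edges)-1`` segments is reduced to an equal share
    of the bins (bins aligned to steps); in ``global`` mode the bins span
    the whole execution span regardless of step boundaries.  Boundaries map
    to sample indices by nearest-sample rounding; windows are half-open.
    """
    values = np.asarray(values, dtype=float)
    times_s = np.asarray(times_s, dtype=float)
    if values.shape[-1] != times_s.shape[0]:
        raise InvalidInputError("values and times_s lengths differ")
    edges = list(edges_s)
    if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
        raise InvalidInputError("edges_s must be at least two strictly increasing times")
    fs = 1.0 / float(np.mean(np.diff(times_s)))
    idx = [int(np.floor((e - times_s[0]) * fs + 0.5)) for e in edges]
    idx = [int(np.clip(i, 0, values.shape[-1])) for i in idx]
    if mode == "global":
        seg = values[..., idx[0] : idx[-1]]
        return _bin_means(seg, n_bins)
    if mode != "per_step":
        raise InvalidInputError(f"unknown time-normalization mode: {mode!r}")
    n_seg = len(edges) - 1
    if n_bins % n_seg != 0:
        raise InvalidInputError(
            f"n_bins={n_bins} not divisible by the {n_seg} segments"
        )
    per = n_bins // n_seg
    parts = []
    for k in range(n_seg):
        seg = values[..., idx[k] : idx[k + 1]]
        if seg.shape[-1] == 0:
            # Degenerate segment between adjacent markers: use nearest sample.
            warnings.warn(
                f"segment {k + 1} shorter than one sample; bins filled from "
                "the nearest sample",
                stacklevel=2,
            )
            near = int(np.clip(idx[k], 0, values.shape[-1] - 1))
            seg = values[..., near : near + 1]
        parts.append(_bin_means(seg, per))
    return np.concatenate(parts, axis=-1)


def step_bins(norm: np.ndarray, n_steps: int = 6) -> np.ndarray:
    """Collapse the time-normalized series into one mean per step.

    The normalized length (300 by default) must divide evenly into
    ``n_steps`` groups of consecutive bins (6 groups of 50 by default).
    """
    norm = np.asarray(norm, dtype=float)
    n = norm.shape[-1]
    if n % n_steps != 0:
        raise InvalidInputError(
            f"normalized length {n} is not divisible into {n_steps} step bins"
        )
    w = n // n_steps
    return norm.reshape(norm.shape[:-1] + (n_steps, w)).mean(axis=-1)


def erds_percent(
    power_timepoint: Union[float, np.ndarray],
    power_baseline: Union[float, np.ndarray],
) -> Union[float, np.ndarray]:
    """ERD/S % = (P_timepoint - P_baseline) / P_baseline * 100.

    Negative values are event-related desynchronization (power loss
    relative to baseline), positive values synchronization.  Invariant
    under common rescaling of both powers.
    """
    pb = np.asarray(power_baseline, dtype=float)
    if np.any(pb <= 0):
        raise InvalidInputError("baseline power must be strictly positive")
    out = (np.asarray(power_timepoint, dtype=float) - pb) / pb * 100.0
    return float(out) if np.isscalar(power_timepoint) and out.ndim == 0 else out


def epoch_step_powers(
    epoch: Epoch,
    freqs_hz: Sequence[float] = THETA_FREQS_HZ,
    n_cycles: float = 5.0,
    n_bins: int = 300,
    mode: str = "per_step",
    baseline_window_s: Optional[Tuple[float, float]] = None,
) -> Tuple[np.ndarray, np.ndarray, List[str]]:
    """Per-step theta power and baseline power for one epoch.

    Returns ``(step_power, base_power, channel_labels)`` with shapes
    (n_channels, n_steps) and (n_channels,).  This is the quantity pooled
    across epochs before forming ERD/S ratios.
    """
    theta = morlet_theta_power(epoch, freqs_hz=freqs_hz, n_cycles=n_cycles)
    window = baseline_window_s or epoch.baseline_window_s
    base = baseline_power(theta, window)
    edges = [0.0] + list(epoch.step_offsets_s)
    norm = time_normalize(theta.power, theta.times_s, edges, n_bins=n_bins, mode=mode)
    steps = step_bins(norm, n_steps=len(edges) - 1)
    return steps, base, theta.channel_labels


def erds_profile(
    epoch: Epoch,
    freqs_hz: Sequence[float] = THETA_FREQS_HZ,
    n_cycles: float = 5.0,
    n_bins: int = 300,
    mode: str = "per_step",
    participant: str = "",
) -> List[StepThetaProfile]:
    """Per-step theta ERD/S of a single epoch, one profile per channel."""
    steps, base, labels = epoch_step_powers(
        epoch, freqs_hz=freqs_hz, n_cycles=n_cycles, n_bins=n_bins, mode=mode
    )
    pct = erds_percent(steps, base[:, None])
    return [
        StepThetaProfile(
            participant=participant,
            block=epoch.block,
            channel=labels[c],
            erds_pct=list(np.asarray(pct)[c]),
        )
        for c in range(steps.shape[0])
    ]


def aggregate_erds(
    epochs: Sequence[Epoch],
    freqs_hz: Sequence[float] = THETA_FREQS_HZ,
    n_cycles: float = 5.0,
    n_bins: int = 300,
    mode: str = "per_step",
    aggregate: str = "pooled",
) -> Tuple[np.ndarray, List[str]]:
    """Across-epoch per-step ERD/S, (n_channels, n_steps), plus labels.

    ``aggregate="pooled"`` (default) averages step and baseline powers
    across epochs before taking the ratio — consistent in expectation even
    with a short, noisy baseline window.  ``"epochwise"`` averages the
    per-epoch ERD/S percentages instead; with few epochs or low SNR this
    estimator is biased upward because the noisy baseline sits in the
    denominator (Jensen's inequality).
    """
    if not epochs:
        raise InvalidInputError("no epochs to aggregate")
    if aggregate not in ("pooled", "epochwise"):
        raise InvalidInputError(f"unknown aggregation: {aggregate!r}")
    step_acc: List[np.ndarray] = []
    base_acc: List[np.ndarray] = []
    pct_acc: List[np.ndarray] = []
    labels: List[str] = []
    for ep in epochs:
        steps, base, labels = epoch_step_powers(
            ep, freqs_hz=freqs_hz, n_cycles=n_cycles, n_bins=n_bins, mode=mode
        )
        step_acc.append(steps)
        base_acc.append(base)
        if aggregate == "epochwise":
            pct_acc.append(np.asarray(erds_percent(steps, base[:, None])))
    if aggregate == "epochwise":
        return np.mean(pct_acc, axis=0), labels
    mean_steps = np.mean(step_acc, axis=0)
    mean_base = np.mean(base_acc, axis=0)
    return np.asarray(erds_percent(mean_steps, mean_base[:, None])), labels
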