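"""File formats, configuration and run manifests.

The on-disk recording container is a CSV bundle: one CSV per signal stream
(a time column plus one column per channel), a markers CSV, and a
``meta.json`` describing stream names, rates and labels.  The bundle is a
plain-text stand-in for an XDF container; an XDF reader is available when
the optional ``pyxdf`` package is installed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import FormatError, InvalidInputError
from .streams import EventMarker, MarkerStream, SignalStream
from .task import SessionSchedule, TrialResult

FLOAT_FMT = "%.10g"


# ---------------------------------------------------------------------------
# Configuration


def default_config() -> Dict:
    """Complete default pipeline configuration (YAML/JSON-serializable).

    ``task.sequences`` holds the two trained base sequences as U/D/L/R
    strings; the novel test pair defaults to the reversed base sequences.
    The 4 NoGo trials are additional to the 48 Go trials (52 per block).
    """
    return {
        "participant": 0,
        "seed": 0,
        "task": {
            "sequence_a": "LRUDRL",
            "sequence_b": "RULURD",
            "novel_a": "LRDURL",
            "novel_b": "DRULUR",
            "n_training_blocks": 4,
            "n_test_blocks": 2,
            "n_go_per_seq": 24,
            "n_nogo": 4,
            "midblock_break_after": 24,
            "midblock_break_s": 30,
            "interblock_break_s": 180,
            "long_break_after_block": 4,
            "long_break_s": 600,
            "timing": {
                "fixation_ms": 1000,
                "stimulus_ms": 750,
                "pre_cue_ms": 1500,
                "nogo_wait_ms": 3000,
                "feedback_ms": 1000,
            },
            "display": {  # informational only (screen geometry of the rig)
                "screen_diag_m": 1.96,
                "viewing_distance_m": 1.2,
                "stimulus_area_deg": 30,
            },
        },
        "simulate": {
            "rt_asymptote_ms": 300.0,
            "rt_gain_ms": 280.0,
            "rt_decay_per_trial": 0.025,
            "rt_noise_sd_ms": 50.0,
            "error_prob": 0.05,
            "eeg_fs_hz": 500.0,
            "kin_fs_hz": 100.0,
            "n_channels": 22,
            "theta_freq_hz": 6.0,
            "baseline_theta_amp_uv": 10.0,
            "erds_per_step_pct": [-30.0, -20.0, -10.0, 10.0, 20.0, 30.0],
            "pink_noise_sd_uv": 7.0,
        },
        "analysis": {
            "bandpass_low_hz": 0.3,
            "bandpass_high_hz": 30.0,
            "freqs_hz": [4, 5, 6, 7, 8],
            "n_cycles": 5.0,
            "n_bins": 300,
            "binning_mode": "per_step",
            "baseline_ms": 200,
            "pad_ms": 100,
            "epoch_anchor": "cue",
            "artifact_method": "none",
            "erds_aggregate": "pooled",
        },
        "kinematics": {"enabled": True, "accurate_only": True},
    }


def load_config(path: Union[str, Path]) -> Dict:
    """Load a YAML or JSON config file, merged over the defaults."""
    path = Path(path)
    with open(path) as fh:
        user = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    cfg = default_config()
    _deep_update(cfg, user or {})
    return cfg


def _deep_update(base: Dict, extra: Dict) -> None:
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v


# ---------------------------------------------------------------------------
# Schedule / results tables


def schedule_frame(session: SessionSchedule) -> pd.DataFrame:
    """One row per scheduled trial (global trial indexing across blocks)."""
    rows = []
    gidx = 0
    for block in session.blocks:
        for t in block.trials:
            rows.append(
                {
                    "block": block.block_index,
                    "phase": t.phase,
                    "familiarity": t.familiarity,
                    "trial_index": gidx,
                    "trial_in_block": t.trial_index,
                    "is_go": t.is_go,
                    "sequence": t.sequence.to_string(),
                }
            )
            gidx += 1
    return pd.DataFrame(rows)


def results_frame(results: Sequence[TrialResult]) -> pd.DataFrame:
    """One row per scored trial with per-step RT and correctness columns."""
    n = max((len(r.trial.sequence) for r in results), default=6)
    rows = []
    for gidx, r in enumerate(results):
        row = {
            "block": r.block_index,
            "trial_index": gidx,
            "phase": r.trial.phase,
            "familiarity": r.trial.familiarity,
            "is_go": r.trial.is_go,
            "sequence": r.trial.sequence.to_string(),
            "too_early": r.too_early,
            "feedback": r.feedback,
        }
        for k in range(n):
            row[f"rt_ms_{k + 1}"] = (
                r.step_rts_ms[k] if k < len(r.step_rts_ms) else np.nan
            )
            row[f"correct_{k + 1}"] = (
                bool(r.per_step_correct[k]) if k < len(r.per_step_correct) else None
            )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CSV-bundle recording container


def write_bundle(
    streams: Sequence[SignalStream],
    markers: MarkerStream,
    out_dir: Union[str, Path],
    extra_meta: Optional[Dict] = None,
) -> Path:
    """Write streams + markers + metadata as a plain-text CSV bundle."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta: Dict = {"format": "dancedsp-csv-bundle-v1", "streams": [], "version": __version__}
    for s in streams:
        df = pd.DataFrame(s.samples.T, columns=s.channel_labels)
        df.insert(0, "time_s", s.times_s)
        df.to_csv(out / f"{s.name}.csv", index=False, float_format=FLOAT_FMT)
        meta["streams"].append(
            {
                "name": s.name,
                "fs_hz": s.fs_hz,
                "start_time_s": s.start_time_s,
                "channel_labels": list(s.channel_labels),
            }
        )
    mdf = pd.DataFrame(
        [
            {
                "timestamp_s": m.timestamp_s,
                "label": m.label,
                "trial_index": m.trial_index,
                "block": m.block,
            }
            for m in markers
        ]
    )
    mdf.to_csv(out / "markers.csv", index=False, float_format=FLOAT_FMT)
    if extra_meta:
        meta["extra"] = extra_meta
    with open(out / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    return out


def read_bundle(
    in_dir: Union[str, Path]
) -> Tuple[Dict[str, SignalStream], MarkerStream]:
    """Read a CSV bundle back into streams and markers."""
    path = Path(in_dir)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise FormatError(f"no meta.json in {path}: not a CSV bundle")
    with open(meta_path) as fh:
        meta = json.load(fh)
    streams: Dict[str, SignalStream] = {}
    for s in meta.get("streams", []):
        f = path / f"{s['name']}.csv"
        if not f.exists():
            raise FormatError(f"stream file missing for declared stream {s['name']!r}")
        df = pd.read_csv(f)
        labels = s["channel_labels"]
        missing = [c for c in labels if c not in df.columns]
        if missing:
            raise FormatError(
                f"stream {s['name']!r}: channel columns missing: {missing}"
            )
        streams[s["name"]] = SignalStream(
            name=s["name"],
            channel_labels=labels,
            fs_hz=float(s["fs_hz"]),
            start_time_s=float(s["start_time_s"]),
            samples=df[labels].to_numpy().T,
        )
    mfile = path / "markers.csv"
    if not mfile.exists():
        raise FormatError(f"marker stream missing: no markers.csv in {path}")
    mdf = pd.read_csv(mfile)
    markers = MarkerStream(
        EventMarker(
            label=row.label,
            timestamp_s=float(row.timestamp_s),
            trial_index=int(row.trial_index),
            block=int(row.block),
        )
        for row in mdf.itertuples()
    )
    return streams, markers


def read_recording(
    path: Union[str, Path], format: str = "csv-bundle"
) -> Tuple[Dict[str, SignalStream], MarkerStream]:
    """Read a multistream recording: ``csv-bundle`` or ``xdf``.

    XDF support needs the optional ``pyxdf`` dependency.
    """
    if format == "csv-bundle":
        return read_bundle(path)
    if format == "xdf":
        return _read_xdf(path)
    raise FormatError(f"unknown recording format: {format!r}")


def _read_xdf(path: Union[str, Path]):
    try:
        import pyxdf  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise FormatError(
            "XDF support requires the optional 'pyxdf' package "
            "(pip install dancedsp[xdf]); the CSV bundle format needs no extras"
        ) from exc
    xstreams, _ = pyxdf.load_xdf(str(path))  # pragma: no cover
    streams: Dict[str, SignalStream] = {}
    marker_list: List[EventMarker] = []
    for xs in xstreams:  # pragma: no cover
        info = xs["info"]
        name = info["name"][0]
        srate = float(info["nominal_srate"][0])
        if srate == 0:  # marker stream
            for label, ts in zip(xs["time_series"], xs["time_stamps"]):
                marker_list.append(EventMarker(label=str(label[0]), timestamp_s=float(ts)))
        else:
            data = np.asarray(xs["time_series"], dtype=float).T
            streams[name] = SignalStream(
                name=name,
                channel_labels=[f"{name}{i}" for i in range(data.shape[0])],
                fs_hz=srate,
                start_time_s=float(xs["time_stamps"][0]),
                samples=data,
            )
    if not marker_list:  # pragma: no cover
        raise FormatError("XDF file contains no marker stream")
    return streams, MarkerStream(sorted(marker_list, key=lambda m: m.timestamp_s))


# ---------------------------------------------------------------------------
# Run manifest


@dataclass
class RunManifest:
    """Reproducibility record written by every pipeline run."""

    config: Dict
    seed: int
    version: str = __version__
    outputs: Dict[str, str] = field(default_factory=dict)  # filename -> sha256
    counts: Dict[str, int] = field(default_factory=dict)
    warnings: List[str] = field(default_factory=list)

    def add_output(self, path: Union[str, Path]) -> None:
        path = Path(path)
        self.outputs[path.name] = sha256_file(path)

    def write(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True, default=str)


def sha256_file(path: Union[str, Path]) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
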