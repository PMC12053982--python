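"""End-to-end pipeline: schedule -> simulate/read -> epochs -> tables.

Every run writes a set of tidy CSV tables plus a JSON manifest recording
the configuration, the seed, per-stage trial counts (so filter attrition
is auditable) and SHA-256 hashes of every output.  Runs are fully
deterministic for a fixed config and seed.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .eeg import (
    FilterSpec,
    aggregate_erds,
    artifact_removal_hook,
    average_reference,
    bandpass,
)
from .errors import EmptySummaryError
from .io import (
    FLOAT_FMT,
    RunManifest,
    default_config,
    results_frame,
    schedule_frame,
)
from .kinematics import CoMTrace, block_kinematics, segment_sequence
from .sequences import DanceSequence
from .simulate import SimParams, SyntheticSession, simulate_session
from .streams import extract_sequence_epochs, validate_markers
from .task import (
    SessionSchedule,
    TimingTemplate,
    block_summary,
    schedule_session,
)

logger = logging.getLogger(__name__)


def session_from_config(config: Dict) -> SessionSchedule:
    """Build the session schedule a config describes."""
    t = config["task"]
    pair = (
        DanceSequence.from_string(t["sequence_a"]),
        DanceSequence.from_string(t["sequence_b"]),
    )
    novel = (
        DanceSequence.from_string(t["novel_a"]),
        DanceSequence.from_string(t["novel_b"]),
    )
    return schedule_session(
        pair,
        novel,
        n_training=t["n_training_blocks"],
        n_test=t["n_test_blocks"],
        participant_index=config["participant"],
        seed=config["seed"],
        n_go_per_seq=t["n_go_per_seq"],
        n_nogo=t["n_nogo"],
        interblock_break_s=t["interblock_break_s"],
        long_break_after_block=t["long_break_after_block"],
        long_break_s=t["long_break_s"],
    )


def timing_from_config(config: Dict) -> TimingTemplate:
    return TimingTemplate(**config["task"]["timing"])


def simparams_from_config(config: Dict) -> SimParams:
    sim = dict(config["simulate"])
    sim["erds_per_step_pct"] = tuple(sim.get("erds_per_step_pct", ()))
    return SimParams(seed=config["seed"], **sim)


def run_pipeline(
    config: Optional[Dict] = None,
    out_dir: Union[str, Path] = "dancedsp_out",
    skip_kinematics: bool = False,
) -> Path:
    """Run schedule -> simulate -> epoch -> ERD/S + kinematics + behavior.

    Returns the output directory, which contains ``schedule.csv``,
    ``behavior.csv``, ``behavior_blocks.csv``, ``erds.csv``,
    ``kinematics_steps.csv``, ``kinematics_blocks.csv`` and
    ``manifest.json``.
    """
    config = config or default_config()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config, seed=config["seed"])
    participant = str(config["participant"])

    session = session_from_config(config)
    sched_df = schedule_frame(session)
    manifest.counts["scheduled_trials"] = len(sched_df)
    logger.info("scheduled %d trials", len(sched_df))

    sim = simulate_session(session, simparams_from_config(config), timing_from_config(config))
    results = sim.behavior.all_results
    manifest.counts["responded_go_trials"] = sum(
        1 for r in results if r.trial.is_go and not r.too_early
    )

    report = validate_markers(sim.markers, session)
    if not report.all_complete:
        manifest.warnings.append(
            f"{len(report.incomplete_trials)} trial(s) with incomplete markers"
        )

    beh_df = results_frame(results)
    block_rows = []
    for bi, block_results in enumerate(sim.behavior.results_by_block):
        try:
            mean_rt, mistake_pct = block_summary(block_results)
        except EmptySummaryError:
            continue
        block_rows.append(
            {
                "participant": participant,
                "block": bi,
                "mean_step_rt_ms": mean_rt,
                "mistake_pct": mistake_pct,
            }
        )
    beh_blocks_df = pd.DataFrame(block_rows)

    ana = config["analysis"]
    eeg = bandpass(
        sim.eeg, FilterSpec(ana["bandpass_low_hz"], ana["bandpass_high_hz"])
    )
    eeg = average_reference(eeg)
    eeg = artifact_removal_hook(eeg, ana.get("artifact_method", "none"))
    seqlen = len(config["task"]["sequence_a"])
    epochs = extract_sequence_epochs(
        eeg,
        sim.markers,
        sequence_length=seqlen,
        pad_s=ana["pad_ms"] / 1000.0,
        baseline_s=ana["baseline_ms"] / 1000.0,
    )
    manifest.counts["epoched_trials"] = len(epochs)
    logger.info("epoched %d trials", len(epochs))

    erds_rows = []
    by_block: Dict[int, List] = {}
    for ep in epochs:
        by_block.setdefault(ep.block, []).append(ep)
    for block, eps in sorted(by_block.items()):
        pct, labels = aggregate_erds(
            eps,
            freqs_hz=tuple(ana["freqs_hz"]),
            n_cycles=ana["n_cycles"],
            n_bins=ana["n_bins"],
            mode=ana["binning_mode"],
            aggregate=ana.get("erds_aggregate", "pooled"),
        )
        for c, label in enumerate(labels):
            for s in range(pct.shape[1]):
                erds_rows.append(
                    {
                        "participant": participant,
                        "block": block,
                        "channel": label,
                        "step": s + 1,
                        "erds_pct": pct[c, s],
                    }
                )
    erds_df = pd.DataFrame(erds_rows)
    manifest.counts["analyzed_blocks"] = len(by_block)

    frames = {
        "schedule.csv": sched_df,
        "behavior.csv": beh_df,
        "behavior_blocks.csv": beh_blocks_df,
        "erds.csv": erds_df,
    }

    if not skip_kinematics and config["kinematics"]["enabled"]:
        trace = CoMTrace.from_stream(sim.kinematics)
        accurate = {
            gidx for gidx, r in enumerate(results) if r.is_accurate
        }
        per_trial = []
        for gidx, r in enumerate(results):
            if not r.trial.is_go or r.too_early:
                continue
            k = segment_sequence(trace, sim.markers, gidx, sequence_length=seqlen)
            if k is not None:
                per_trial.append(k)
        step_rows = []
        for k in per_trial:
            for s in range(k.per_step_mean_velocity.shape[0]):
                for a, axis in enumerate(("x", "y", "z")):
                    step_rows.append(
                        {
                            "participant": participant,
                            "block": k.block,
                            "trial_index": k.trial_index,
                            "step": s + 1,
                            "axis": axis,
                            "mean_velocity_mps": k.per_step_mean_velocity[s, a],
                            "mean_abs_velocity_mps": k.per_step_mean_abs_velocity[s, a],
                        }
                    )
        kin_block_rows = []
        only_accurate = config["kinematics"].get("accurate_only", True)
        for block in sorted({k.block for k in per_trial}):
            try:
                bk = block_kinematics(
                    per_trial, block, accurate if only_accurate else None
                )
            except EmptySummaryError:
                continue
            for a, axis in enumerate(("x", "y", "z")):
                kin_block_rows.append(
                    {
                        "participant": participant,
                        "block": block,
                        "axis": axis,
                        "mean_velocity_mps": bk.mean_velocity_mps[a],
                        "sd_velocity_mps": bk.sd_velocity_mps[a],
                        "mean_abs_velocity_mps": bk.mean_abs_velocity_mps[a],
                        "n_trials": bk.n_trials,
                    }
                )
        frames["kinematics_steps.csv"] = pd.DataFrame(step_rows)
        frames["kinematics_blocks.csv"] = pd.DataFrame(kin_block_rows)
        manifest.counts["kinematic_trials"] = len(per_trial)

    for name, df in frames.items():
        path = out / name
        df.to_csv(path, index=False, float_format=FLOAT_FMT)
        manifest.add_output(path)
    manifest.write(out / "manifest.json")
    return out
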