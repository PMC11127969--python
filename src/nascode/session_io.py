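"""Session file formats: delimited-text tables plus a manifest.

A session directory holds three TSV tables (spikes, trials, trajectories), an
optional ground-truth sidecar (YAML key-value, synthetic sessions only) and a
manifest naming the dialect. Times are seconds from cue onset per trial;
row/column indices are 0-based; all windows are half-open [start, end).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synth import Session, SynthConfig

__all__ = ["write_session", "read_session", "validate_session"]

_FLOAT_FMT = "%.17g"  # round-trippable doubles

SPIKE_COLS = ["unit_id", "trial_id", "t_s"]
TRIAL_COLS = [
    "trial_id", "target_row", "target_col", "t_cue_on", "t_delay_on",
    "t_nav_on", "t_end", "iti_start", "iti_end", "correct",
]
TRAJ_COLS = ["trial_id", "t_s", "x", "y", "z"]


def write_session(session: Session, path: str | Path) -> Path:
    """Write a session to a directory of TSV tables plus manifest."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    session.spikes[SPIKE_COLS].to_csv(path / "spikes.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    session.trials[TRIAL_COLS].to_csv(path / "trials.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    session.trajectories[TRAJ_COLS].to_csv(
        path / "trajectories.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )
    session.units.to_csv(path / "units.tsv", sep="\t", index=False)
    manifest = {
        "format": "tsv",
        "files": {
            "spikes": "spikes.tsv",
            "trials": "trials.tsv",
            "trajectories": "trajectories.tsv",
            "units": "units.tsv",
        },
    }
    if session.ground_truth is not None:
        with open(path / "ground_truth.yaml", "w") as fh:
            yaml.safe_dump(session.ground_truth, fh)
        manifest["files"]["ground_truth"] = "ground_truth.yaml"
    with open(path / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh)
    return path


def read_session(path: str | Path) -> Session:
    path = Path(path)
    with open(path / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    files = manifest["files"]
    spikes = pd.read_csv(path / files["spikes"], sep="\t")
    trials = pd.read_csv(path / files["trials"], sep="\t")
    trials["correct"] = trials["correct"].astype(bool)
    trajectories = pd.read_csv(path / files["trajectories"], sep="\t")
    units = pd.read_csv(path / files["units"], sep="\t")
    gt = None
    cfg = None
    if "ground_truth" in files and (path / files["ground_truth"]).exists():
        with open(path / files["ground_truth"]) as fh:
            gt = yaml.safe_load(fh)
        if gt and "config" in gt:
            raw = {
                k: tuple(v) if isinstance(v, list) else v for k, v in gt["config"].items()
            }
            cfg = SynthConfig(**raw)
    return Session(
        units=units, trials=trials, spikes=spikes, trajectories=trajectories,
        ground_truth=gt, config=cfg,
    )


def validate_session(session: Session) -> list[str]:
    """Schema, ordering and referential checks. Returns the violation list
    (empty for a well-formed session); nothing is silently repaired."""
    v: list[str] = []
    trials = session.trials
    spikes = session.spikes

    for col in TRIAL_COLS:
        if col not in trials.columns:
            v.append(f"trials: missing column {col}")
    for col in SPIKE_COLS:
        if col not in spikes.columns:
            v.append(f"spikes: missing column {col}")
    if v:
        return v

    if trials["trial_id"].duplicated().any():
        v.append("trials: duplicated trial_id")
    bad_order = trials[
        ~(
            (trials.t_cue_on == 0.0)
            & (trials.t_cue_on < trials.t_delay_on)
            & (trials.t_delay_on < trials.t_nav_on)
            & (trials.t_nav_on < trials.t_end)
            & (trials.t_end <= trials.iti_start)
            & (trials.iti_start < trials.iti_end)
        )
    ]
    for row in bad_order.itertuples():
        v.append(f"trials: trial {row.trial_id} has non-increasing epoch onsets")
    bad_tgt = trials[~trials.target_row.isin([0, 1, 2]) | ~trials.target_col.isin([0, 1, 2])]
    for row in bad_tgt.itertuples():
        v.append(f"trials: trial {row.trial_id} target outside the 3x3 grid")

    known_trials = set(trials["trial_id"].tolist())
    orphan = spikes[~spikes["trial_id"].isin(known_trials)]
    for tid in sorted(orphan["trial_id"].unique().tolist()):
        v.append(f"spikes: reference to unknown trial {tid}")
    known_units = set(session.units["unit_id"].tolist())
    orphan_u = spikes[~spikes["unit_id"].isin(known_units)]
    for uid in sorted(orphan_u["unit_id"].unique().tolist()):
        v.append(f"spikes: reference to unknown unit {uid}")
    if (spikes["t_s"] < 0).any():
        v.append("spikes: negative spike times")

    end_by_trial = trials.set_index("trial_id")["iti_end"]
    joined = spikes.join(end_by_trial, on="trial_id")
    late = joined[joined["t_s"] >= joined["iti_end"]]
    for tid in sorted(late["trial_id"].unique().tolist()):
        v.append(f"spikes: trial {tid} has spikes at or beyond the recorded window")

    for (uid, tid), g in spikes.groupby(["unit_id", "trial_id"], sort=False):
        t = g["t_s"].to_numpy()
        if t.size > 1 and np.any(np.diff(t) < 0):
            v.append(f"spikes: unsorted spike times for unit {uid}, trial {tid}")

    traj_orphan = session.trajectories[~session.trajectories["trial_id"].isin(known_trials)]
    for tid in sorted(traj_orphan["trial_id"].unique().tolist()):
        v.append(f"trajectories: reference to unknown trial {tid}")
    return v
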