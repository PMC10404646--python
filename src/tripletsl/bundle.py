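"""Dataset bundle: the on-disk and in-memory layout of one experiment dataset.

A bundle holds the participant table, one familiarization stream per
participant × task, the raw keypress logs, the 2-AFC response tables, the
task configurations, and a provenance block (seeds, config hash, package
version).  On disk it is a directory of plain CSV/JSON files:

    participants.csv   streams.csv   keypresses.csv   afc_responses.csv
    configs.json       provenance.json   [truth.csv]

``truth.csv`` (simulated datasets only) carries the generator's
ground-truth parameters for parameter-recovery checks.
"""
from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .task_design import Stream, TaskConfig

__all__ = ["DatasetBundle", "write_bundle", "read_bundle", "validate_bundle"]

_PARTICIPANT_COLS = ["participant_id", "group", "age_years", "sex"]


@dataclass
class DatasetBundle:
    participants: pd.DataFrame
    streams: dict  # (participant_id, task) -> Stream
    keypresses: pd.DataFrame  # participant_id, task, time_ms
    afc_responses: pd.DataFrame  # participant_id, task, trial_id, item_id, correct
    configs: dict  # task -> TaskConfig
    provenance: dict = field(default_factory=dict)
    truth: pd.DataFrame | None = None

    def tasks_of(self, participant_id: str) -> list[str]:
        return sorted(t for (p, t) in self.streams if p == participant_id)


def config_hash(configs: dict) -> str:
    blob = json.dumps({k: v.to_dict() for k, v in sorted(configs.items())}, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _streams_frame(bundle: DatasetBundle) -> pd.DataFrame:
    frames = []
    for (pid, task), s in bundle.streams.items():
        f = s.to_frame()
        f.insert(0, "task", task)
        f.insert(0, "participant_id", pid)
        f["target_triplet_id"] = s.target_triplet_id
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


def write_bundle(bundle: DatasetBundle, path) -> Path:
    """Write a bundle as a directory of CSV/JSON files; returns the path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    bundle.participants.to_csv(path / "participants.csv", index=False)
    _streams_frame(bundle).to_csv(path / "streams.csv", index=False)
    bundle.keypresses.to_csv(path / "keypresses.csv", index=False)
    bundle.afc_responses.to_csv(path / "afc_responses.csv", index=False)
    if bundle.truth is not None:
        bundle.truth.to_csv(path / "truth.csv", index=False)
    with open(path / "configs.json", "w") as fh:
        json.dump({k: v.to_dict() for k, v in bundle.configs.items()}, fh, indent=1)
    prov = dict(bundle.provenance)
    prov.setdefault("config_hash", config_hash(bundle.configs))
    from . import __version__

    prov.setdefault("software_version", f"tripletsl {__version__}")
    with open(path / "provenance.json", "w") as fh:
        json.dump(prov, fh, indent=1)
    return path


def _require_columns(df: pd.DataFrame, cols, name: str, issues: list):
    for c in cols:
        if c not in df.columns:
            issues.append(f"{name}: missing required column {c!r}")


def validate_bundle(bundle: DatasetBundle) -> list[str]:
    """Return an itemized list of integrity problems (empty when valid)."""
    issues: list[str] = []
    _require_columns(bundle.participants, _PARTICIPANT_COLS, "participants", issues)
    _require_columns(bundle.keypresses, ["participant_id", "task", "time_ms"], "keypresses", issues)
    _require_columns(
        bundle.afc_responses, ["participant_id", "task", "trial_id", "item_id", "correct"], "afc_responses", issues
    )
    if issues:
        return issues

    pids = set(bundle.participants["participant_id"])
    known = set(bundle.streams)
    for name, df in (("keypresses", bundle.keypresses), ("afc_responses", bundle.afc_responses)):
        for i, (pid, task) in enumerate(zip(df["participant_id"], df["task"])):
            if pid not in pids:
                issues.append(f"{name} row {i}: unknown participant {pid!r}")
            elif (pid, task) not in known:
                issues.append(f"{name} row {i}: no stream for participant {pid!r} task {task!r}")
    times = pd.to_numeric(bundle.keypresses["time_ms"], errors="coerce")
    bad = np.flatnonzero(~np.isfinite(times.to_numpy(dtype=float)))
    issues.extend(f"keypresses row {i}: malformed timestamp" for i in bad[:20])
    for (pid, task) in bundle.streams:
        if pid not in pids:
            issues.append(f"streams: unknown participant {pid!r} (task {task!r})")
    if "correct" in bundle.afc_responses:
        vals = set(pd.unique(bundle.afc_responses["correct"])) - {0, 1, True, False}
        if vals:
            issues.append(f"afc_responses: non-binary 'correct' values {sorted(map(str, vals))[:5]}")
    return issues


def read_bundle(path) -> DatasetBundle:
    """Load and validate a bundle directory; raises ValidationError on failure.

    Participants with fewer streams than the bundle's task set (children who
    stopped after three of the four tasks) load fine with a warning.
    """
    path = Path(path)
    configs = {
        k: TaskConfig.from_dict(v) for k, v in json.load(open(path / "configs.json")).items()
    }
    participants = pd.read_csv(path / "participants.csv")
    sf = pd.read_csv(path / "streams.csv")
    streams = {}
    for (pid, task), grp in sf.groupby(["participant_id", "task"], sort=True):
        grp = grp.sort_values("index")
        cfg = configs[task]
        occ = grp["target_occurrence_index"].fillna(0).to_numpy(dtype=np.int64)
        streams[(pid, task)] = Stream(
            config=cfg,
            target_triplet_id=str(grp["target_triplet_id"].iloc[0]),
            stimulus_id=grp["stimulus_id"].to_numpy(dtype=object),
            onset_ms=grp["onset_ms"].to_numpy(dtype=float),
            triplet_id=grp["triplet_id"].to_numpy(dtype=object),
            within_triplet_position=grp["within_triplet_position"].to_numpy(dtype=np.int64),
            is_target=grp["is_target"].to_numpy(dtype=bool),
            target_occurrence_index=occ,
        )
    keypresses = pd.read_csv(path / "keypresses.csv")
    afc = pd.read_csv(path / "afc_responses.csv")
    truth = pd.read_csv(path / "truth.csv") if (path / "truth.csv").exists() else None
    provenance = json.load(open(path / "provenance.json")) if (path / "provenance.json").exists() else {}
    bundle = DatasetBundle(
        participants=participants,
        streams=streams,
        keypresses=keypresses,
        afc_responses=afc,
        configs=configs,
        provenance=provenance,
        truth=truth,
    )
    issues = validate_bundle(bundle)
    if issues:
        raise ValidationError(issues)
    n_tasks = len(configs)
    for pid in participants["participant_id"]:
        done = bundle.tasks_of(pid)
        if 0 < len(done) < n_tasks:
            missing = sorted(set(configs) - set(done))
            warnings.warn(f"participant {pid!r} missing task(s): {', '.join(missing)}", stacklevel=2)
    return bundle
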