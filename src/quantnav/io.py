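"""File formats, configuration loading and the run manifest.

All on-disk formats are plain text and versioned with a ``format_version``
field: trajectory logs are CSV, trial lists and response tables JSON-lines,
analysis results and the manifest JSON.  The manifest records the config
snapshot, the master seed and a SHA-256 per output file, so a rerun with an
equal manifest is reproducible bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .agents import EVENTS, TRAJ_COLUMNS, AgentParams, CohortData, SimConfig
from .errors import ConfigError, LogFormatError
from .protocols import (
    EstimationProtocol,
    EstimationTrialSpec,
    ForcedChoiceProtocol,
    ForcedChoiceTrialSpec,
    NavProtocol,
    NavTrialSpec,
)
from .space import Position, SpaceConfig

__all__ = [
    "FORMAT_VERSION",
    "RunManifest",
    "write_trajectory",
    "read_trajectory",
    "write_trials",
    "read_trials",
    "write_cohort",
    "read_cohort",
    "load_config",
    "file_sha256",
]

FORMAT_VERSION = 1


# --------------------------------------------------------------------------
# trajectory CSV
# --------------------------------------------------------------------------

def write_trajectory(log: pd.DataFrame, path) -> None:
    """Write a trajectory log as CSV with the documented header."""
    missing = [c for c in TRAJ_COLUMNS if c not in log.columns]
    if missing:
        raise LogFormatError(f"trajectory log missing columns {missing}")
    log[TRAJ_COLUMNS].to_csv(path, index=False)


def read_trajectory(path) -> pd.DataFrame:
    """Read and strictly validate a trajectory CSV.

    Checks the header, event labels and per-trial timestamp ordering;
    errors name the offending line (1-based, counting the header).
    """
    log = pd.read_csv(path)
    missing = [c for c in TRAJ_COLUMNS if c not in log.columns]
    if missing:
        raise LogFormatError(f"{path}: missing columns {missing}")
    bad_ev = ~log["event"].isin(EVENTS)
    if bad_ev.any():
        line = int(np.flatnonzero(bad_ev.to_numpy())[0]) + 2
        raise LogFormatError(
            f"{path}:{line}: unknown event label {log['event'][bad_ev].iloc[0]!r}")
    for c in ("t", "q1", "q2", "theta", "raw_speed"):
        if not np.issubdtype(log[c].dtype, np.number):
            raise LogFormatError(f"{path}: non-numeric column {c!r}")
    for (aid, trial), sub in log.groupby(["agent_id", "trial"]):
        dt = np.diff(sub["t"].to_numpy(dtype=float))
        if np.any(dt <= 0):
            line = int(sub.index[np.argmax(dt <= 0) + 1]) + 2
            raise LogFormatError(
                f"{path}:{line}: timestamps not strictly increasing "
                f"(agent {aid}, trial {trial})")
    return log


# --------------------------------------------------------------------------
# trial lists (JSON-lines)
# --------------------------------------------------------------------------

_TRIAL_TYPES = {
    "navigation": NavTrialSpec,
    "estimation": EstimationTrialSpec,
    "forced_choice": ForcedChoiceTrialSpec,
}


def _spec_to_dict(spec) -> dict:
    out = {}
    for f in dataclasses.fields(spec):
        v = getattr(spec, f.name)
        out[f.name] = [v.q1, v.q2] if isinstance(v, Position) else v
    return out


def _spec_from_dict(cls, d: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in d:
            continue
        v = d[f.name]
        if f.type in ("Position",) or (isinstance(v, list) and len(v) == 2
                                       and f.name in ("start", "goal", "A", "B", "C")):
            v = Position(*v)
        kwargs[f.name] = v
    return cls(**kwargs)


def write_trials(trials, task: str, path) -> None:
    """Serialize a trial list to JSON-lines with a versioned header record."""
    if task not in _TRIAL_TYPES:
        raise ConfigError(f"unknown task {task!r}")
    with open(path, "w") as fh:
        fh.write(json.dumps({"format_version": FORMAT_VERSION, "task": task,
                             "n_trials": len(trials)}) + "\n")
        for t in trials:
            fh.write(json.dumps(_spec_to_dict(t)) + "\n")


def read_trials(path):
    """Read a JSON-lines trial list written by :func:`write_trials`."""
    with open(path) as fh:
        try:
            header = json.loads(fh.readline())
        except json.JSONDecodeError as e:
            raise LogFormatError(f"{path}:1: bad header: {e}") from e
        task = header.get("task")
        if task not in _TRIAL_TYPES:
            raise LogFormatError(f"{path}:1: unknown task {task!r}")
        cls = _TRIAL_TYPES[task]
        trials = []
        for i, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            try:
                trials.append(_spec_from_dict(cls, json.loads(line)))
            except (json.JSONDecodeError, TypeError) as e:
                raise LogFormatError(f"{path}:{i}: malformed row: {e}") from e
    return trials


# --------------------------------------------------------------------------
# run manifest and cohort dataset directory
# --------------------------------------------------------------------------

def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record of one simulated dataset."""

    master_seed: int
    config: dict
    files: dict = field(default_factory=dict)
    format_version: int = FORMAT_VERSION
    package_version: str = ""

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))

    def verify(self, base_dir) -> None:
        base = Path(base_dir)
        for name, digest in self.files.items():
            p = base / name
            if not p.exists():
                raise LogFormatError(f"manifest names missing file {name}")
            if file_sha256(p) != digest:
                raise LogFormatError(f"checksum mismatch for {name}")


_COHORT_TABLES = ("agents", "nav_log", "nav_responses", "est_responses",
                  "fc_responses")


def write_cohort(cohort: CohortData, out_dir) -> RunManifest:
    """Write a cohort dataset (CSV tables + manifest) to a directory."""
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        master_seed=cohort.master_seed,
        config={"space": cohort.cfg.to_dict()},
        package_version=__version__,
    )
    for name in _COHORT_TABLES:
        path = out / f"{name}.csv"
        getattr(cohort, name).to_csv(path, index=False)
        manifest.files[path.name] = file_sha256(path)
    manifest.save(out / "manifest.json")
    return manifest


def read_cohort(in_dir, verify: bool = True) -> CohortData:
    """Load a cohort dataset directory written by :func:`write_cohort`."""
    base = Path(in_dir)
    mpath = base / "manifest.json"
    if not mpath.exists():
        raise LogFormatError(f"{in_dir}: no manifest.json")
    manifest = RunManifest.load(mpath)
    if verify:
        manifest.verify(base)
    tables = {name: pd.read_csv(base / f"{name}.csv") for name in _COHORT_TABLES}
    return CohortData(
        cfg=SpaceConfig.from_dict(manifest.config["space"]),
        master_seed=manifest.master_seed,
        **tables,
    )


# --------------------------------------------------------------------------
# configuration files
# --------------------------------------------------------------------------

_SECTION_TYPES = {
    "space": SpaceConfig,
    "sim": SimConfig,
    "nav": NavProtocol,
    "estimation": EstimationProtocol,
    "forced_choice": ForcedChoiceProtocol,
}


def _build(cls, d: dict, section: str):
    known = set(cls.__dataclass_fields__)
    for key in d:
        if key not in known:
            raise ConfigError(f"{section}.{key}: unknown key")
    try:
        return cls(**d)
    except (TypeError, ValueError) as e:
        raise ConfigError(f"{section}: {e}") from e


def load_config(path) -> dict:
    """Load and validate a YAML/JSON run configuration.

    Recognized sections: ``space``, ``sim``, ``nav``, ``estimation``,
    ``forced_choice``, ``agents`` (group label -> AgentParams fields),
    ``n_per_group``, ``master_seed``.  Unknown sections or keys raise
    :class:`ConfigError` naming the offending key.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    out: dict = {}
    for section, val in raw.items():
        if section in _SECTION_TYPES:
            if not isinstance(val, dict):
                raise ConfigError(f"{section}: must be a mapping")
            out[section] = _build(_SECTION_TYPES[section], val, section)
        elif section == "agents":
            out["agents"] = {}
            for group, params in (val or {}).items():
                if group not in ("MG", "GG"):
                    raise ConfigError(f"agents.{group}: unknown group")
                if "weber_fraction" in params and isinstance(
                        params["weber_fraction"], list):
                    params["weber_fraction"] = tuple(params["weber_fraction"])
                out["agents"][group] = _build(AgentParams, params,
                                              f"agents.{group}")
        elif section in ("n_per_group", "master_seed"):
            if not isinstance(val, int) or val < 0:
                raise ConfigError(f"{section}: must be a non-negative integer")
            out[section] = val
        else:
            raise ConfigError(f"{section}: unknown section")
    return out
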