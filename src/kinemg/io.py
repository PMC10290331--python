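"""Dataset bundles, CSV dialect and run configuration.

A *dataset bundle* is a directory holding ``manifest.json`` plus one HDF5
file per subject (raw EMG float32, motion float64, cue annotations).  The
manifest records the generating configuration, subject profiles, task
templates and a SHA-256 checksum of every file, so any result can be traced
back to its inputs.

The CSV dialect mirrors the recording schema for interoperability: motion
files carry ``time_s``, six named joint-angle columns (degrees), hand
position (m) and a wxyz unit quaternion; EMG files carry ``time_s`` and
``emg_1``..``emg_8``.  Columns are matched by name, never by position.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, fields
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .synth import JOINTS, RawRecording

__all__ = [
    "MOTION_COLUMNS",
    "EMG_COLUMNS",
    "save_bundle",
    "load_bundle",
    "write_motion_csv",
    "read_motion_csv",
    "write_emg_csv",
    "read_emg_csv",
    "RunConfig",
    "load_run_config",
]

MOTION_COLUMNS = (
    "time_s",
    *[f"{j}_deg" for j in JOINTS],
    "hand_x", "hand_y", "hand_z",
    "quat_w", "quat_x", "quat_y", "quat_z",
)

EMG_COLUMNS = ("time_s", *[f"emg_{i}" for i in range(1, 9)])


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def save_bundle(recordings: list[RawRecording], manifest: dict,
                directory: str | Path) -> Path:
    """Write recordings + manifest to a bundle directory; returns its path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = {}
    for rec in recordings:
        name = f"subject_{rec.subject_id:02d}.h5"
        path = directory / name
        with h5py.File(path, "w") as h5:
            h5.create_dataset("emg", data=np.asarray(rec.emg, np.float32))
            h5.create_dataset("motion", data=np.asarray(rec.motion, np.float64))
            h5.create_dataset("cue_onsets", data=np.asarray(rec.cue_onsets, np.int64))
            h5.create_dataset("labels", data=np.asarray(rec.labels, np.int64))
            if rec.activation is not None:
                h5.create_dataset("activation", data=np.asarray(rec.activation, np.float64))
            h5.attrs["subject_id"] = rec.subject_id
            h5.attrs["emg_rate"] = rec.emg_rate
            h5.attrs["motion_rate"] = rec.motion_rate
        files[name] = _sha256(path)
    full = dict(manifest)
    full["files"] = files
    (directory / "manifest.json").write_text(json.dumps(full, indent=2))
    return directory


def load_bundle(directory: str | Path) -> tuple[list[RawRecording], dict]:
    """Load a bundle, verifying every file checksum against the manifest."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    recordings = []
    for name, checksum in sorted(manifest["files"].items()):
        path = directory / name
        if not path.exists():
            raise FileNotFoundError(f"bundle file {name} listed in the manifest is missing")
        if _sha256(path) != checksum:
            raise ValueError(f"checksum mismatch for {name}: bundle is corrupt")
        with h5py.File(path, "r") as h5:
            recordings.append(RawRecording(
                subject_id=int(h5.attrs["subject_id"]),
                emg=h5["emg"][...], emg_rate=float(h5.attrs["emg_rate"]),
                motion=h5["motion"][...], motion_rate=float(h5.attrs["motion_rate"]),
                cue_onsets=h5["cue_onsets"][...],
                labels=[tuple(map(int, row)) for row in h5["labels"][...]],
                activation=h5["activation"][...] if "activation" in h5 else None,
            ))
    return recordings, manifest


def _check_columns(frame: pd.DataFrame, expected: tuple[str, ...], what: str):
    got, want = set(frame.columns), set(expected)
    if got != want:
        missing, extra = sorted(want - got), sorted(got - want)
        raise ValueError(f"{what} CSV schema violation: missing {missing}, extra {extra}")
    t = frame["time_s"].to_numpy()
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"{what} CSV: time_s must be strictly increasing")


def write_motion_csv(motion: np.ndarray, rate: float, path: str | Path) -> None:
    t = np.arange(motion.shape[0]) / rate
    frame = pd.DataFrame(np.column_stack([t, motion]), columns=list(MOTION_COLUMNS))
    frame.to_csv(path, index=False)


def read_motion_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Returns (time_s, motion block of 13 columns in canonical order)."""
    frame = pd.read_csv(path)
    _check_columns(frame, MOTION_COLUMNS, "motion")
    return (frame["time_s"].to_numpy(),
            frame[list(MOTION_COLUMNS[1:])].to_numpy(dtype=float))


def write_emg_csv(emg: np.ndarray, rate: float, path: str | Path) -> None:
    t = np.arange(emg.shape[0]) / rate
    frame = pd.DataFrame(np.column_stack([t, emg]), columns=list(EMG_COLUMNS))
    frame.to_csv(path, index=False)


def read_emg_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Returns (time_s, EMG block of 8 channels in canonical order)."""
    frame = pd.read_csv(path)
    _check_columns(frame, EMG_COLUMNS, "emg")
    return (frame["time_s"].to_numpy(),
            frame[list(EMG_COLUMNS[1:])].to_numpy(dtype=float))


@dataclass
class RunConfig:
    """Structured configuration of one end-to-end run."""

    protocol: str = "general"
    architecture: str = "RNN"
    feature_config: str = "ALL"
    seed: int = 0
    output_dir: str = "runs"
    # training
    learning_rate: float = 1e-3
    batch_size: int | None = None
    max_epochs: int = 100
    patience: int = 5
    # protocol layout
    n_subjects: int = 5
    n_tasks: int = 20
    n_repetitions: int = 18
    exclude_subject: int | None = None
    exclude_tasks: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def load_run_config(path: str | Path) -> RunConfig:
    """Load a YAML/JSON run configuration, rejecting unknown keys."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError("run config must be a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"unknown run-config keys: {unknown}")
    return RunConfig(**raw)
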