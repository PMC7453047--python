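"""On-disk formats: the epochs container, montage files, and run configs.

The epochs container is a directory holding ``metadata.json`` (format
version, sampling rate, time axis, channel names, lock, units, tensor
shape), ``data.bin`` (row-major float64, dimension order trial x channel x
time) and ``trials.tsv``.  Montages are tab-separated (name, x, y, z) plus a
neighbor-pair list.  Round trips are lossless and validated against the
metadata; corruption yields distinct error types rather than garbage data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import EpochSet, Montage

__all__ = [
    "EpochIOError",
    "MissingMemberError",
    "ShapeMismatchError",
    "UnsupportedVersionError",
    "write_epochs",
    "read_epochs",
    "write_montage",
    "read_montage",
    "RunConfig",
    "load_config",
]

CONTAINER_VERSION = 1


class EpochIOError(RuntimeError):
    """Base class for epochs-container errors."""


class MissingMemberError(EpochIOError):
    pass


class ShapeMismatchError(EpochIOError):
    pass


class UnsupportedVersionError(EpochIOError):
    pass


def write_epochs(epochs: EpochSet, path: str | Path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = dict(
        version=CONTAINER_VERSION,
        fs_hz=epochs.fs_hz,
        times_ms=[float(t) for t in epochs.times_ms],
        channels=list(epochs.channels),
        lock=epochs.lock,
        units=epochs.units,
        shape=list(epochs.data.shape),
        dim_order=["trial", "channel", "time"],
    )
    (path / "metadata.json").write_text(json.dumps(meta, indent=1))
    epochs.data.astype("<f8").tofile(path / "data.bin")
    epochs.trials.to_csv(path / "trials.tsv", sep="\t", index=False)
    return path


def read_epochs(path: str | Path) -> EpochSet:
    path = Path(path)
    for member in ("metadata.json", "data.bin", "trials.tsv"):
        if not (path / member).exists():
            raise MissingMemberError(f"missing container member {member!r} in {path}")
    meta = json.loads((path / "metadata.json").read_text())
    if meta.get("version") != CONTAINER_VERSION:
        raise UnsupportedVersionError(f"unsupported container version {meta.get('version')!r}")
    if meta.get("dim_order") != ["trial", "channel", "time"]:
        raise ShapeMismatchError(f"unexpected dim_order {meta.get('dim_order')!r}")
    shape = tuple(meta["shape"])
    raw = np.fromfile(path / "data.bin", dtype="<f8")
    if raw.size != int(np.prod(shape)):
        raise ShapeMismatchError(
            f"data.bin holds {raw.size} values; metadata declares shape {shape}"
        )
    trials = pd.read_csv(path / "trials.tsv", sep="\t")
    if len(meta["channels"]) != shape[1]:
        raise ShapeMismatchError("channel list does not match tensor shape")
    if len(meta["times_ms"]) != shape[2]:
        raise ShapeMismatchError("time axis does not match tensor shape")
    if len(trials) != shape[0]:
        raise ShapeMismatchError("trial table does not match tensor shape")
    return EpochSet(
        data=raw.reshape(shape),
        times_ms=np.asarray(meta["times_ms"], dtype=float),
        channels=list(meta["channels"]),
        trials=trials,
        lock=meta["lock"],
        units=meta["units"],
        fs_hz=float(meta["fs_hz"]),
    )


def write_montage(montage: Montage, path: str | Path) -> Path:
    path = Path(path)
    frame = pd.DataFrame(
        dict(
            name=montage.names,
            x=montage.positions[:, 0],
            y=montage.positions[:, 1],
            z=montage.positions[:, 2],
        )
    )
    pairs = montage.adjacency_pairs()
    frame["neighbors"] = [
        ",".join(montage.names[j] for j in np.flatnonzero(montage.adjacency[i]))
        for i in range(montage.n_channels)
    ]
    frame.to_csv(path, sep="\t", index=False)
    return path


def read_montage(path: str | Path) -> Montage:
    frame = pd.read_csv(path, sep="\t")
    names = list(frame["name"])
    pos = frame[["x", "y", "z"]].to_numpy(dtype=float)
    idx = {n: i for i, n in enumerate(names)}
    adj = np.zeros((len(names), len(names)), dtype=bool)
    for i, cell in enumerate(frame["neighbors"]):
        for n in str(cell).split(","):
            n = n.strip()
            if n:
                adj[i, idx[n]] = True
    adj |= adj.T  # enforce symmetry on read
    np.fill_diagonal(adj, False)
    return Montage(names=names, positions=pos, adjacency=adj)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_KNOWN_KEYS = {
    "epochs_dir", "montage_path", "behavior_path", "out_dir",
    "seed", "n_subjects", "n_channels", "fs_hz", "window_ms",
    "n_perm", "cluster_forming_p", "alpha_cluster", "predictor",
    "component_windows", "n_folds", "shrinkage_gamma",
    "stages", "calibration_targets", "jitter_levels", "log_level",
}


@dataclass
class RunConfig:
    """Pipeline configuration; unknown keys are rejected at load time."""

    epochs_dir: str | None = None
    montage_path: str | None = None
    behavior_path: str | None = None
    out_dir: str = "veplink_out"
    seed: int = 0
    n_subjects: int = 16
    n_channels: int = 32
    fs_hz: float = 200.0
    window_ms: tuple = (-100.0, 500.0)
    n_perm: int = 1000
    cluster_forming_p: float = 0.01
    alpha_cluster: float = 0.01
    predictor: str = "log_jitter"
    component_windows: tuple = (("C1", 60.0, 140.0), ("C2", 250.0, 350.0), ("C3", 350.0, 480.0))
    n_folds: int = 10
    shrinkage_gamma: float | None = None
    stages: tuple = ()
    calibration_targets: tuple = (0.95, 0.50, 6)
    jitter_levels: tuple = (1.0, 13.8, 26.6, 39.4, 52.2, 65.0)
    log_level: str = "INFO"

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def provenance(self) -> dict:
        return dict(config_hash=self.config_hash(), seed=self.seed)


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "window_ms" in raw:
        raw["window_ms"] = tuple(raw["window_ms"])
    if "component_windows" in raw:
        raw["component_windows"] = tuple(tuple(w) for w in raw["component_windows"])
    for key in ("stages", "calibration_targets", "jitter_levels"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)
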