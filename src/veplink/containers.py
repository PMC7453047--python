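"""In-memory containers shared across the pipeline.

An :class:`EpochSet` holds a trials x channels x time amplitude tensor
together with its trial table and time axis; a :class:`Montage` holds
electrode names, 3D positions and a symmetric neighbor relation used for
spatial clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["EpochSet", "Montage"]


@dataclass
class Montage:
    """Electrode layout: names, 3D positions, and spatial adjacency.

    Adjacency is a boolean (n, n) matrix; it must be symmetric and
    irreflexive, and every channel must have at least one neighbor.
    """

    names: list[str]
    positions: np.ndarray  # (n, 3)
    adjacency: np.ndarray  # (n, n) bool

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.adjacency = np.asarray(self.adjacency, dtype=bool)
        n = len(self.names)
        if self.positions.shape != (n, 3):
            raise ValueError(f"positions must be ({n}, 3), got {self.positions.shape}")
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency shape does not match channel count")
        if np.any(np.diag(self.adjacency)):
            raise ValueError("adjacency must be irreflexive")
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(self.adjacency.sum(axis=1) == 0):
            isolated = [self.names[i] for i in np.flatnonzero(self.adjacency.sum(axis=1) == 0)]
            raise ValueError(f"isolated channels (no neighbors): {isolated}")

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def adjacency_pairs(self) -> np.ndarray:
        """Return (k, 2) array of neighbor index pairs with i < j."""
        i, j = np.nonzero(np.triu(self.adjacency, 1))
        return np.column_stack([i, j])


@dataclass
class EpochSet:
    """Epoched multi-channel time series with its trial table.

    data has shape (n_trials, n_channels, n_times); times_ms is strictly
    increasing with a uniform step of 1000/fs; the trial table has one row
    per trial.
    """

    data: np.ndarray
    times_ms: np.ndarray
    channels: list[str]
    trials: pd.DataFrame
    lock: str = "stimulus"  # "stimulus" | "response"
    units: str = "uV"
    fs_hz: float = 200.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.lock not in ("stimulus", "response"):
            raise ValueError(f"unknown lock {self.lock!r}")
        nt, nc, ns = self.data.shape
        if len(self.channels) != nc:
            raise ValueError("channel names do not match tensor")
        if len(self.times_ms) != ns:
            raise ValueError("time axis does not match tensor")
        if len(self.trials) != nt:
            raise ValueError("trial table does not match tensor")
        steps = np.diff(self.times_ms)
        if len(steps) and (np.any(steps <= 0) or not np.allclose(steps, 1000.0 / self.fs_hz)):
            raise ValueError("times must increase uniformly with step 1000/fs")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def copy_with(self, **kwargs) -> "EpochSet":
        return replace(self, **kwargs)

    def time_index(self, t_ms: float) -> int:
        """Index of the sample nearest to t_ms."""
        return int(np.argmin(np.abs(self.times_ms - t_ms)))

    def time_window_slice(self, t_lo: float, t_hi: float) -> slice:
        """Slice covering samples with t_lo <= t <= t_hi (inclusive)."""
        idx = np.flatnonzero((self.times_ms >= t_lo) & (self.times_ms <= t_hi))
        if idx.size == 0:
            raise ValueError(f"window ({t_lo}, {t_hi}) ms outside epoch")
        return slice(int(idx[0]), int(idx[-1]) + 1)
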