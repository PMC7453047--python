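"""Shared fixtures for the veplink test suite."""

import numpy as np
import pandas as pd
import pytest

from veplink import synth
from veplink.containers import EpochSet


@pytest.fixture(scope="session")
def montage16():
    return synth.make_montage(16)


@pytest.fixture(scope="session")
def montage32():
    return synth.make_montage(32)


def make_epochs(
    data: np.ndarray,
    fs_hz: float = 200.0,
    t0_ms: float = -100.0,
    trials: pd.DataFrame | None = None,
    lock: str = "stimulus",
) -> EpochSet:
    """EpochSet around a raw (trials, channels, times) tensor with a minimal
    trial table (one subject, cycling jitter levels) unless one is given."""
    n_trials, n_channels, n_times = data.shape
    times = t0_ms + 1000.0 / fs_hz * np.arange(n_times)
    if trials is None:
        levels = np.resize(np.asarray(synth.DEFAULT_JITTER_LEVELS), n_trials)
        trials = pd.DataFrame(
            dict(
                subject=np.zeros(n_trials, dtype=int),
                condition=["contour_fixed"] * n_trials,
                jitter_deg=levels,
                orientation=np.resize(["vertical", "horizontal"], n_trials),
                response=np.resize(["vertical", "horizontal"], n_trials),
                correct=np.ones(n_trials, dtype=int),
                rt_ms=np.full(n_trials, 800.0),
            )
        )
    return EpochSet(
        data=data,
        times_ms=times,
        channels=[f"E{i:03d}" for i in range(n_channels)],
        trials=trials,
        lock=lock,
        units="z",
        fs_hz=fs_hz,
    )
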