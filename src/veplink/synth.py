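"""Synthetic behavior and EEG with known ground truth.

The behavioral generator draws trials from a probit observer over the
session schedule (blocks x six jitter levels, balanced stimulus
orientations, lognormal reaction times).  The EEG generator produces epoched
multi-channel data containing:

* spatially correlated Gaussian noise (exponential distance kernel on the
  montage) plus white noise,
* evoked components (Gaussian time kernel x spatial topography) with a
  per-subject latency offset drawn once per subject,
* a planted linear dependence of *rectified, z-scored* amplitude on log
  jitter at chosen channels/latencies, and
* a stimulus-orientation-dependent topography in a chosen window.

Planted-effect calibration.  The analysis pipeline average-references,
z-scores (one mean/SD per subject over all trials x channels x timepoints)
and rectifies before regressing on log jitter, so a "planted slope" is only
well defined on that scale.  The generator therefore (a) uses sign-balanced
(dipolar) channel gains so the spatial mean — and hence the average
reference — is unaffected by the effect, and (b) solves, per channel and
jitter level, for the signed pre-noise mean whose rectified expectation
equals ``pooled_sd * (baseline + slope * log jitter)``, where the pooled SD
is obtained by fixed-point iteration over the analytic second moment of the
generated data.  Component topographies are mean-centered across channels
for the same reason.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import EpochSet, Montage

__all__ = [
    "ObserverSpec",
    "Component",
    "JitterEffect",
    "ClassSignal",
    "EEGSpec",
    "GroundTruth",
    "simulate_behavior",
    "simulate_cohort_behavior",
    "implied_dprime_slope",
    "make_montage",
    "contiguous_channel_set",
    "simulate_epochs",
    "DEFAULT_JITTER_LEVELS",
    "ISI_SET_MS",
]

DEFAULT_JITTER_LEVELS = (1.0, 13.8, 26.6, 39.4, 52.2, 65.0)
ISI_SET_MS = (500, 550, 600, 650)


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

@dataclass
class ObserverSpec:
    """Probit observer plus session schedule.

    ``conditions`` maps condition name -> (mu, s, guess, lapse).  Defaults
    follow the EEG-session design: two conditions x two blocks of 432 trials,
    72 repetitions per jitter level per block (1728 trials total), lognormal
    RTs with mean ~820 ms, and ISIs drawn from {500, 550, 600, 650} ms.
    """

    conditions: dict = field(
        default_factory=lambda: {
            "contour_fixed": (40.0, 10.0, 0.5, 0.02),
            "surface_fixed": (40.0, 10.0, 0.5, 0.02),
        }
    )
    jitter_levels: tuple = DEFAULT_JITTER_LEVELS
    blocks_per_condition: int = 2
    trials_per_block: int = 432
    rt_mean_ms: float = 820.0
    rt_sd_ms: float = 119.0
    isi_set_ms: tuple = ISI_SET_MS

    def __post_init__(self) -> None:
        if self.trials_per_block % len(self.jitter_levels) != 0:
            raise ValueError(
                f"trials_per_block={self.trials_per_block} not divisible by "
                f"{len(self.jitter_levels)} jitter levels"
            )

    @property
    def reps_per_level(self) -> int:
        return self.trials_per_block // len(self.jitter_levels)

    @property
    def n_trials(self) -> int:
        return len(self.conditions) * self.blocks_per_condition * self.trials_per_block


def _probit_pc(j: float, params: tuple[float, float, float, float]) -> float:
    mu, s, g, l = params
    return g + (1.0 - g - l) * stats.norm.cdf((mu - j) / s)


def implied_dprime_slope(
    params: tuple[float, float, float, float], levels=DEFAULT_JITTER_LEVELS
) -> tuple[float, float]:
    """(beta0, beta1) of log d' on log jitter implied by a probit observer.

    Expected per-level d' = 2 Phi^{-1}(PC(level)); levels at or below chance
    are dropped (no logarithm), mirroring the estimation path.
    """
    lev = np.asarray(levels, dtype=float)
    pc = np.array([_probit_pc(j, params) for j in lev])
    d = 2.0 * stats.norm.ppf(pc)
    ok = d > 0
    x = np.log(lev[ok])
    y = np.log(d[ok])
    xc = x - x.mean()
    b1 = float(np.sum(xc * y) / np.sum(xc**2))
    b0 = float(y.mean() - b1 * x.mean())
    return b0, b1


def simulate_behavior(spec: ObserverSpec, seed: int, subject: int = 0) -> pd.DataFrame:
    """Simulate one observer's trial table over the full session schedule."""
    rng = np.random.default_rng(seed)
    lev = np.asarray(spec.jitter_levels, dtype=float)
    reps = spec.reps_per_level
    if reps % 2 != 0:
        raise ValueError("repetitions per level must be even to balance orientations")
    # lognormal with the requested mean/SD
    cv2 = (spec.rt_sd_ms / spec.rt_mean_ms) ** 2
    ln_sigma = math.sqrt(math.log1p(cv2))
    ln_mu = math.log(spec.rt_mean_ms) - 0.5 * ln_sigma**2

    rows = []
    trial = 0
    for condition, params in spec.conditions.items():
        for block in range(spec.blocks_per_condition):
            jitters = np.repeat(lev, reps)
            orientations = np.tile(
                np.concatenate([np.repeat("vertical", reps // 2), np.repeat("horizontal", reps - reps // 2)]),
                len(lev),
            )
            order = rng.permutation(len(jitters))
            jitters, orientations = jitters[order], orientations[order]
            pcs = np.array([_probit_pc(j, params) for j in jitters])
            correct = rng.random(len(jitters)) < pcs
            rts = rng.lognormal(ln_mu, ln_sigma, size=len(jitters))
            isis = rng.choice(spec.isi_set_ms, size=len(jitters))
            for j, ori, c, rt, isi in zip(jitters, orientations, correct, rts, isis):
                resp = ori if c else ("horizontal" if ori == "vertical" else "vertical")
                rows.append(
                    dict(
                        trial=trial, subject=subject, condition=condition, block=block,
                        jitter_deg=float(j), orientation=ori, response=resp,
                        correct=bool(c), rt_ms=float(rt), isi_ms=int(isi),
                    )
                )
                trial += 1
    return pd.DataFrame(rows)


def simulate_cohort_behavior(spec: ObserverSpec, n_subjects: int, seed: int) -> pd.DataFrame:
    """Concatenate independent observers sharing one spec (seeded per subject)."""
    seq = np.random.SeedSequence(seed).spawn(n_subjects)
    tables = [
        simulate_behavior(spec, seed=int(s.generate_state(1)[0] % (2**31)), subject=i)
        for i, s in enumerate(seq)
    ]
    return pd.concat(tables, ignore_index=True)


# ---------------------------------------------------------------------------
# montage
# ---------------------------------------------------------------------------

def make_montage(n_channels: int = 128, neighbor_factor: float = 1.6) -> Montage:
    """Fibonacci-spiral layout on the upper unit hemisphere.

    Adjacency joins channel pairs closer than ``neighbor_factor`` times the
    median nearest-neighbor distance; the factor is widened automatically
    until the median neighbor count lies in [4, 10].
    """
    if n_channels < 2:
        raise ValueError("need at least 2 channels")
    i = np.arange(n_channels)
    z = (i + 0.5) / n_channels  # heights above the equator
    r = np.sqrt(1.0 - z**2)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = i * golden
    pos = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    names = [f"E{k + 1:03d}" for k in range(n_channels)]
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    nn = d.min(axis=1)
    factor = neighbor_factor
    for _ in range(20):
        adj = d < factor * np.median(nn)
        med = np.median(adj.sum(axis=1))
        if med < 4:
            factor *= 1.15
        elif med > 10:
            factor /= 1.15
        else:
            break
    adj = d < factor * np.median(nn)
    np.fill_diagonal(adj, False)
    return Montage(names=names, positions=pos, adjacency=adj)


# ---------------------------------------------------------------------------
# EEG spec
# ---------------------------------------------------------------------------

@dataclass
class Component:
    """Evoked component: spatial bump topography x Gaussian time kernel."""

    label: str
    latency_ms: float
    latency_sd_ms: float  # SD of the per-subject latency offset
    width_ms: float
    amplitude: float
    peak_channel: int = 0  # channel index at which the spatial bump is centered
    spatial_scale: float = 0.6  # kernel length on the unit sphere


@dataclass
class JitterEffect:
    """Planted dependence of rectified z-scored amplitude on log jitter."""

    channels: tuple  # channel indices carrying the effect
    window_ms: tuple  # (t_lo, t_hi)
    slope: float  # rectified z-units per log-degree
    baseline: float = 3.5  # rectified z-units at log jitter = 0


@dataclass
class ClassSignal:
    """Stimulus-orientation-dependent topography (sign flips by class)."""

    channels: tuple
    window_ms: tuple
    amplitude: float
    spatial_scale: float = 0.6


@dataclass
class EEGSpec:
    n_channels: int = 128
    fs_hz: float = 200.0
    window_ms: tuple = (-100.0, 500.0)
    noise_corr_sd: float = 0.8
    noise_white_sd: float = 0.6
    noise_corr_scale: float = 0.7  # exponential kernel length (unit-sphere distance)
    components: tuple = ()
    effects: tuple = ()
    class_signal: "ClassSignal | None" = None

    def times_ms(self) -> np.ndarray:
        step = 1000.0 / self.fs_hz
        n = int(round((self.window_ms[1] - self.window_ms[0]) / step)) + 1
        return self.window_ms[0] + step * np.arange(n)


@dataclass
class GroundTruth:
    """Planted parameters; consumed only by tests."""

    effect_mask: np.ndarray  # (C, T) bool, union over effects
    effect_slopes: list  # per effect: (mask (C,T), slope)
    component_latency_ms: dict  # label -> {subject: latency used}
    component_peak_channel: dict  # label -> channel index (post-centering argmax)
    class_mask: "np.ndarray | None"  # (C, T) bool
    class_topography: "np.ndarray | None"  # (C,)
    pooled_sd: dict  # subject -> analytic pooled SD used for calibration


def contiguous_channel_set(montage: Montage, seed_channel: int, k: int) -> tuple:
    """k channel indices forming a connected set under the montage adjacency.

    Breadth-first growth from ``seed_channel``; use this to plant effects
    whose ground-truth extent is a single spatial cluster.
    """
    if k < 1 or k > montage.n_channels:
        raise ValueError("k out of range")
    seen = [seed_channel]
    frontier = [seed_channel]
    while len(seen) < k and frontier:
        nxt = []
        for ch in frontier:
            for nb in np.flatnonzero(montage.adjacency[ch]):
                if nb not in seen:
                    seen.append(int(nb))
                    nxt.append(int(nb))
                    if len(seen) == k:
                        return tuple(seen)
        frontier = nxt
    if len(seen) < k:
        raise ValueError("montage adjacency cannot grow a connected set of that size")
    return tuple(seen[:k])


def _noise_covariance(spec: EEGSpec, montage: Montage) -> np.ndarray:
    d = np.linalg.norm(montage.positions[:, None, :] - montage.positions[None, :, :], axis=-1)
    cov = spec.noise_corr_sd**2 * np.exp(-d / spec.noise_corr_scale)
    cov += spec.noise_white_sd**2 * np.eye(len(d))
    return cov


def _bump_topography(montage: Montage, peak_channel: int, scale: float) -> np.ndarray:
    """Gaussian spatial bump, mean-centered so the average reference keeps it."""
    d = np.linalg.norm(montage.positions - montage.positions[peak_channel], axis=1)
    topo = np.exp(-(d**2) / (2 * scale**2))
    topo = topo - topo.mean()
    return topo / np.abs(topo).max()


def _effect_gains(channels: tuple, n_channels: int) -> np.ndarray:
    """Sign-balanced (dipolar) unit gains over the effect channels."""
    g = np.zeros(n_channels)
    signs = np.where(np.arange(len(channels)) % 2 == 0, 1.0, -1.0)
    if len(channels) % 2 == 1:
        # keep the spatial sum zero for odd counts by down-weighting evenly
        signs = signs - signs.mean()
        signs = signs / np.abs(signs).max()
    g[np.asarray(channels)] = signs
    return g


def _rectified_mean(mu: float, sigma: float) -> float:
    """E|mu + eps| for eps ~ N(0, sigma)."""
    z = mu / sigma
    return mu * (1.0 - 2.0 * stats.norm.cdf(-z)) + sigma * math.sqrt(2.0 / math.pi) * math.exp(-0.5 * z * z)


def _solve_rectified_mean(target: float, sigma: float) -> float:
    """Smallest mu >= 0 with E|mu + eps| = target (monotone for mu >= 0)."""
    floor = sigma * math.sqrt(2.0 / math.pi)
    if target < floor - 1e-12:
        raise ValueError(
            f"rectified target {target:.3f} below the noise floor {floor:.3f}; "
            "raise the effect baseline"
        )
    hi = max(target + 6.0 * sigma, 1.0)
    return float(optimize.brentq(lambda m: _rectified_mean(m, sigma) - target, 0.0, hi, xtol=1e-10))


def _window_mask(times: np.ndarray, window_ms: tuple) -> np.ndarray:
    return (times >= window_ms[0]) & (times <= window_ms[1])


def simulate_epochs(
    eeg_spec: EEGSpec,
    behavior: pd.DataFrame,
    montage: Montage,
    seed: int,
) -> tuple[EpochSet, GroundTruth]:
    """Simulate epochs for every trial in ``behavior`` (all subjects).

    Returns the EpochSet plus a ground-truth sidecar with the planted masks,
    slopes, per-subject component latencies and the analytic pooled SD used
    to calibrate the rectified-slope effect.
    """
    if behavior.empty:
        raise ValueError("behavior table is empty")
    behavior = behavior.reset_index(drop=True)
    C = eeg_spec.n_channels
    if montage.n_channels != C:
        raise ValueError("montage does not match spec channel count")
    times = eeg_spec.times_ms()
    T = len(times)
    for eff in eeg_spec.effects:
        if eff.window_ms[0] < times[0] or eff.window_ms[1] > times[-1]:
            raise ValueError(f"effect window {eff.window_ms} outside epoch")
    cov = _noise_covariance(eeg_spec, montage)
    H = np.eye(C) - np.ones((C, C)) / C
    cov_ref = H @ cov @ H
    sigma_ref = np.sqrt(np.diag(cov_ref))  # per-channel noise SD after average reference
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(C))

    levels = np.sort(behavior["jitter_deg"].unique())
    log_levels = np.log(levels)

    # spatial pieces shared by all subjects
    comp_topos = {
        c.label: c.amplitude * _bump_topography(montage, c.peak_channel, c.spatial_scale)
        for c in eeg_spec.components
    }
    # the class topography is a zero-mean bump over ALL channels (so the
    # average reference leaves it intact); ``channels[0]`` sets the bump peak
    class_topo = None
    class_mask = None
    if eeg_spec.class_signal is not None:
        cs = eeg_spec.class_signal
        class_topo = cs.amplitude * _bump_topography(montage, cs.channels[0], cs.spatial_scale)
        class_mask = np.zeros((C, T), dtype=bool)
        class_mask[:, _window_mask(times, cs.window_ms)] = True

    effect_masks = []
    effect_gains = []
    for eff in eeg_spec.effects:
        mask = np.zeros((C, T), dtype=bool)
        mask[np.asarray(eff.channels)[:, None], _window_mask(times, eff.window_ms)] = True
        effect_masks.append(mask)
        effect_gains.append(_effect_gains(eff.channels, C))

    subjects = behavior["subject"].unique()
    root = np.random.SeedSequence(seed)
    subj_seeds = {s: ss for s, ss in zip(subjects, root.spawn(len(subjects)))}

    data = np.empty((len(behavior), C, T))
    latencies: dict[str, dict] = {c.label: {} for c in eeg_spec.components}
    pooled_sds: dict = {}

    for subj in subjects:
        rng = np.random.default_rng(subj_seeds[subj])
        rows = behavior.index[behavior["subject"] == subj].to_numpy()
        btab = behavior.loc[rows]
        n_trials = len(rows)

        # per-subject component latency offsets (drawn once per subject)
        comp_kernels = {}
        for comp in eeg_spec.components:
            lat = comp.latency_ms + rng.normal(0.0, comp.latency_sd_ms)
            latencies[comp.label][subj] = float(lat)
            comp_kernels[comp.label] = np.exp(-((times - lat) ** 2) / (2 * comp.width_ms**2))

        comp_field = np.zeros((C, T))
        for comp in eeg_spec.components:
            comp_field += comp_topos[comp.label][:, None] * comp_kernels[comp.label][None, :]

        # --- calibrate the planted rectified-slope means (fixed point on sd)
        sd_pool = 1.0
        mu_tables = []  # per effect: (C_eff, n_levels) signed means, plus masks
        for _ in range(40):
            mu_tables = []
            second = comp_field**2  # E[x^2] accumulator per (c, t), starts with components
            mean_field = comp_field.copy()
            if class_topo is not None:
                # orientation-balanced: mean 0, second moment topo^2 in window
                cmask = _window_mask(times, eeg_spec.class_signal.window_ms)
                add = np.zeros((C, T))
                add[:, cmask] = class_topo[:, None] ** 2
                second = second + add
            for eff, gains in zip(eeg_spec.effects, effect_gains):
                tmask = _window_mask(times, eff.window_ms)
                mus = np.zeros((len(eff.channels), len(levels)))
                for ci, ch in enumerate(eff.channels):
                    for li, lj in enumerate(log_levels):
                        target = sd_pool * (eff.baseline + eff.slope * lj)
                        mus[ci, li] = _solve_rectified_mean(target, sigma_ref[ch])
                mu_tables.append((eff, mus, tmask))
                # level-averaged second moment at effect points
                m2_eff = (mus**2).mean(axis=1)
                for ci, ch in enumerate(eff.channels):
                    second[ch, tmask] += m2_eff[ci]
                    mean_field_contrib = gains[ch] * mus[ci].mean()
                    mean_field[ch, tmask] += mean_field_contrib
            noise_m2 = (sigma_ref**2).mean()
            m2 = noise_m2 + second.mean()
            m1 = mean_field.mean()
            new_sd = math.sqrt(max(m2 - m1**2, 1e-12))
            if abs(new_sd - sd_pool) < 1e-10:
                sd_pool = new_sd
                break
            sd_pool = new_sd
        pooled_sds[subj] = sd_pool

        # --- assemble trials
        noise = chol @ rng.standard_normal((C, n_trials * T))
        block = noise.reshape(C, n_trials, T).transpose(1, 0, 2)
        block += comp_field[None, :, :]

        lev_index = np.searchsorted(levels, btab["jitter_deg"].to_numpy())
        for eff_i, (eff, mus, tmask) in enumerate(mu_tables):
            gains = effect_gains[eff_i]
            for ci, ch in enumerate(eff.channels):
                block[:, ch, tmask] += gains[ch] * mus[ci, lev_index][:, None]

        if class_topo is not None:
            cmask = _window_mask(times, eeg_spec.class_signal.window_ms)
            sign = np.where(btab["orientation"].to_numpy() == "vertical", 1.0, -1.0)
            block[:, :, cmask] += sign[:, None, None] * class_topo[None, :, None]
        data[rows] = block

    epochs = EpochSet(
        data=data,
        times_ms=times,
        channels=list(montage.names),
        trials=behavior.reset_index(drop=True),
        lock="stimulus",
        units="sim",
        fs_hz=eeg_spec.fs_hz,
    )
    union_mask = np.zeros((C, T), dtype=bool)
    for m in effect_masks:
        union_mask |= m
    truth = GroundTruth(
        effect_mask=union_mask,
        effect_slopes=[(m, e.slope) for m, e in zip(effect_masks, eeg_spec.effects)],
        component_latency_ms=latencies,
        component_peak_channel={
            c.label: int(np.argmax(np.abs(comp_topos[c.label]))) for c in eeg_spec.components
        },
        class_mask=class_mask,
        class_topography=class_topo,
        pooled_sd=pooled_sds,
    )
    return epochs, truth
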