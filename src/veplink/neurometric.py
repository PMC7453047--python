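"""Mass-univariate linking of rectified VEP amplitude to cue jitter.

Pipeline: average-reference, z-score (one mean/SD per subject over all
trials x channels x timepoints), rectify; regress single-trial rectified
amplitude on log jitter per (channel, timepoint) and subject; test the
per-subject slope maps against zero with a group-level sign-flip
cluster-based permutation test (cluster mass = sum of |t| over connected
suprathreshold points of the same sign, spatial adjacency x temporal
contiguity); retain the points inside significant clusters whose
cross-subject mean slope falls within the 95% CI of the behavioral
d'-jitter slope.  The same machinery applies to response-locked epochs after
re-centering each trial on its reaction time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

from .containers import EpochSet, Montage
from .psychometrics import DPrimeRegression

__all__ = [
    "SlopeMap",
    "Cluster",
    "ClusterResult",
    "MatchMask",
    "preprocess_epochs",
    "fit_slope_map",
    "fit_slope_maps_by_subject",
    "cluster_permutation",
    "behavioral_slope_ci",
    "match_behavioral_ci",
    "relock_to_response",
]

logger = logging.getLogger(__name__)


@dataclass
class SlopeMap:
    """Per-subject regression slopes: (subjects, channels, times)."""

    slopes: np.ndarray
    channels: list[str]
    times_ms: np.ndarray
    subjects: list
    predictor_desc: str = "log_jitter"


@dataclass
class Cluster:
    mask: np.ndarray  # (C, T) bool
    sign: int  # +1 / -1
    mass: float  # sum of |t| over member points
    p_value: float


@dataclass
class ClusterResult:
    clusters: list
    t_map: np.ndarray  # (C, T)
    t_threshold: float
    alpha_cluster: float
    cluster_forming_p: float
    n_permutations: int
    seed: int

    def significant(self) -> list:
        return [c for c in self.clusters if c.p_value <= self.alpha_cluster]

    def significant_mask(self) -> np.ndarray:
        mask = np.zeros_like(self.t_map, dtype=bool)
        for c in self.significant():
            mask |= c.mask
        return mask

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                dict(
                    cluster=i + 1, sign=c.sign, mass=c.mass, p_value=c.p_value,
                    n_points=int(c.mask.sum()),
                    n_channels=int(c.mask.any(axis=1).sum()),
                    n_times=int(c.mask.any(axis=0).sum()),
                )
                for i, c in enumerate(self.clusters)
            ]
        )


@dataclass
class MatchMask:
    point_mask: np.ndarray  # (C, T): pointwise mean slope inside the CI
    cluster_mask: np.ndarray  # (C, T): clusters whose average slope is inside
    behavioral_ci: tuple


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess_epochs(
    epochs: EpochSet,
    reference: bool = True,
    zscore: bool = True,
    rectify: bool = True,
) -> EpochSet:
    """Average-reference -> per-subject z-score -> rectify (each toggleable).

    The z-score uses a single mean/SD per subject computed over all trials,
    channels and timepoints of that subject.
    """
    if epochs.n_channels < 2:
        raise ValueError("need at least 2 channels")
    data = epochs.data.copy()
    units = epochs.units
    if reference:
        data -= data.mean(axis=1, keepdims=True)
        units = f"{units},avgref"
    if zscore:
        subj = epochs.trials["subject"].to_numpy()
        for s in np.unique(subj):
            rows = np.flatnonzero(subj == s)
            block = data[rows]
            sd = block.std()
            if sd == 0:
                raise ValueError(f"zero variance for subject {s!r}")
            data[rows] = (block - block.mean()) / sd
        units = "z"
    if rectify:
        data = np.abs(data)
        units = f"|{units}|"
    return epochs.copy_with(data=data, units=units)


# ---------------------------------------------------------------------------
# slope maps
# ---------------------------------------------------------------------------

def _single_subject_slopes(data: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Vectorized per-point OLS slope of data (trials, C, T) on x (trials,)."""
    xc = x - x.mean()
    ssx = float(np.sum(xc**2))
    if ssx == 0:
        raise ValueError("predictor has a single level")
    n, C, T = data.shape
    flat = data.reshape(n, C * T)
    num = xc @ (flat - flat.mean(axis=0, keepdims=True))
    return (num / ssx).reshape(C, T)


def fit_slope_map(epochs: EpochSet, predictor: str = "log_jitter") -> np.ndarray:
    """Per-point OLS slope of single-trial amplitude on jitter for ONE subject.

    ``predictor``: 'log_jitter' (default, commensurate with the behavioral
    log-log model) or 'jitter' (raw degrees).
    """
    subjects = epochs.trials["subject"].unique()
    if len(subjects) != 1:
        raise ValueError("fit_slope_map expects a single subject; use fit_slope_maps_by_subject")
    j = epochs.trials["jitter_deg"].to_numpy(dtype=float)
    if len(np.unique(j)) < 2:
        raise ValueError("need at least 2 distinct jitter levels")
    if predictor == "log_jitter":
        x = np.log(j)
    elif predictor == "jitter":
        x = j
    else:
        raise ValueError(f"unknown predictor {predictor!r}")
    return _single_subject_slopes(epochs.data, x)


def fit_slope_maps_by_subject(epochs: EpochSet, predictor: str = "log_jitter") -> SlopeMap:
    """Stack per-subject slope maps into a SlopeMap (subjects, C, T)."""
    subj = epochs.trials["subject"].to_numpy()
    subjects = list(pd.unique(subj))
    maps = []
    for s in subjects:
        rows = np.flatnonzero(subj == s)
        sub = epochs.copy_with(data=epochs.data[rows], trials=epochs.trials.iloc[rows].reset_index(drop=True))
        maps.append(fit_slope_map(sub, predictor=predictor))
    return SlopeMap(
        slopes=np.stack(maps), channels=list(epochs.channels),
        times_ms=epochs.times_ms, subjects=subjects, predictor_desc=predictor,
    )


# ---------------------------------------------------------------------------
# cluster-based permutation
# ---------------------------------------------------------------------------

def _label_clusters(
    supra: np.ndarray, pos: np.ndarray, adj_pairs: np.ndarray
) -> tuple[np.ndarray, int]:
    """Connected components of suprathreshold points.

    ``supra``: (C, T) bool; ``pos``: (C, T) bool sign map (True where t > 0).
    Points connect through spatial adjacency (same timepoint) or temporal
    contiguity (same channel) when both are suprathreshold with the same
    sign.  Returns (labels (C, T) int, -1 outside clusters; n_clusters).
    """
    C, T = supra.shape
    idx = np.full((C, T), -1, dtype=np.int64)
    nodes = np.flatnonzero(supra.ravel())
    k = len(nodes)
    if k == 0:
        return idx, 0
    idx.ravel()[nodes] = np.arange(k)
    rows = []
    cols = []
    same = ~(pos[:, :-1] ^ pos[:, 1:])
    tlink = supra[:, :-1] & supra[:, 1:] & same
    a = idx[:, :-1][tlink]
    b = idx[:, 1:][tlink]
    rows.append(a)
    cols.append(b)
    if len(adj_pairs):
        ci, cj = adj_pairs[:, 0], adj_pairs[:, 1]
        slink = supra[ci] & supra[cj] & ~(pos[ci] ^ pos[cj])  # (n_pairs, T)
        pi, ti = np.nonzero(slink)
        rows.append(idx[ci[pi], ti])
        cols.append(idx[cj[pi], ti])
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    graph = sparse.coo_matrix((np.ones(len(r), dtype=np.int8), (r, c)), shape=(k, k))
    n_comp, labels = connected_components(graph, directed=False)
    out = np.full(C * T, -1, dtype=np.int64)
    out[nodes] = labels
    return out.reshape(C, T), n_comp


def _cluster_masses(tmap: np.ndarray, thresh: float, adj_pairs: np.ndarray):
    """Clusters and their masses for one t-map. Returns (labels, masses, signs)."""
    supra = np.abs(tmap) > thresh
    pos = tmap > 0
    labels, n = _label_clusters(supra, pos, adj_pairs)
    if n == 0:
        return labels, np.array([]), np.array([], dtype=int)
    flat_labels = labels.ravel()
    member = flat_labels >= 0
    masses = np.bincount(flat_labels[member], weights=np.abs(tmap).ravel()[member], minlength=n)
    signs = np.zeros(n, dtype=int)
    # sign of any member point (clusters are same-sign by construction)
    first = np.full(n, -1, dtype=np.int64)
    mem_idx = np.flatnonzero(member)
    first[flat_labels[mem_idx]] = mem_idx  # last write wins; any member is fine
    signs = np.where(pos.ravel()[first], 1, -1)
    return labels, masses, signs


def _t_one_sample(maps: np.ndarray) -> np.ndarray:
    """One-sample t across the first axis (subjects)."""
    S = maps.shape[0]
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    sd = np.where(sd == 0, np.inf, sd)
    return mean / (sd / np.sqrt(S))


def cluster_permutation(
    slope_map: SlopeMap,
    montage: Montage,
    n_perm: int = 5000,
    cluster_forming_p: float = 0.01,
    alpha_cluster: float = 0.01,
    tail: str = "two_sided",
    seed: int = 0,
) -> ClusterResult:
    """Group-level sign-flip cluster-based permutation test on slope maps.

    Per point, a one-sample t across subjects; points with |t| above the
    two-tailed cluster-forming quantile are clustered under spatial
    adjacency x temporal contiguity with equal sign; cluster mass is the sum
    of |t|.  The null is the distribution of the maximum cluster mass over
    both signs under random per-subject sign flips, giving two-sided
    family-wise control at ``alpha_cluster``; cluster
    p = (1 + #{null >= observed}) / (1 + n_perm).
    """
    if tail != "two_sided":
        raise NotImplementedError("only the two-sided test is implemented")
    maps = slope_map.slopes
    S, C, T = maps.shape
    if S < 5:
        raise ValueError("need at least 5 subjects for a stable one-sample t")
    if montage.n_channels != C:
        raise ValueError("montage does not cover the slope-map channels")
    adj_pairs = montage.adjacency_pairs()
    tcrit = float(stats.t.ppf(1.0 - cluster_forming_p / 2.0, S - 1))

    t_obs = _t_one_sample(maps)
    labels, masses, signs = _cluster_masses(t_obs, tcrit, adj_pairs)

    rng = np.random.default_rng(seed)
    flat = maps.reshape(S, C * T)
    sumsq = np.sum(flat**2, axis=0)  # invariant under sign flips
    null_max = np.zeros(n_perm)
    batch = max(1, int(2e7 // (C * T)))
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        signs_b = rng.choice([-1.0, 1.0], size=(b, S))
        mean_b = (signs_b @ flat) / S  # (b, C*T)
        var_b = (sumsq[None, :] - S * mean_b**2) / (S - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_b = mean_b / np.sqrt(var_b / S)
        t_b = np.nan_to_num(t_b, nan=0.0, posinf=0.0, neginf=0.0)
        for i in range(b):
            tm = t_b[i].reshape(C, T)
            if not np.any(np.abs(tm) > tcrit):
                continue
            _, m, _ = _cluster_masses(tm, tcrit, adj_pairs)
            if len(m):
                null_max[done + i] = m.max()
        done += b

    clusters = []
    for ci in range(len(masses)):
        p = (1.0 + float(np.sum(null_max >= masses[ci]))) / (1.0 + n_perm)
        clusters.append(Cluster(mask=labels == ci, sign=int(signs[ci]), mass=float(masses[ci]), p_value=p))
    clusters.sort(key=lambda c: c.mass, reverse=True)
    return ClusterResult(
        clusters=clusters, t_map=t_obs, t_threshold=tcrit,
        alpha_cluster=alpha_cluster, cluster_forming_p=cluster_forming_p,
        n_permutations=n_perm, seed=seed,
    )


# ---------------------------------------------------------------------------
# behavioral CI matching
# ---------------------------------------------------------------------------

def behavioral_slope_ci(behav: "list[DPrimeRegression] | DPrimeRegression") -> tuple[float, float]:
    """95% CI for the behavioral d'-jitter slope.

    Primary mode: a list of per-subject regressions -> t-based CI of the
    mean of the per-subject beta1 values.  Alternate mode: a single pooled
    regression -> its own slope CI.
    """
    if isinstance(behav, DPrimeRegression):
        return behav.ci95_beta1
    b1 = np.array([b.beta1 for b in behav], dtype=float)
    n = len(b1)
    if n < 2:
        raise ValueError("need >= 2 subjects for a group-level CI")
    se = b1.std(ddof=1) / np.sqrt(n)
    tcrit = float(stats.t.ppf(0.975, n - 1))
    return (float(b1.mean() - tcrit * se), float(b1.mean() + tcrit * se))


def match_behavioral_ci(
    clusters: ClusterResult,
    slope_map: SlopeMap,
    behav: "list[DPrimeRegression] | DPrimeRegression",
) -> MatchMask:
    """Retain significant-cluster points whose slope matches behavior.

    Pointwise: a point in a significant cluster is kept iff the
    cross-subject mean EEG slope at that point lies within the behavioral
    95% CI.  Cluster-level variant: all points of significant clusters whose
    cluster-average slope lies within the CI.
    """
    if clusters.t_map.shape != slope_map.slopes.shape[1:]:
        raise ValueError("cluster result and slope map use different grids")
    lo, hi = behavioral_slope_ci(behav)
    mean_slope = slope_map.slopes.mean(axis=0)
    sig = clusters.significant_mask()
    point_mask = sig & (mean_slope >= lo) & (mean_slope <= hi)
    cluster_mask = np.zeros_like(sig)
    for c in clusters.significant():
        if lo <= float(mean_slope[c.mask].mean()) <= hi:
            cluster_mask |= c.mask
    return MatchMask(point_mask=point_mask, cluster_mask=cluster_mask, behavioral_ci=(lo, hi))


# ---------------------------------------------------------------------------
# response locking
# ---------------------------------------------------------------------------

def relock_to_response(stimulus_epochs: EpochSet, window_ms: tuple = (-1000.0, 0.0)) -> EpochSet:
    """Re-center each trial's window on its response (stimulus time + RT).

    Uses nearest-sample alignment; trials whose re-centered window exceeds
    the available samples are dropped (count logged).  Raises if no trial
    survives.
    """
    if "rt_ms" not in stimulus_epochs.trials.columns:
        raise ValueError("trial table lacks rt_ms")
    times = stimulus_epochs.times_ms
    step = 1000.0 / stimulus_epochs.fs_hz
    n_out = int(round((window_ms[1] - window_ms[0]) / step)) + 1
    out_times = window_ms[0] + step * np.arange(n_out)
    rts = stimulus_epochs.trials["rt_ms"].to_numpy(dtype=float)
    # sample index of the response per trial
    resp_idx = np.round((rts - times[0]) / step).astype(int)
    start = resp_idx + int(round(window_ms[0] / step))
    stop = start + n_out
    keep = (start >= 0) & (stop <= stimulus_epochs.n_times)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("relock_to_response: dropping %d/%d trials outside the epoch", n_drop, len(keep))
    if not np.any(keep):
        raise ValueError("no trial's response-locked window fits inside the epoch")
    rows = np.flatnonzero(keep)
    data = np.empty((len(rows), stimulus_epochs.n_channels, n_out))
    for k, r in enumerate(rows):
        data[k] = stimulus_epochs.data[r, :, start[r] : stop[r]]
    return EpochSet(
        data=data,
        times_ms=out_times,
        channels=list(stimulus_epochs.channels),
        trials=stimulus_epochs.trials.iloc[rows].reset_index(drop=True),
        lock="response",
        units=stimulus_epochs.units,
        fs_hz=stimulus_epochs.fs_hz,
    )
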