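"""Per-timepoint shrinkage-LDA decoding of stimulus orientation.

At each timepoint the channel vector is classified into vertical vs
horizontal with linear discriminant analysis whose pooled covariance is
shrunk toward a scaled identity, Sigma_g = (1 - g) S + g (tr S / C) I.  A
common shrinkage factor g is the across-subject average of per-subject OAS
(oracle approximating shrinkage) estimates.  Classes are balanced by random
down-sampling of the majority class; accuracy is stratified 10-fold
cross-validated.  Classifier weights are projected into interpretable scalp
topographies as activation patterns (covariance x weights), and per-subject
accuracy time courses are tested against chance with a sign-flip temporal
cluster permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.covariance import OAS
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold

from .containers import EpochSet

__all__ = [
    "DecodingResult",
    "TemporalCluster",
    "balance_classes",
    "estimate_common_shrinkage",
    "decode_timecourse",
    "activation_patterns",
    "temporal_cluster_test",
]

LABEL_COL = "orientation"


@dataclass
class DecodingResult:
    accuracy: np.ndarray  # (T,) mean CV accuracy
    weights: np.ndarray  # (C, T) full-data LDA weights
    patterns: np.ndarray  # (C, T) activation patterns (unit max abs per timepoint)
    times_ms: np.ndarray
    channels: list
    shrinkage_gamma: float


@dataclass
class TemporalCluster:
    start_idx: int
    stop_idx: int  # exclusive
    sign: int
    mass: float
    p_value: float


def balance_classes(trials: pd.DataFrame, seed: int, label_col: str = LABEL_COL) -> np.ndarray:
    """Row positions of a class-balanced subset (majority class down-sampled)."""
    labels = trials[label_col].to_numpy()
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2 or np.any(counts == 0):
        raise ValueError("both classes must be present")
    n_min = counts.min()
    rng = np.random.default_rng(seed)
    keep = []
    for cls in classes:
        rows = np.flatnonzero(labels == cls)
        if len(rows) > n_min:
            rows = rng.choice(rows, size=n_min, replace=False)
        keep.append(rows)
    return np.sort(np.concatenate(keep))


def estimate_common_shrinkage(per_subject_epochs: list[EpochSet]) -> float:
    """Across-subject mean of per-subject OAS shrinkage coefficients.

    Per subject, the OAS coefficient of the channel covariance is computed
    at each timepoint and averaged over timepoints; the returned gamma is
    the mean across subjects (in [0, 1]).
    """
    if not per_subject_epochs:
        raise ValueError("need at least one subject")
    gammas = []
    for ep in per_subject_epochs:
        if ep.n_trials < 2:
            raise ValueError("need at least 2 trials to estimate a covariance")
        per_t = []
        for t in range(ep.n_times):
            est = OAS(assume_centered=False).fit(ep.data[:, :, t])
            per_t.append(est.shrinkage_)
        gammas.append(float(np.mean(per_t)))
    return float(np.clip(np.mean(gammas), 0.0, 1.0))


def decode_timecourse(
    epochs: EpochSet,
    gamma: float,
    n_folds: int = 10,
    seed: int = 0,
    label_col: str = LABEL_COL,
) -> DecodingResult:
    """Stratified k-fold LDA decoding at each timepoint.

    Classes must already be balanced (use :func:`balance_classes`).  The
    covariance is the sklearn 'lsqr' shrunk estimate
    (1 - gamma) S + gamma (tr S / C) I, matching the shrinkage-LDA model.
    Weights come from a full-data fit; patterns are the full-data covariance
    times the weights, normalized to unit maximum absolute value.
    """
    y = epochs.trials[label_col].to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("decoding requires exactly 2 classes")
    if counts.min() != counts.max():
        raise ValueError("classes are unbalanced; run balance_classes first")
    if counts.min() < n_folds:
        raise ValueError(f"n_folds={n_folds} exceeds the per-class trial count {counts.min()}")
    T, C = epochs.n_times, epochs.n_channels
    acc = np.zeros(T)
    weights = np.zeros((C, T))
    patterns = np.zeros((C, T))
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed % (2**32))
    splits = list(cv.split(np.zeros(len(y)), y))
    for t in range(T):
        X = epochs.data[:, :, t]
        fold_acc = []
        for train, test in splits:
            lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=gamma)
            lda.fit(X[train], y[train])
            fold_acc.append(lda.score(X[test], y[test]))
        acc[t] = float(np.mean(fold_acc))
        full = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=gamma)
        full.fit(X, y)
        w = full.coef_.ravel()
        weights[:, t] = w
        cov = np.cov(X, rowvar=False)
        patterns[:, t] = activation_patterns(w, cov)
    return DecodingResult(
        accuracy=acc, weights=weights, patterns=patterns,
        times_ms=epochs.times_ms, channels=list(epochs.channels),
        shrinkage_gamma=gamma,
    )


def activation_patterns(weights: np.ndarray, covariance: np.ndarray) -> np.ndarray:
    """Forward-model projection: pattern = covariance @ weights, unit max abs.

    Classifier weights are not interpretable as source topographies; the
    covariance projection recovers the activation pattern of the decoded
    signal.
    """
    w = np.asarray(weights, dtype=float)
    cov = np.asarray(covariance, dtype=float)
    if cov.shape != (len(w), len(w)):
        raise ValueError("covariance does not match weight length")
    if not np.allclose(cov, cov.T, atol=1e-8):
        raise ValueError("covariance must be symmetric")
    pattern = cov @ w
    m = np.abs(pattern).max()
    return pattern / m if m > 0 else pattern


def temporal_cluster_test(
    per_subject_accuracy: np.ndarray,
    chance: float = 0.5,
    n_perm: int = 1000,
    alpha: float = 0.05,
    cluster_forming_p: float = 0.05,
    seed: int = 0,
) -> list[TemporalCluster]:
    """Sign-flip cluster permutation on accuracy time courses vs chance.

    One-sample t on (accuracy - chance) per timepoint; suprathreshold runs
    of equal sign form clusters with mass = sum |t|; the null is the maximum
    cluster mass over both signs under per-subject sign flips;
    p = (1 + #null >= observed) / (1 + n_perm).
    """
    A = np.asarray(per_subject_accuracy, dtype=float) - chance
    S, T = A.shape
    if S < 5:
        raise ValueError("need at least 5 subjects")
    tcrit = float(stats.t.ppf(1.0 - cluster_forming_p / 2.0, S - 1))

    def _tstat(mat: np.ndarray) -> np.ndarray:
        sd = mat.std(axis=0, ddof=1)
        sd = np.where(sd == 0, np.inf, sd)
        return mat.mean(axis=0) / (sd / np.sqrt(S))

    def _runs(tv: np.ndarray):
        """Maximal runs of suprathreshold same-sign points: (start, stop, sign, mass)."""
        supra = np.abs(tv) > tcrit
        out = []
        i = 0
        while i < T:
            if not supra[i]:
                i += 1
                continue
            sign = 1 if tv[i] > 0 else -1
            j = i
            while j < T and supra[j] and (tv[j] > 0) == (sign > 0):
                j += 1
            out.append((i, j, sign, float(np.abs(tv[i:j]).sum())))
            i = j
        return out

    t_obs = _tstat(A)
    obs = _runs(t_obs)
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, S))
    sumsq = np.sum(A**2, axis=0)
    mean_p = (signs @ A) / S
    var_p = (sumsq[None, :] - S * mean_p**2) / (S - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_p = mean_p / np.sqrt(var_p / S)
    t_p = np.nan_to_num(t_p, nan=0.0, posinf=0.0, neginf=0.0)
    null_max = np.zeros(n_perm)
    for i in range(n_perm):
        runs = _runs(t_p[i])
        if runs:
            null_max[i] = max(r[3] for r in runs)
    clusters = [
        TemporalCluster(
            start_idx=i, stop_idx=j, sign=s, mass=m,
            p_value=(1.0 + float(np.sum(null_max >= m))) / (1.0 + n_perm),
        )
        for i, j, s, m in obs
    ]
    return [c for c in sorted(clusters, key=lambda c: c.mass, reverse=True)]
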