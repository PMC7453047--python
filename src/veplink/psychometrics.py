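"""Psychometric modeling and the d'-jitter linking regression.

Accuracy as a function of orientation jitter is modeled with a
four-parameter cumulative-normal (probit) function

    P(correct | j) = guess + (1 - guess - lapse) * Phi((mu - j) / s)

with location mu (the threshold: jitter at the inflection point, the
midpoint between asymptotes), scale s > 0, and free guess / lapse rates in
[0, 0.5].  Performance decreases with jitter, so the slope at the inflection
point is negative.  The inverse function calibrates jitter levels that hit
fixed percent-correct targets.

For neurometric linking, per-level accuracy is re-expressed as a
sensitivity index d' = 2 * Phi^{-1}(PC) (single-interval two-alternative
convention) and log d' is regressed on log jitter:

    log d' = beta0 + beta1 * log(jitter) + eps,  eps ~ N(0, sigma)

The slope beta1 and its 95% CI are the behavioral anchor that EEG regression
slopes are later matched against.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "PsychometricFit",
    "DPrimeRegression",
    "fit_probit",
    "evaluate_probit",
    "invert_probit",
    "calibrate_levels",
    "dprime_from_counts",
    "dprime_yes_no",
    "fit_dprime_regression",
]

_NORM = stats.norm


@dataclass
class PsychometricFit:
    """Four-parameter probit fit in location/scale form."""

    mu: float  # location = threshold (deg jitter)
    s: float  # scale (deg), > 0
    guess: float
    lapse: float
    loglik: float
    converged: bool
    message: str = ""

    @property
    def threshold(self) -> float:
        """Jitter at the inflection point (midpoint between asymptotes)."""
        return self.mu

    @property
    def slope_at_inflection(self) -> float:
        """dP/d jitter at threshold; negative (performance falls with jitter)."""
        return -(1.0 - self.guess - self.lapse) * _NORM.pdf(0.0) / self.s

    @property
    def asymptotes(self) -> tuple[float, float]:
        return self.guess, 1.0 - self.lapse


@dataclass
class DPrimeRegression:
    """OLS fit of log d' on log jitter."""

    beta0: float
    beta1: float
    sigma: float
    ci95_beta1: tuple[float, float]
    n_points: int


def evaluate_probit(fit: PsychometricFit, jitter: float | np.ndarray) -> float | np.ndarray:
    """P(correct) predicted at the given jitter."""
    j = np.asarray(jitter, dtype=float)
    p = fit.guess + (1.0 - fit.guess - fit.lapse) * _NORM.cdf((fit.mu - j) / fit.s)
    return float(p) if np.isscalar(jitter) else p


def _neg_loglik(params: np.ndarray, j: np.ndarray, k: np.ndarray, n: np.ndarray) -> float:
    mu, s, g, l = params
    p = g + (1.0 - g - l) * _NORM.cdf((mu - j) / s)
    p = np.clip(p, 1e-9, 1.0 - 1e-9)
    return -float(np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))


def fit_probit(
    jitter_levels: np.ndarray,
    n_correct: np.ndarray,
    n_total: np.ndarray,
    n_starts: int = 10,
    seed: int = 0,
) -> PsychometricFit:
    """Maximum-likelihood four-parameter probit fit with multistart.

    guess and lapse are free within [0, 0.5].  Non-identifiable data
    (performance flat at ceiling or at chance across all levels) yield
    ``converged=False`` with a diagnostic message rather than a fabricated
    fit.
    """
    j = np.asarray(jitter_levels, dtype=float)
    k = np.asarray(n_correct, dtype=float)
    n = np.asarray(n_total, dtype=float)
    if len(np.unique(j)) < 4:
        raise ValueError("need at least 4 distinct jitter levels")
    if np.any(n <= 0):
        raise ValueError("all n_total must be positive")
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("n_correct must lie in [0, n_total]")

    pc = k / n
    flat = np.all(pc >= 1.0 - 1.0 / (2 * n)) or np.all(pc <= 0.5 + np.sqrt(0.25 / n) * 2)
    jr = j.max() - j.min()
    bounds = [
        (j.min() - jr, j.max() + jr),
        (jr * 1e-3, jr * 10),
        (0.0, 0.5),
        (0.0, 0.5),
    ]
    rng = np.random.default_rng(seed)
    best = None
    for i in range(n_starts):
        if i == 0:
            x0 = np.array([np.median(j), jr / 3.0, 0.45, 0.02])
        else:
            x0 = np.array([b[0] + rng.uniform(0.05, 0.95) * (b[1] - b[0]) for b in bounds])
        res = optimize.minimize(
            _neg_loglik, x0, args=(j, k, n), method="L-BFGS-B", bounds=bounds
        )
        if best is None or res.fun < best.fun:
            best = res
    mu, s, g, l = best.x
    converged = bool(best.success) and not flat
    message = "" if converged else ("non-identifiable: performance flat across levels" if flat else str(best.message))
    return PsychometricFit(
        mu=float(mu), s=float(s), guess=float(g), lapse=float(l),
        loglik=-float(best.fun), converged=converged, message=message,
    )


def invert_probit(fit: PsychometricFit, target_pc: float) -> float:
    """Jitter at which the fitted function predicts ``target_pc``.

    Closed-form inverse; the forward evaluation of the result round-trips to
    the target.  Targets must lie strictly between the asymptotes.
    """
    lo, hi = fit.asymptotes
    if not (lo < target_pc < hi):
        raise ValueError(
            f"target {target_pc} outside the open asymptote interval ({lo:.4f}, {hi:.4f})"
        )
    q = (target_pc - fit.guess) / (1.0 - fit.guess - fit.lapse)
    return float(fit.mu - fit.s * _NORM.ppf(q))


def calibrate_levels(
    fit: PsychometricFit, pc_max: float = 0.95, pc_min: float = 0.50, n_levels: int = 6
) -> tuple[np.ndarray, np.ndarray]:
    """Equidistant percent-correct targets and their inverse-mapped jitters.

    Returns ``(targets, jitters)``; targets include both endpoints.  The
    default reproduces the 95..50% calibration ladder in 6 steps
    (95, 86, 77, 68, 59, 50%).
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    if not pc_max > pc_min:
        raise ValueError("pc_max must exceed pc_min")
    targets = np.linspace(pc_max, pc_min, n_levels)
    jitters = np.array([invert_probit(fit, t) for t in targets])
    return targets, jitters


def dprime_from_counts(n_correct: int, n_total: int, convention: str = "2afc") -> float:
    """Sensitivity index from a per-level accuracy count.

    PC is clipped to [1/(2N), 1 - 1/(2N)] so the transform is finite.  The
    default single-interval two-alternative convention gives
    d' = 2 * Phi^{-1}(PC); ``convention='yesno'`` gives Phi^{-1}(PC) (one
    judgment axis), kept for comparison.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    pc = n_correct / n_total
    lo = 1.0 / (2.0 * n_total)
    pc = min(max(pc, lo), 1.0 - lo)
    z = float(_NORM.ppf(pc))
    if convention == "2afc":
        return 2.0 * z
    if convention == "yesno":
        return z
    raise ValueError(f"unknown convention {convention!r}")


def dprime_yes_no(n_hit: int, n_signal: int, n_fa: int, n_noise: int) -> float:
    """Yes/no d' = Phi^{-1}(H) - Phi^{-1}(FA) with 1/(2N) clipping."""
    if n_signal <= 0 or n_noise <= 0:
        raise ValueError("trial counts must be positive")
    h = min(max(n_hit / n_signal, 1 / (2 * n_signal)), 1 - 1 / (2 * n_signal))
    fa = min(max(n_fa / n_noise, 1 / (2 * n_noise)), 1 - 1 / (2 * n_noise))
    return float(_NORM.ppf(h) - _NORM.ppf(fa))


def fit_dprime_regression(jitter_levels: np.ndarray, dprimes: np.ndarray) -> DPrimeRegression:
    """OLS of log d' on log jitter with a t-based 95% CI on the slope.

    Levels with non-positive d' have no logarithm; they are dropped with a
    warning.  At least 3 usable points are required.
    """
    j = np.asarray(jitter_levels, dtype=float)
    d = np.asarray(dprimes, dtype=float)
    usable = d > 0
    if np.any(~usable):
        warnings.warn(
            f"dropping {int((~usable).sum())} level(s) with non-positive d'", stacklevel=2
        )
    j, d = j[usable], d[usable]
    n = len(j)
    if n < 3:
        raise ValueError("need at least 3 levels with positive d'")
    x = np.log(j)
    y = np.log(d)
    xc = x - x.mean()
    ssx = float(np.sum(xc**2))
    beta1 = float(np.sum(xc * y) / ssx)
    beta0 = float(y.mean() - beta1 * x.mean())
    resid = y - (beta0 + beta1 * x)
    dof = n - 2
    sigma = float(np.sqrt(np.sum(resid**2) / dof))
    se = sigma / np.sqrt(ssx)
    tcrit = float(stats.t.ppf(0.975, dof))
    ci = (beta1 - tcrit * se, beta1 + tcrit * se)
    return DPrimeRegression(beta0=beta0, beta1=beta1, sigma=sigma, ci95_beta1=ci, n_points=n)
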