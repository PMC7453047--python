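"""Peak-aligned evoked-component analysis.

Evoked components are not perfectly time-locked across participants, so
amplitude effects can wash out of stimulus-locked grand averages.  This
module (a) finds, per subject and component search window, the electrode
with the strongest average activity and the latency of its extremum, then
reads out amplitudes at that electrode/latency per condition x jitter level;
and (b) fits a multilevel (random intercept per subject) linear model of
peak amplitude on log jitter, condition, and their interaction, simplified
backwards by likelihood-ratio tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.formula.api as smf

from .containers import EpochSet

__all__ = [
    "find_component_peaks",
    "fit_component_model",
    "ComponentRegressionResult",
]


@dataclass
class ComponentRegressionResult:
    """Backward-simplified multilevel regression of peak amplitude."""

    selected_model: str  # 'full' | 'additive' | 'jitter_only' | 'condition_only' | 'intercept_only'
    fixed_effects: dict  # name -> (estimate, SE) for the selected model
    lrt_chain: pd.DataFrame  # one row per nested comparison
    converged: bool


def find_component_peaks(
    epochs: EpochSet,
    windows: list[tuple[str, float, float]],
    polarity: str = "abs",
) -> pd.DataFrame:
    """Individual peak electrode/latency detection and amplitude readout.

    Per subject and window: the grand average over all conditions and jitter
    levels selects the electrode with the highest activity (largest absolute
    mean in-window amplitude by default; ``polarity`` 'pos'/'neg' for signed
    components); the latency of the in-window extremum at that electrode is
    the subject's component latency; amplitudes are then read out at that
    electrode and latency for each condition x jitter level average.

    Boundary extrema (peak at the window edge, e.g. on flat or monotone
    signal) are flagged via ``boundary`` — callers should exclude those
    subjects rather than trust the latency.
    """
    if polarity not in ("abs", "pos", "neg"):
        raise ValueError("polarity must be 'abs', 'pos', or 'neg'")
    times = epochs.times_ms
    for label, lo, hi in windows:
        if lo < times[0] or hi > times[-1]:
            raise ValueError(f"window {label!r} ({lo}, {hi}) outside epoch")
    subj_col = epochs.trials["subject"].to_numpy()
    rows = []
    for subj in pd.unique(subj_col):
        sel = np.flatnonzero(subj_col == subj)
        avg = epochs.data[sel].mean(axis=0)  # (C, T)
        trials = epochs.trials.iloc[sel]
        for label, lo, hi in windows:
            win = epochs.time_window_slice(lo, hi)
            seg = avg[:, win]
            if polarity == "abs":
                strength = np.abs(seg).mean(axis=1)
                elec = int(np.argmax(strength))
                lat_idx = int(np.argmax(np.abs(seg[elec])))
            elif polarity == "pos":
                elec = int(np.argmax(seg.mean(axis=1)))
                lat_idx = int(np.argmax(seg[elec]))
            else:
                elec = int(np.argmin(seg.mean(axis=1)))
                lat_idx = int(np.argmin(seg[elec]))
            boundary = lat_idx in (0, seg.shape[1] - 1)
            t_idx = win.start + lat_idx
            latency = float(times[t_idx])
            for (cond, jit), cell in trials.groupby(["condition", "jitter_deg"]):
                amp = float(epochs.data[cell.index.to_numpy(), elec, t_idx].mean())
                rows.append(
                    dict(
                        subject=subj, component=label, electrode=epochs.channels[elec],
                        electrode_index=elec, latency_ms=latency, condition=cond,
                        jitter_deg=float(jit), amplitude=amp, boundary=boundary,
                    )
                )
    return pd.DataFrame(rows)


_MODELS = {
    "full": "amplitude ~ log_jitter * condition",
    "additive": "amplitude ~ log_jitter + condition",
    "jitter_only": "amplitude ~ log_jitter",
    "intercept_only": "amplitude ~ 1",
}
_CHAIN = ["full", "additive", "jitter_only", "intercept_only"]


def _fit_ml(formula: str, frame: pd.DataFrame):
    """Random-intercept model by ML; falls back to plain ML regression when
    the between-subject variance sits on the zero boundary (singular
    Hessian), where both models coincide."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = smf.mixedlm(formula, frame, groups=frame["subject"])
            fit = model.fit(reml=False, method="lbfgs")
            if np.isfinite(fit.llf):
                return fit
        except (np.linalg.LinAlgError, ValueError):
            pass
        ols = smf.ols(formula, frame).fit()
        ols.fe_params = ols.params
        ols.bse_fe = ols.bse
        ols.converged = True
        return ols


def fit_component_model(peaks: pd.DataFrame, alpha: float = 0.05) -> ComponentRegressionResult:
    """Backward LRT simplification of the multilevel peak-amplitude model.

    Fits amplitude ~ log(jitter) * condition with a random intercept per
    subject by maximum likelihood, then drops interaction, condition, and
    jitter in turn; a drop is accepted while the likelihood-ratio test is
    non-significant at ``alpha``.  Requires one component at a time, >= 2
    conditions x >= 3 levels x >= 5 subjects, and <= 20% missing cells.
    """
    frame = peaks.copy()
    if "boundary" in frame.columns:
        frame = frame[~frame["boundary"]]
    if frame["component"].nunique() > 1:
        raise ValueError("pass one component at a time")
    n_subj = frame["subject"].nunique()
    n_cond = frame["condition"].nunique()
    n_lev = frame["jitter_deg"].nunique()
    if n_subj < 5 or n_cond < 2 or n_lev < 3:
        raise ValueError(
            f"need >=5 subjects, >=2 conditions, >=3 levels; got {n_subj}/{n_cond}/{n_lev}"
        )
    full_cells = n_subj * n_cond * n_lev
    if len(frame) < 0.8 * full_cells:
        raise ValueError(
            f"{full_cells - len(frame)} of {full_cells} cells missing (> 20%)"
        )
    frame = frame.assign(log_jitter=np.log(frame["jitter_deg"].to_numpy(dtype=float)))

    fits = {name: _fit_ml(_MODELS[name], frame) for name in _CHAIN}
    chain_rows = []
    selected = "intercept_only"
    for bigger, smaller in zip(_CHAIN[:-1], _CHAIN[1:]):
        ll_big, ll_small = fits[bigger].llf, fits[smaller].llf
        dev = max(2.0 * (ll_big - ll_small), 0.0)  # nested: nonnegative up to optimizer noise
        df = len(fits[bigger].fe_params) - len(fits[smaller].fe_params)
        p = float(stats.chi2.sf(dev, df))
        chain_rows.append(dict(comparison=f"{bigger} vs {smaller}", deviance=dev, df=df, p_value=p))
        if p < alpha:
            selected = bigger
            break
    # special case: jitter dropped but condition might matter (branch off additive)
    if selected == "intercept_only" and n_cond >= 2:
        fit_cond = _fit_ml("amplitude ~ condition", frame)
        dev = max(2.0 * (fit_cond.llf - fits["intercept_only"].llf), 0.0)
        df = len(fit_cond.fe_params) - 1
        p = float(stats.chi2.sf(dev, df))
        chain_rows.append(dict(comparison="condition_only vs intercept_only", deviance=dev, df=df, p_value=p))
        if p < alpha:
            selected = "condition_only"
            fits["condition_only"] = fit_cond

    sel_fit = fits[selected]
    fixed = {
        name: (float(est), float(se))
        for name, est, se in zip(sel_fit.fe_params.index, sel_fit.fe_params, sel_fit.bse_fe)
    }
    return ComponentRegressionResult(
        selected_model=selected,
        fixed_effects=fixed,
        lrt_chain=pd.DataFrame(chain_rows),
        converged=bool(getattr(sel_fit, "converged", True)),
    )
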