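"""Survival primitives: Cox screening and fits, Harrell's C, log-rank,
Kaplan–Meier, and time-dependent AUC at a fixed horizon.

Cox models are fitted with lifelines (Efron tie handling, Newton–Raphson);
the concordance index and the inverse-probability-of-censoring-weighted
cumulative/dynamic AUC are implemented here because their pair-level
conventions are what the package's evaluation rests on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test

from .containers import SurvivalData


@dataclass
class CoxFit:
    """One Cox proportional-hazards fit: log hazard ratios with Wald stats."""

    covariates: list[str]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    p_values: np.ndarray
    log_likelihood: float
    converged: bool

    def coefficient(self, name: str) -> float:
        return float(self.coefficients[self.covariates.index(name)])

    def p_value(self, name: str) -> float:
        return float(self.p_values[self.covariates.index(name)])


def _fit_cox(df: pd.DataFrame, covariates: list[str]) -> CoxFit:
    cph = CoxPHFitter()
    cph.fit(
        df[["time", "event", *covariates]],
        duration_col="time",
        event_col="event",
    )
    summary = cph.summary
    return CoxFit(
        covariates=list(summary.index),
        coefficients=summary["coef"].to_numpy(),
        standard_errors=summary["se(coef)"].to_numpy(),
        p_values=summary["p"].to_numpy(),
        log_likelihood=float(cph.log_likelihood_),
        converged=True,
    )


def univariate_cox_screen(
    features: pd.DataFrame,
    surv: SurvivalData,
    alpha: float = 0.05,
) -> tuple[list[str], dict[str, CoxFit]]:
    """Fit one single-covariate Cox model per feature column; keep features
    with Wald p < alpha, input order preserved.  Constant or non-convergent
    features are skipped with a warning, never selected."""
    if surv.n_events < 2:
        raise ValueError("need at least 2 events for a Cox screen")
    base = pd.DataFrame({"time": surv.time, "event": surv.event})
    selected: list[str] = []
    fits: dict[str, CoxFit] = {}
    for name in features.columns:
        x = features[name].to_numpy(float)
        if np.std(x) == 0:
            warnings.warn(f"constant feature {name!r} skipped", RuntimeWarning, stacklevel=2)
            continue
        df = base.copy()
        df[name] = x
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = _fit_cox(df, [name])
        except (ConvergenceError, np.linalg.LinAlgError, ValueError):
            warnings.warn(
                f"Cox fit failed to converge for feature {name!r}; skipped",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        fits[name] = fit
        if fit.p_value(name) < alpha:
            selected.append(name)
    return selected, fits


def multivariate_cox(features: pd.DataFrame, surv: SurvivalData) -> CoxFit:
    """Joint Cox fit over all feature columns."""
    x = features.to_numpy(float)
    if x.shape[0] <= x.shape[1]:
        raise ValueError("need more samples than covariates")
    rank = np.linalg.matrix_rank(x - x.mean(axis=0))
    if rank < x.shape[1]:
        corr = np.corrcoef(x, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise ValueError(
            f"singular design; near-collinear columns include "
            f"{features.columns[i]!r} and {features.columns[j]!r}"
        )
    df = pd.DataFrame({"time": surv.time, "event": surv.event})
    for c in features.columns:
        df[c] = features[c].to_numpy(float)
    return _fit_cox(df, list(features.columns))


def concordance_index(risk: np.ndarray, surv: SurvivalData) -> float:
    """Harrell's C: over comparable pairs (the smaller observed time is an
    event), the fraction where the shorter-lived sample has the higher risk
    score; tied scores count 1/2."""
    risk = np.asarray(risk, dtype=float)
    if not np.isfinite(risk).all():
        raise ValueError("risk scores must be finite")
    t, e = surv.time, surv.event
    n = len(t)
    concordant = 0.0
    comparable = 0
    for i in range(n):
        if e[i] != 1:
            continue
        mask = t > t[i]  # j strictly later than event i
        comparable += int(mask.sum())
        concordant += float((risk[i] > risk[mask]).sum())
        concordant += 0.5 * float((risk[i] == risk[mask]).sum())
    if comparable == 0:
        raise ValueError("no comparable pairs; C-index undefined")
    return concordant / comparable


def logrank_test(labels: np.ndarray, surv: SurvivalData) -> tuple[float, float]:
    """Log-rank test across groups; returns (chi-square statistic, p)."""
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups for a log-rank test")
    if surv.n_events < 1:
        raise ValueError("need at least one event")
    res = multivariate_logrank_test(surv.time, labels, surv.event)
    return float(res.test_statistic), float(res.p_value)


def km_curve(surv: SurvivalData) -> pd.DataFrame:
    """Kaplan–Meier product-limit estimate as a right-continuous step
    function; columns ``time`` and ``survival``, starting at S(0)=1."""
    kmf = KaplanMeierFitter()
    kmf.fit(surv.time, surv.event)
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(float), "survival": sf.iloc[:, 0].to_numpy(float)})


def km_median(surv: SurvivalData) -> float:
    kmf = KaplanMeierFitter()
    kmf.fit(surv.time, surv.event)
    return float(kmf.median_survival_time_)


def _censoring_survival(surv: SurvivalData) -> tuple[np.ndarray, np.ndarray]:
    """KM estimate of the censoring distribution G(t) (event flipped)."""
    kmf = KaplanMeierFitter()
    kmf.fit(surv.time, 1 - surv.event)
    sf = kmf.survival_function_
    return sf.index.to_numpy(float), sf.iloc[:, 0].to_numpy(float)


def _eval_step(times: np.ndarray, values: np.ndarray, t: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(times, t, side="right") - 1
    out = np.ones(len(t))
    mask = idx >= 0
    out[mask] = values[idx[mask]]
    return out


def time_dependent_auc(
    risk: np.ndarray, surv: SurvivalData, horizon: float
) -> tuple[float, pd.DataFrame]:
    """Cumulative/dynamic AUC at ``horizon`` with KM-based inverse
    censoring weights.

    Cases are samples with an observed event by the horizon (weight
    1/G(T_i)); controls are samples still at risk beyond it (weight
    1/G(horizon)).  Returns the AUC and the weighted ROC point set.
    """
    risk = np.asarray(risk, dtype=float)
    t, e = surv.time, surv.event
    if horizon <= t.min() or horizon >= t.max():
        raise ValueError("horizon must lie strictly inside the observed time range")
    cases = (t <= horizon) & (e == 1)
    controls = t > horizon
    if cases.sum() == 0 or controls.sum() == 0:
        raise ValueError("no cases or no controls at the horizon")
    gt, gs = _censoring_survival(surv)
    g_cases = _eval_step(gt, gs, t[cases])
    g_horizon = _eval_step(gt, gs, np.array([horizon]))[0]
    if g_horizon <= 0 or np.any(g_cases <= 0):
        raise ValueError("censoring survival reaches 0 before the horizon")
    w_cases = 1.0 / g_cases
    w_controls = np.full(int(controls.sum()), 1.0 / g_horizon)
    r_cases, r_controls = risk[cases], risk[controls]
    # weighted pairwise comparison
    diff = r_cases[:, None] - r_controls[None, :]
    wpair = w_cases[:, None] * w_controls[None, :]
    num = float((wpair * ((diff > 0) + 0.5 * (diff == 0))).sum())
    den = float(wpair.sum())
    auc = num / den
    # weighted ROC point set over score thresholds
    thresholds = np.concatenate(([np.inf], np.sort(np.unique(risk))[::-1]))
    tpr = [
        float(w_cases[r_cases >= c].sum()) / float(w_cases.sum()) for c in thresholds
    ]
    fpr = [
        float(w_controls[r_controls >= c].sum()) / float(w_controls.sum())
        for c in thresholds
    ]
    roc = pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr})
    return auc, roc


def naive_binary_auc(risk: np.ndarray, surv: SurvivalData, horizon: float) -> float:
    """Plain AUC of 'event by horizon', censored-before-horizon samples
    excluded; provided for comparison with the weighted estimator."""
    from sklearn.metrics import roc_auc_score

    t, e = surv.time, surv.event
    keep = (t > horizon) | (e == 1)
    y = ((t <= horizon) & (e == 1))[keep].astype(int)
    if y.min() == y.max():
        raise ValueError("no cases or no controls at the horizon")
    return float(roc_auc_score(y, np.asarray(risk)[keep]))
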