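"""Prognostic multiomics panel: feature picking from the cross-arm
intersection, multivariate Cox risk score, maximally selected log-rank
cutpoint, and evaluation (KM split, log-rank, C-index, horizon AUC).

The cutpoint search scans midpoints of sorted unique scores inside the
10th–90th percentile window and keeps the split maximizing the log-rank
statistic.  That search inflates the resulting log-rank p (a multiple-
testing artifact); the p is reported raw, as the field's tooling does, and
the inflation is documented rather than corrected.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import SurvivalData
from .survival import (
    concordance_index,
    km_curve,
    logrank_test,
    multivariate_cox,
    time_dependent_auc,
    univariate_cox_screen,
)


@dataclass
class RiskPanel:
    """Selected features with multivariate Cox coefficients and a score cutoff."""

    features: list[str]
    coefficients: np.ndarray
    cutoff: float
    with_clinical: bool = False
    clinical_features: list[str] = field(default_factory=list)
    clinical_coefficients: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.features) != len(self.coefficients):
            raise ValueError("features and coefficients must have equal length")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "features": self.features,
            "coefficients": [float(b) for b in self.coefficients],
            "cutoff": float(self.cutoff),
            "with_clinical": self.with_clinical,
        }
        if self.with_clinical and self.clinical_coefficients is not None:
            payload["clinical_features"] = self.clinical_features
            payload["clinical_coefficients"] = [
                float(b) for b in self.clinical_coefficients
            ]
        Path(path).write_text(json.dumps(payload, indent=2))


def pick_panel_features(
    intersection: dict[str, pd.DataFrame], per_omics_count: int = 2
) -> list[str]:
    """Per omics, the ``per_omics_count`` intersected features with the
    smallest DE p-values, ranked by the mean of the two arms' p-values."""
    picked: list[str] = []
    for kind in sorted(intersection):
        table = intersection[kind]
        if table.empty:
            warnings.warn(f"no intersected {kind} features", RuntimeWarning, stacklevel=2)
            continue
        t = table.copy()
        t["mean_p"] = (t["p_a"] + t["p_b"]) / 2.0
        t = t.sort_values(by=["mean_p", "feature_id"], kind="stable")
        if len(t) < per_omics_count:
            warnings.warn(
                f"only {len(t)} intersected {kind} features (< {per_omics_count})",
                RuntimeWarning,
                stacklevel=2,
            )
        picked.extend(t["feature_id"].head(per_omics_count).tolist())
    return picked


def compute_risk_scores(panel: RiskPanel, x: pd.DataFrame) -> np.ndarray:
    """Linear risk score: score_i = sum_j beta_j * x_ij."""
    missing = [f for f in panel.features if f not in x.columns]
    if missing:
        raise KeyError(f"panel features missing from matrix: {missing}")
    return x[panel.features].to_numpy(float) @ panel.coefficients


def _two_group_logrank_stat(member: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Chi-square log-rank statistic for a binary split, vectorized over
    distinct event times (fast enough to scan hundreds of candidate cuts)."""
    order = np.argsort(time, kind="stable")
    t, e, g = time[order], event[order], member[order].astype(float)
    uniq, first = np.unique(t, return_index=True)
    n = len(t)
    # at-risk counts just before each distinct time
    at_risk = n - first
    cum_g = np.concatenate(([0.0], np.cumsum(g)))
    at_risk_g = g.sum() - cum_g[first]
    d = np.add.reduceat(e.astype(float), first)
    d_g = np.add.reduceat(e * g, first)
    keep = d > 0
    nk, n1k, dk, d1k = at_risk[keep], at_risk_g[keep], d[keep], d_g[keep]
    expected = dk * n1k / nk
    with np.errstate(invalid="ignore", divide="ignore"):
        var = dk * (n1k / nk) * (1 - n1k / nk) * (nk - dk) / np.maximum(nk - 1, 1)
    v = float(np.nansum(var))
    if v <= 0:
        return 0.0
    o_minus_e = float((d1k - expected).sum())
    return o_minus_e**2 / v


def find_cutoff(scores: np.ndarray, surv: SurvivalData) -> float:
    """Maximally selected log-rank cutpoint over the 10th–90th percentile
    score window (candidates at midpoints of sorted unique scores)."""
    scores = np.asarray(scores, dtype=float)
    if len(scores) < 10 or surv.n_events < 2:
        raise ValueError("need >= 10 samples and >= 2 events for a cutpoint search")
    uniq = np.unique(scores)
    if len(uniq) < 2:
        raise ValueError("all scores equal; no cutpoint exists")
    lo, hi = np.percentile(scores, [10, 90])
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    candidates = mids[(mids >= lo) & (mids <= hi)]
    if len(candidates) == 0:
        candidates = mids
    best_stat, best_cut = -np.inf, candidates[0]
    for c in candidates:
        member = scores > c
        if member.all() or not member.any():
            continue
        stat = _two_group_logrank_stat(member, surv.time, surv.event)
        if stat > best_stat:
            best_stat, best_cut = stat, float(c)
    return best_cut


def fit_panel(
    candidate_features: list[str],
    x: pd.DataFrame,
    surv: SurvivalData,
    screen_alpha: float = 0.05,
) -> RiskPanel:
    """Univariate pre-screen (p < alpha) of the candidate features, then a
    multivariate Cox fit and cutpoint search on the resulting score."""
    selected, _ = univariate_cox_screen(x[candidate_features], surv, alpha=screen_alpha)
    if not selected:
        warnings.warn(
            "no candidate passed the univariate screen; using all candidates",
            RuntimeWarning,
            stacklevel=2,
        )
        selected = list(candidate_features)
    fit = multivariate_cox(x[selected], surv)
    panel = RiskPanel(features=selected, coefficients=fit.coefficients, cutoff=0.0)
    scores = compute_risk_scores(panel, x)
    panel.cutoff = find_cutoff(scores, surv)
    return panel


def evaluate_panel(
    panel: RiskPanel,
    x: pd.DataFrame,
    surv: SurvivalData,
    clinical: pd.DataFrame | None = None,
    horizon: float = 60.0,
) -> dict:
    """KM curves per risk group, log-rank p of the split, C-index of the
    continuous score, and the cumulative/dynamic AUC at ``horizon``.

    With ``clinical`` given, the multivariate Cox model is refitted with
    the encoded clinical covariates appended and the same metrics reported
    for the combined score.
    """
    scores = compute_risk_scores(panel, x)
    high = scores > panel.cutoff
    if high.all() or not high.any():
        raise ValueError("degenerate split: one risk group is empty")
    stat, p = logrank_test(high.astype(int), surv)
    report = {
        "n": surv.n,
        "n_events": surv.n_events,
        "n_high": int(high.sum()),
        "n_low": int((~high).sum()),
        "cutoff": float(panel.cutoff),
        "logrank_statistic": stat,
        "logrank_p": p,
        "c_index": concordance_index(scores, surv),
    }
    try:
        auc, roc = time_dependent_auc(scores, surv, horizon)
        report["auc"] = auc
        report["roc"] = roc
    except ValueError as exc:
        report["auc"] = None
        report["auc_error"] = str(exc)
    mask_high = high
    report["km_high"] = km_curve(
        SurvivalData(
            surv.time[mask_high],
            surv.event[mask_high],
            [s for s, m in zip(surv.sample_ids, mask_high) if m],
        )
    )
    report["km_low"] = km_curve(
        SurvivalData(
            surv.time[~mask_high],
            surv.event[~mask_high],
            [s for s, m in zip(surv.sample_ids, mask_high) if not m],
        )
    )
    if clinical is not None:
        from .classifier import encode_clinical

        clin = encode_clinical(clinical.loc[x.index], ("gleason", "age", "stage"))
        xc = pd.concat([x[panel.features], clin], axis=1)
        fit = multivariate_cox(xc, surv)
        combined = xc.to_numpy(float) @ fit.coefficients
        cut = find_cutoff(combined, surv)
        high_c = combined > cut
        stat_c, p_c = logrank_test(high_c.astype(int), surv)
        report["clinical"] = {
            "features": list(xc.columns),
            "coefficients": fit.coefficients.tolist(),
            "cutoff": float(cut),
            "logrank_statistic": stat_c,
            "logrank_p": p_c,
            "c_index": concordance_index(combined, surv),
        }
        try:
            auc_c, _ = time_dependent_auc(combined, surv, horizon)
            report["clinical"]["auc"] = auc_c
        except ValueError as exc:
            report["clinical"]["auc"] = None
            report["clinical"]["auc_error"] = str(exc)
    return report
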