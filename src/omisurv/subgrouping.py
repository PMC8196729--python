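"""Subtype discovery and differential-feature machinery.

K-means on the Cox-selected latent nodes picks the cluster number by mean
silhouette (elbow/within-cluster SS reported as a diagnostic); the two
subgroups are then tagged high/low recurrence risk from their Kaplan–Meier
curves; per-omics Wilcoxon rank-sum tests rank features between the risk
groups; the two arms' top lists are intersected with a direction-concordance
check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .containers import LatentMatrix, OmicsMatrix, SurvivalData
from .survival import km_median

LOW_SILHOUETTE = 0.25


@dataclass
class SubgroupLabels:
    """Per-sample cluster labels in {1..k}; for k=2 a high/low risk tag."""

    labels: np.ndarray
    sample_ids: list[str]
    risk_order: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.sample_ids):
            raise ValueError("labels and sample_ids must have equal length")

    @property
    def k(self) -> int:
        return len(np.unique(self.labels))

    def high_risk_mask(self) -> np.ndarray:
        if not self.risk_order:
            raise ValueError("risk order not assigned; call assign_risk_order")
        high = [lab for lab, tag in self.risk_order.items() if tag == "high"]
        return np.isin(self.labels, high)


def kmeans_select_k(
    latent: LatentMatrix,
    k_range: tuple[int, ...] = tuple(range(2, 11)),
    seed: int = 0,
) -> tuple[int, SubgroupLabels, dict[int, float], dict[int, float]]:
    """Pick k maximizing mean silhouette over ``k_range``; returns
    (k*, labels, silhouette trace, within-cluster-SS elbow trace)."""
    x = latent.values
    n = x.shape[0]
    if x.shape[1] < 2:
        raise ValueError("need at least 2 selected nodes for clustering")
    feasible = [k for k in k_range if 2 <= k <= n - 1]
    if len(feasible) < len(k_range):
        warnings.warn(
            f"k_range truncated to {feasible} for n={n}", RuntimeWarning, stacklevel=2
        )
    silhouette: dict[int, float] = {}
    elbow: dict[int, float] = {}
    fits: dict[int, np.ndarray] = {}
    for k in feasible:
        km = KMeans(n_clusters=k, n_init=20, random_state=seed).fit(x)
        fits[k] = km.labels_ + 1
        elbow[k] = float(km.inertia_)
        silhouette[k] = float(silhouette_score(x, km.labels_))
    best = max(silhouette.values())
    k_star = min(k for k, s in silhouette.items() if s == best)
    if best < LOW_SILHOUETTE:
        warnings.warn(
            f"low silhouette ({best:.3f}) at k={k_star}: weak cluster structure",
            RuntimeWarning,
            stacklevel=2,
        )
    labels = SubgroupLabels(fits[k_star], latent.sample_ids)
    return k_star, labels, silhouette, elbow


def assign_risk_order(labels: SubgroupLabels, surv: SurvivalData) -> SubgroupLabels:
    """Tag the k=2 subgroup with the shorter median KM survival 'high'
    (fallback: higher event rate; final tie: higher event count)."""
    if labels.k != 2:
        raise ValueError("risk order is defined only for k = 2")
    groups = sorted(np.unique(labels.labels))
    stats_per_group = {}
    for g in groups:
        mask = labels.labels == g
        sub = SurvivalData(
            surv.time[mask], surv.event[mask], [s for s, m in zip(surv.sample_ids, mask) if m]
        )
        stats_per_group[g] = (
            km_median(sub),
            sub.n_events / sub.n,
            sub.n_events,
        )
    (m1, r1, c1), (m2, r2, c2) = (stats_per_group[g] for g in groups)
    if np.isfinite(m1) or np.isfinite(m2):
        med1 = m1 if np.isfinite(m1) else np.inf
        med2 = m2 if np.isfinite(m2) else np.inf
    else:
        med1 = med2 = np.inf
    if med1 != med2:
        high = groups[0] if med1 < med2 else groups[1]
    elif r1 != r2:
        high = groups[0] if r1 > r2 else groups[1]
    else:
        warnings.warn(
            "groups have identical survival profile; risk tie broken by event count",
            RuntimeWarning,
            stacklevel=2,
        )
        high = groups[0] if c1 >= c2 else groups[1]
    low = groups[1] if high == groups[0] else groups[0]
    return SubgroupLabels(
        labels.labels, labels.sample_ids, {high: "high", low: "low"}
    )


def _rank_sum_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney U): exact for small
    tie-free groups, tie-corrected normal approximation otherwise."""
    if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
        return 0.0, 1.0
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (min(len(x), len(y)) < 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_de(block: OmicsMatrix, labels: SubgroupLabels) -> pd.DataFrame:
    """Per-feature rank-sum test between the high- and low-risk subgroups.

    Returns the DE table: kind, feature_id, statistic, p, mean_high,
    mean_low, direction (sign of mean_high - mean_low)."""
    high = labels.high_risk_mask()
    if high.sum() == 0 or (~high).sum() == 0:
        raise ValueError("both subgroups must be nonempty")
    rows = []
    for j, fid in enumerate(block.feature_ids):
        x = block.values[high, j]
        y = block.values[~high, j]
        mean_high, mean_low = float(x.mean()), float(y.mean())
        if np.std(np.concatenate([x, y])) == 0:
            stat, p = 0.0, 1.0
        else:
            stat, p = _rank_sum_p(x, y)
        d = mean_high - mean_low
        direction = "+" if d > 0 else ("-" if d < 0 else "0")
        rows.append((block.kind, fid, stat, p, mean_high, mean_low, direction))
    return pd.DataFrame(
        rows,
        columns=["kind", "feature_id", "statistic", "p", "mean_high", "mean_low", "direction"],
    )


DEFAULT_QUOTAS = {"expression": 100, "methylation": 100, "mirna": 50}


def select_top_features(
    tables: dict[str, pd.DataFrame], quotas: dict[str, int] | None = None
) -> pd.DataFrame:
    """Per omics, sort by ascending p (ties: larger |mean difference|
    first, then lexicographic ID), truncate to the quota, concatenate."""
    quotas = dict(DEFAULT_QUOTAS if quotas is None else quotas)
    parts = []
    for kind, table in tables.items():
        quota = quotas.get(kind, len(table))
        t = table.copy()
        t["abs_diff"] = (t["mean_high"] - t["mean_low"]).abs()
        t = t.sort_values(
            by=["p", "abs_diff", "feature_id"], ascending=[True, False, True], kind="stable"
        ).drop(columns="abs_diff")
        if quota > len(t):
            warnings.warn(
                f"quota {quota} exceeds {len(t)} available {kind} features; taking all",
                RuntimeWarning,
                stacklevel=2,
            )
            quota = len(t)
        parts.append(t.head(quota))
    return pd.concat(parts, ignore_index=True)


def intersect_models(
    top_a: pd.DataFrame, top_b: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Per-omics intersection of the two arms' top-feature lists with a
    direction-concordance flag (directions must already be computed on
    risk-aligned labels in both arms)."""
    report: dict[str, pd.DataFrame] = {}
    kinds = sorted(set(top_a["kind"]).union(top_b["kind"]))
    for kind in kinds:
        a = top_a[top_a["kind"] == kind].set_index("feature_id")
        b = top_b[top_b["kind"] == kind].set_index("feature_id")
        shared = sorted(set(a.index) & set(b.index))
        rows = []
        for fid in shared:
            dir_a, dir_b = a.loc[fid, "direction"], b.loc[fid, "direction"]
            rows.append(
                {
                    "kind": kind,
                    "feature_id": fid,
                    "p_a": float(a.loc[fid, "p"]),
                    "p_b": float(b.loc[fid, "p"]),
                    "direction_a": dir_a,
                    "direction_b": dir_b,
                    "concordant": bool(dir_a == dir_b),
                }
            )
        report[kind] = pd.DataFrame(
            rows,
            columns=[
                "kind", "feature_id", "p_a", "p_b",
                "direction_a", "direction_b", "concordant",
            ],
        )
    return report
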