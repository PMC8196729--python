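"""End-to-end orchestration of the two subtyping arms and the risk panel.

The two arms run independently on the same preprocessed cohort:

* SNF arm — per-omics affinity graphs, cross-network fusion, spectral
  clustering of the fused network;
* autoencoder arm — stacked matrix, bottleneck features, univariate Cox
  screen of the latent nodes, k-means on the surviving nodes.

Each arm's two subgroups are tagged high/low risk from their KM curves,
differential features are ranked per omics, the arms' top lists are
intersected, and the panel stage fits a multivariate Cox risk score on the
intersected features with a maximally selected cutpoint.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .autoencoder import AEConfig, encode, train_autoencoder, tuned_profile
from .classifier import crossvalidate_svm, build_feature_table
from .containers import LatentMatrix, MultiOmicsSet, SurvivalData
from .preprocess import preprocess_blocks
from .snf import AffinityGraph, SNFConfig, affinity_matrix, estimate_num_clusters, fuse_networks, pairwise_distance, spectral_cluster
from .subgrouping import (
    DEFAULT_QUOTAS,
    SubgroupLabels,
    assign_risk_order,
    intersect_models,
    kmeans_select_k,
    select_top_features,
    wilcoxon_de,
)
from .survival import concordance_index, logrank_test, univariate_cox_screen
from .synthetic import Cohort
from .risk_panel import RiskPanel, evaluate_panel, fit_panel, pick_panel_features


@dataclass
class RunConfig:
    """Everything one end-to-end run needs."""

    snf: SNFConfig = field(default_factory=SNFConfig)
    ae: AEConfig = field(default_factory=tuned_profile)
    screen_alpha: float = 0.05
    de_quotas: dict = field(default_factory=lambda: dict(DEFAULT_QUOTAS))
    cv_folds: int = 5
    cv_reps: int = 10
    panel_per_omics: int = 2
    horizon: float = 60.0
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(
            dataclasses.asdict(self), sort_keys=True, default=str
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class ArmResult:
    """One arm's dichotomy plus its survival metrics and DE output."""

    name: str
    labels: SubgroupLabels
    c_index: float
    logrank_statistic: float
    logrank_p: float
    de_tables: dict[str, pd.DataFrame]
    top_features: pd.DataFrame
    extras: dict = field(default_factory=dict)


def _arm_metrics(labels: SubgroupLabels, surv: SurvivalData) -> tuple[float, float, float]:
    risk = labels.high_risk_mask().astype(float)
    c = concordance_index(risk, surv)
    stat, p = logrank_test(risk.astype(int), surv)
    return c, stat, p


def _de_and_top(
    mos: MultiOmicsSet, labels: SubgroupLabels, quotas: dict
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    tables = {b.kind: wilcoxon_de(b, labels) for b in mos.blocks}
    return tables, select_top_features(tables, quotas)


def snf_arm(mos: MultiOmicsSet, surv: SurvivalData, cfg: RunConfig) -> ArmResult:
    """Fuse the per-omics affinity graphs and dichotomize by spectral
    clustering (k = 2, the study's dichotomy; the estimated k is reported)."""
    graphs: list[AffinityGraph] = []
    for b in mos.blocks:
        d = pairwise_distance(b.values, b.sample_ids)
        graphs.append(affinity_matrix(d, cfg.snf))
    fused = fuse_networks(graphs, cfg.snf)
    k_eigengap, k_rotation = estimate_num_clusters(fused, cfg.snf)
    raw = spectral_cluster(fused, 2, seed=cfg.snf.seed)
    labels = assign_risk_order(SubgroupLabels(raw, mos.sample_ids), surv)
    c, stat, p = _arm_metrics(labels, surv)
    de, top = _de_and_top(mos, labels, cfg.de_quotas)
    return ArmResult(
        "snf", labels, c, stat, p, de, top,
        extras={"k_eigengap": k_eigengap, "k_rotation": k_rotation, "fused": fused},
    )


def autoencoder_arm(mos: MultiOmicsSet, surv: SurvivalData, cfg: RunConfig) -> ArmResult:
    """Train the autoencoder on the stacked matrix, screen the latent nodes
    by univariate Cox, k-means the surviving nodes into two subgroups."""
    if mos.stacked is None:
        raise ValueError("multiomics set is not stacked")
    model = train_autoencoder(mos.stacked, cfg.ae)
    latent = encode(model, mos.stacked, mos.sample_ids)
    selected, _ = univariate_cox_screen(latent.to_frame(), surv, alpha=cfg.screen_alpha)
    if len(selected) < 2:
        warnings.warn(
            f"only {len(selected)} latent nodes passed the Cox screen; "
            "clustering on all nodes",
            RuntimeWarning,
            stacklevel=2,
        )
        selected = latent.node_ids
    latent_sel = latent.select_nodes(selected)
    k_star, labels_k, silhouette, elbow = kmeans_select_k(
        latent_sel, seed=cfg.seed
    )
    if k_star == 2:
        raw = labels_k.labels
    else:
        raw = KMeans(n_clusters=2, n_init=20, random_state=cfg.seed).fit_predict(
            latent_sel.values
        ) + 1
    labels = assign_risk_order(SubgroupLabels(raw, mos.sample_ids), surv)
    c, stat, p = _arm_metrics(labels, surv)
    de, top = _de_and_top(mos, labels, cfg.de_quotas)
    return ArmResult(
        "autoencoder", labels, c, stat, p, de, top,
        extras={
            "k_star": k_star,
            "silhouette": silhouette,
            "elbow": elbow,
            "latent": latent,
            "selected_nodes": selected,
            "latent_selected": latent_sel,
            "loss_trace": model.loss_trace,
        },
    )


@dataclass
class SubtypingResult:
    snf: ArmResult
    autoencoder: ArmResult
    intersection: dict[str, pd.DataFrame]
    mos: MultiOmicsSet
    survival: SurvivalData
    clinical: pd.DataFrame
    config_hash: str

    def manifest(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "n_samples": self.survival.n,
            "n_events": self.survival.n_events,
            "artifacts": {
                "snf_labels": len(self.snf.labels.labels),
                "autoencoder_labels": len(self.autoencoder.labels.labels),
                "de_tables": {
                    arm.name: sorted(arm.de_tables) for arm in (self.snf, self.autoencoder)
                },
                "intersection": {k: len(v) for k, v in self.intersection.items()},
            },
        }


def run_subtyping(cohort: Cohort, cfg: RunConfig | None = None) -> SubtypingResult:
    """Preprocess the cohort and run both arms through the intersection."""
    cfg = cfg or RunConfig()
    mos, clin, _ = preprocess_blocks(cohort.omics, cohort.clinical)
    surv = cohort.survival.subset(mos.sample_ids)
    snf_res = snf_arm(mos, surv, cfg)
    ae_res = autoencoder_arm(mos, surv, cfg)
    intersection = intersect_models(ae_res.top_features, snf_res.top_features)
    return SubtypingResult(
        snf=snf_res,
        autoencoder=ae_res,
        intersection=intersection,
        mos=mos,
        survival=surv,
        clinical=clin,
        config_hash=cfg.config_hash(),
    )


def feature_value_frame(mos: MultiOmicsSet) -> pd.DataFrame:
    """Stacked values keyed by feature_id (IDs must be globally unique)."""
    fids = [fid for _, fid in mos.provenance]
    if len(set(fids)) != len(fids):
        fids = [f"{kind}:{fid}" for kind, fid in mos.provenance]
    return pd.DataFrame(mos.stacked, index=mos.sample_ids, columns=fids)


def run_panel(
    subtyping: SubtypingResult, cfg: RunConfig | None = None
) -> tuple[RiskPanel, dict]:
    """Pick, fit and evaluate the multiomics panel on the intersection."""
    cfg = cfg or RunConfig()
    if all(t.empty for t in subtyping.intersection.values()):
        raise ValueError(
            "empty cross-arm intersection; increase the DE quotas and rerun"
        )
    candidates = pick_panel_features(subtyping.intersection, cfg.panel_per_omics)
    x = feature_value_frame(subtyping.mos)
    panel = fit_panel(candidates, x, subtyping.survival, screen_alpha=cfg.screen_alpha)
    report = evaluate_panel(
        panel, x, subtyping.survival, clinical=subtyping.clinical, horizon=cfg.horizon
    )
    panel.with_clinical = "clinical" in report
    if panel.with_clinical:
        panel.clinical_features = report["clinical"]["features"]
        panel.clinical_coefficients = np.asarray(report["clinical"]["coefficients"])
    return panel, report


def run_classifier_suite(
    subtyping: SubtypingResult, cfg: RunConfig | None = None, sets: tuple[str, ...] | None = None
) -> pd.DataFrame:
    """Repeated-CV SVM table over the feature-set combinations, using the
    autoencoder arm's labels (the arm with the stronger dichotomy)."""
    cfg = cfg or RunConfig()
    labels = subtyping.autoencoder.labels
    latent_sel: LatentMatrix = subtyping.autoencoder.extras["latent_selected"]
    sets = sets or (
        "nodes",
        "multiomics",
        "multiomics+all_clinical",
        "multiomics+stage",
        "multiomics+age",
        "multiomics+gleason",
    )
    rows = []
    for set_name in sets:
        table = build_feature_table(
            set_name,
            latent_sel,
            subtyping.autoencoder.top_features,
            subtyping.mos,
            subtyping.clinical,
        )
        report = crossvalidate_svm(
            table, labels, folds=cfg.cv_folds, reps=cfg.cv_reps,
            seed=cfg.seed, feature_set=set_name,
        )
        rows.append(report.summary())
    return pd.DataFrame(rows)
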