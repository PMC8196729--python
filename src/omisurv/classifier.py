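"""SVM subgroup classifiers evaluated by repeated stratified 5-fold CV.

Feature sets combine the Cox-selected latent nodes, the top multiomics
features (default 100 + 100 + 50 = 250), and clinical covariates (age
numeric, Gleason numeric, stage ordinal from the T category).  Metrics are
accuracy, sensitivity and specificity with the high-risk subgroup as the
positive class; feature standardization is fitted on training folds only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .containers import LatentMatrix, MultiOmicsSet
from .subgrouping import SubgroupLabels

FEATURE_SETS = (
    "nodes",
    "multiomics",
    "multiomics+all_clinical",
    "multiomics+stage",
    "multiomics+age",
    "multiomics+gleason",
)

STAGE_ORDER = {"I": 1, "II": 2, "III": 3, "IV": 4}


@dataclass
class CVReport:
    """Per-fold metrics of one repeated stratified CV run."""

    feature_set: str
    accuracy: np.ndarray  # (reps * folds,)
    sensitivity: np.ndarray
    specificity: np.ndarray
    folds: int
    reps: int
    seed: int

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracy.mean())

    @property
    def mean_sensitivity(self) -> float:
        return float(np.nanmean(self.sensitivity))

    @property
    def mean_specificity(self) -> float:
        return float(np.nanmean(self.specificity))

    def summary(self) -> dict[str, float]:
        return {
            "feature_set": self.feature_set,
            "accuracy": self.mean_accuracy,
            "accuracy_sd": float(self.accuracy.std(ddof=1)),
            "sensitivity": self.mean_sensitivity,
            "specificity": self.mean_specificity,
        }


def encode_clinical(clinical: pd.DataFrame, which: tuple[str, ...]) -> pd.DataFrame:
    """Numeric encoding of the requested clinical covariates."""
    cols = {}
    for name in which:
        if name == "age":
            cols["age"] = clinical["age"].to_numpy(float)
        elif name == "gleason":
            cols["gleason"] = clinical["gleason"].to_numpy(float)
        elif name == "stage":
            cols["stage"] = clinical["stage"].map(STAGE_ORDER).to_numpy(float)
        else:
            raise KeyError(f"unknown clinical covariate {name!r}")
    return pd.DataFrame(cols, index=clinical.index)


def build_feature_table(
    set_name: str,
    latent_selected: LatentMatrix,
    multiomics_top: pd.DataFrame,
    stacked: MultiOmicsSet,
    clinical: pd.DataFrame,
) -> pd.DataFrame:
    """Assemble the named feature matrix (samples x columns).

    ``multiomics_top`` is the combined top-feature table from the DE step;
    its values are pulled out of the stacked multiomics set.
    """
    if set_name not in FEATURE_SETS:
        raise KeyError(f"unknown feature set {set_name!r}; valid: {FEATURE_SETS}")
    sample_ids = stacked.sample_ids
    if set_name == "nodes":
        return latent_selected.to_frame()
    col_index = {kf: i for i, kf in enumerate(stacked.provenance)}
    cols = {}
    for _, row in multiomics_top.iterrows():
        key = (row["kind"], row["feature_id"])
        cols[f"{row['kind']}:{row['feature_id']}"] = stacked.stacked[:, col_index[key]]
    table = pd.DataFrame(cols, index=sample_ids)
    if set_name == "multiomics":
        return table
    suffix = set_name.split("+", 1)[1]
    which = ("gleason", "age", "stage") if suffix == "all_clinical" else (suffix,)
    clin = encode_clinical(clinical.loc[sample_ids], which)
    return pd.concat([table, clin], axis=1)


def crossvalidate_svm(
    x: pd.DataFrame,
    labels: SubgroupLabels,
    folds: int = 5,
    reps: int = 10,
    seed: int = 0,
    feature_set: str = "custom",
) -> CVReport:
    """Repeated stratified k-fold CV of an RBF-kernel SVM (C=1,
    gamma='scale'); sensitivity treats the high-risk subgroup as positive."""
    y = labels.high_risk_mask().astype(int)
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    if len(y) < folds:
        raise ValueError("need at least `folds` samples")
    xv = x.to_numpy(float)
    cv = RepeatedStratifiedKFold(n_splits=folds, n_repeats=reps, random_state=seed)
    acc, sens, spec = [], [], []
    for train, test in cv.split(xv, y):
        clf = make_pipeline(StandardScaler(), SVC(C=1.0, kernel="rbf", gamma="scale"))
        clf.fit(xv[train], y[train])
        pred = clf.predict(xv[test])
        truth = y[test]
        acc.append(float((pred == truth).mean()))
        pos, neg = truth == 1, truth == 0
        sens.append(float((pred[pos] == 1).mean()) if pos.any() else np.nan)
        spec.append(float((pred[neg] == 0).mean()) if neg.any() else np.nan)
    return CVReport(
        feature_set=feature_set,
        accuracy=np.asarray(acc),
        sensitivity=np.asarray(sens),
        specificity=np.asarray(spec),
        folds=folds,
        reps=reps,
        seed=seed,
    )
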