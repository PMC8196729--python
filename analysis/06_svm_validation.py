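"""Repeated stratified 5-fold SVM cross-validation over the feature-set
combinations (latent nodes / top multiomics features / clinical add-ons),
using the autoencoder arm's subgroup labels."""

import warnings
from pathlib import Path

import pandas as pd

from omisurv.classifier import FEATURE_SETS, build_feature_table, crossvalidate_svm
from omisurv.preprocess import preprocess_blocks
from omisurv.containers import LatentMatrix
from omisurv.synthetic import read_cohort

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = read_cohort(ROOT / "cohort")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mos, clin, _ = preprocess_blocks(cohort.omics, cohort.clinical)
    import importlib.util

    spec = importlib.util.spec_from_file_location(
        "de_step", Path(__file__).with_name("05_differential_features.py")
    )
    de_step = importlib.util.module_from_spec(spec)
    spec.loader.exec_module(de_step)
    labels = de_step.load_labels(ROOT / "autoencoder_labels.tsv", mos.sample_ids)
    top = pd.read_csv(ROOT / "autoencoder_top_features.tsv", sep="\t")
    nodes = pd.read_csv(ROOT / "autoencoder_selected_nodes.tsv", sep="\t", index_col=0)
    latent = LatentMatrix(
        nodes.to_numpy(float), [str(s) for s in nodes.index], list(nodes.columns)
    )
    rows = []
    for set_name in FEATURE_SETS:
        table = build_feature_table(set_name, latent, top, mos, clin)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = crossvalidate_svm(table, labels, seed=0, feature_set=set_name)
        rows.append(report.summary())
        print(f"{set_name:28s} accuracy {report.mean_accuracy:6.1%} "
              f"sensitivity {report.mean_sensitivity:6.1%} "
              f"specificity {report.mean_specificity:6.1%}")
    pd.DataFrame(rows).to_csv(ROOT / "svm_cv.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
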