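"""Differential features per arm (Wilcoxon rank-sum between the high- and
low-risk subgroups), top-100/100/50 selection, and the cross-arm
intersection with direction concordance."""

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from omisurv.preprocess import preprocess_blocks
from omisurv.subgrouping import (
    SubgroupLabels,
    intersect_models,
    select_top_features,
    wilcoxon_de,
)
from omisurv.synthetic import read_cohort

ROOT = Path(__file__).resolve().parent.parent / "results"


def load_labels(path: Path, sample_ids: list[str]) -> SubgroupLabels:
    df = pd.read_csv(path, sep="\t", index_col=0).loc[sample_ids]
    labels = SubgroupLabels(df["cluster"].to_numpy(int), sample_ids)
    labels.risk_order = {
        int(c): str(df["risk"][df["cluster"] == c].iloc[0])
        for c in np.unique(df["cluster"])
    }
    return labels


def main() -> None:
    cohort = read_cohort(ROOT / "cohort")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mos, _, _ = preprocess_blocks(cohort.omics, cohort.clinical)
    tops = {}
    for arm in ("snf", "autoencoder"):
        labels = load_labels(ROOT / f"{arm}_labels.tsv", mos.sample_ids)
        tables = {b.kind: wilcoxon_de(b, labels) for b in mos.blocks}
        top = select_top_features(tables)
        top.to_csv(ROOT / f"{arm}_top_features.tsv", sep="\t", index=False)
        tops[arm] = top
        counts = top["kind"].value_counts().to_dict()
        print(f"{arm}: top features per omics {counts} "
              f"(total {len(top)})")
    intersection = intersect_models(tops["autoencoder"], tops["snf"])
    payload = {}
    for kind, table in intersection.items():
        payload[kind] = table.to_dict(orient="records")
        n_conc = int(table["concordant"].sum()) if not table.empty else 0
        print(f"intersection {kind}: {len(table)} shared, "
              f"{n_conc} direction-concordant")
    (ROOT / "intersection.json").write_text(json.dumps(payload, indent=2))


if __name__ == "__main__":
    main()
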