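"""Filter, z-score and stack the cohort's omics blocks; record what was
dropped and the stacked dimensionality."""

import json
from pathlib import Path

from omisurv.preprocess import preprocess_blocks
from omisurv.synthetic import read_cohort

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = read_cohort(ROOT / "cohort")
    mos, clin, logs = preprocess_blocks(cohort.omics, cohort.clinical)
    droplog = {kind: log.as_dict() for kind, log in logs.items()}
    out = ROOT / "preprocess_droplog.json"
    out.write_text(json.dumps(droplog, indent=2))
    print(f"samples after alignment: {len(mos.sample_ids)}")
    for b in mos.blocks:
        print(f"  {b.kind}: {b.n_features} features kept, "
              f"{logs[b.kind].n_dropped} dropped")
    print(f"stacked matrix: {mos.stacked.shape[0]} x {mos.stacked.shape[1]}")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
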