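"""Feature filtering, per-feature z-scoring, sample alignment and stacking.

Filtering drops any feature that contains a missing value, is identically
zero, or has zero variance (the last so that z-scoring is defined).
Normalization is per-feature: mean 0, sample SD 1 — the semantics of the
standard normalization step used by similarity-network tooling; per-sample
scaling would destroy cross-sample distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import AlignmentError, MultiOmicsSet, OmicsMatrix


class EmptyBlockError(ValueError):
    """Every feature of a block was dropped by filtering."""


@dataclass
class DropLog:
    """Feature IDs removed by :func:`filter_features`, with reasons."""

    missing: list[str] = field(default_factory=list)
    all_zero: list[str] = field(default_factory=list)
    zero_variance: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, list[str]]:
        return {
            "missing": self.missing,
            "all_zero": self.all_zero,
            "zero_variance": self.zero_variance,
        }

    @property
    def n_dropped(self) -> int:
        return len(self.missing) + len(self.all_zero) + len(self.zero_variance)


def filter_features(m: OmicsMatrix) -> tuple[OmicsMatrix, DropLog]:
    """Return a copy of ``m`` without missing/all-zero/constant features."""
    x = m.values
    log = DropLog()
    keep = np.ones(m.n_features, dtype=bool)
    has_nan = np.isnan(x).any(axis=0)
    all_zero = (x == 0).all(axis=0) & ~has_nan
    with np.errstate(invalid="ignore"):
        const = np.nanstd(x, axis=0) == 0
    const = const & ~has_nan & ~all_zero
    for j in range(m.n_features):
        if has_nan[j]:
            log.missing.append(m.feature_ids[j])
            keep[j] = False
        elif all_zero[j]:
            log.all_zero.append(m.feature_ids[j])
            keep[j] = False
        elif const[j]:
            log.zero_variance.append(m.feature_ids[j])
            keep[j] = False
    if not keep.any():
        raise EmptyBlockError(f"all {m.n_features} features of {m.kind} block dropped")
    kept_ids = [f for f, k in zip(m.feature_ids, keep) if k]
    return OmicsMatrix(x[:, keep], m.sample_ids, kept_ids, m.kind), log


def normalize_features(m: OmicsMatrix) -> OmicsMatrix:
    """Z-score each feature column (mean 0, sample SD 1, ddof=1)."""
    x = m.values
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [m.feature_ids[j] for j in np.nonzero(sd == 0)[0][:5]]
        raise ValueError(
            f"constant feature(s) {bad} in {m.kind} block; run filter_features first"
        )
    z = (x - x.mean(axis=0)) / sd
    return OmicsMatrix(z, m.sample_ids, m.feature_ids, m.kind)


def align_samples(blocks: list[OmicsMatrix], clinical: pd.DataFrame) -> tuple[list[OmicsMatrix], pd.DataFrame]:
    """Keep only samples present in every block AND the clinical table,
    ordered as in the clinical table."""
    common = [s for s in clinical.index.astype(str)]
    for b in blocks:
        present = set(b.sample_ids)
        common = [s for s in common if s in present]
    if not common:
        raise AlignmentError("no samples shared by all omics blocks and the clinical table")
    return [b.subset_samples(common) for b in blocks], clinical.loc[common]


def stack_omics(s: MultiOmicsSet) -> MultiOmicsSet:
    """Concatenate the blocks column-wise and record column provenance."""
    ids0 = s.blocks[0].sample_ids
    offenders = [b.kind for b in s.blocks if b.sample_ids != ids0]
    if offenders:
        raise AlignmentError(f"sample order mismatch in blocks: {offenders}")
    stacked = np.concatenate([b.values for b in s.blocks], axis=1)
    provenance = [(b.kind, f) for b in s.blocks for f in b.feature_ids]
    return MultiOmicsSet(s.blocks, stacked, provenance)


def preprocess_blocks(
    blocks: list[OmicsMatrix], clinical: pd.DataFrame
) -> tuple[MultiOmicsSet, pd.DataFrame, dict[str, DropLog]]:
    """filter -> normalize -> align -> stack, the standard front end."""
    aligned, clin = align_samples(blocks, clinical)
    logs: dict[str, DropLog] = {}
    cleaned = []
    for b in aligned:
        fb, log = filter_features(b)
        logs[b.kind] = log
        cleaned.append(normalize_features(fb))
    mos = stack_omics(MultiOmicsSet(cleaned))
    return mos, clin, logs
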