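"""Core data containers shared across the pipeline.

Every container keeps an explicit, ordered list of sample IDs so that
cross-block alignment is checkable rather than implicit.  Matrices are plain
``numpy`` arrays (samples x features); TSV round-tripping goes through
``pandas``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

OMICS_KINDS = ("expression", "methylation", "mirna")


class AlignmentError(ValueError):
    """Sample IDs do not line up across containers."""


@dataclass
class OmicsMatrix:
    """One omics block: samples x features with IDs and a kind tag."""

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = list(self.sample_ids)
        self.feature_ids = list(self.feature_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples x features matrix")
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.sample_ids)} samples / {len(self.feature_ids)} features"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample IDs")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature IDs")
        if self.kind not in OMICS_KINDS:
            raise ValueError(f"kind must be one of {OMICS_KINDS}, got {self.kind!r}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)

    def subset_samples(self, sample_ids: Sequence[str]) -> "OmicsMatrix":
        """Reorder/subset rows to ``sample_ids`` (all must be present)."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise AlignmentError(f"samples absent from {self.kind} block: {missing[:5]}")
        rows = [index[s] for s in sample_ids]
        return OmicsMatrix(self.values[rows], list(sample_ids), self.feature_ids, self.kind)

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path, kind: str) -> "OmicsMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(float), [str(s) for s in df.index], [str(c) for c in df.columns], kind)


@dataclass
class SurvivalData:
    """Per-sample time-to-recurrence (months) and event indicator (1 = recurrence)."""

    time: np.ndarray
    event: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        self.sample_ids = list(self.sample_ids)
        if not (len(self.time) == len(self.event) == len(self.sample_ids)):
            raise ValueError("time, event and sample_ids must have equal length")
        if np.any(self.time <= 0):
            raise ValueError("all times must be > 0")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicator must be 0/1")

    @property
    def n(self) -> int:
        return len(self.time)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, sample_ids: Sequence[str]) -> "SurvivalData":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise AlignmentError(f"samples absent from survival data: {missing[:5]}")
        rows = [index[s] for s in sample_ids]
        return SurvivalData(self.time[rows], self.event[rows], list(sample_ids))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_months": self.time, "event": self.event}, index=self.sample_ids
        )


@dataclass
class MultiOmicsSet:
    """Three sample-aligned omics blocks, optionally stacked column-wise.

    ``provenance`` maps each stacked column index to ``(kind, feature_id)``.
    """

    blocks: list[OmicsMatrix]
    stacked: np.ndarray | None = None
    provenance: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("at least one omics block required")
        ids0 = self.blocks[0].sample_ids
        for b in self.blocks[1:]:
            if b.sample_ids != ids0:
                raise AlignmentError(
                    f"sample order of {b.kind} block differs from {self.blocks[0].kind}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return self.blocks[0].sample_ids

    def block(self, kind: str) -> OmicsMatrix:
        for b in self.blocks:
            if b.kind == kind:
                return b
        raise KeyError(kind)


@dataclass
class LatentMatrix:
    """Bottleneck activations: one row per sample, one column per latent node."""

    values: np.ndarray
    sample_ids: list[str]
    node_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.node_ids)):
            raise ValueError("latent matrix shape inconsistent with IDs")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.node_ids)

    def select_nodes(self, node_ids: Sequence[str]) -> "LatentMatrix":
        idx = [self.node_ids.index(n) for n in node_ids]
        return LatentMatrix(self.values[:, idx], self.sample_ids, list(node_ids))
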