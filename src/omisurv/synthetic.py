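"""Synthetic multiomics survival cohorts with planted two-subgroup structure.

The generator emulates a prostate-adenocarcinoma recurrence cohort: three
omics blocks (gene expression, methylation beta values, miRNA expression)
carrying a mean-shift signal on an informative feature fraction, exponential
recurrence times with a subgroup hazard ratio, independent exponential
censoring, and clinical covariates (age, Gleason, stage, PSA) whose
distributions shift with the subgroup.

Recurrence times are exponential rather than Weibull: the simplest model
satisfying proportional hazards, which every downstream Cox step assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import OmicsMatrix, SurvivalData

STAGES = ("I", "II", "III", "IV")
GLEASONS = (6, 7, 8, 9, 10)


class ConfigError(ValueError):
    """A simulation-config field violates its invariant."""


@dataclass
class SimConfig:
    """Parameters of the planted-subgroup cohort generator.

    ``effect_size`` is the standardized mean shift added to informative
    features in the high-risk subgroup; ``hazard_ratio`` multiplies the
    recurrence hazard of that subgroup; ``baseline_scale`` is the mean
    recurrence time (months) of the low-risk subgroup.
    """

    n_samples: int = 400
    n_features: tuple[int, int, int] = (400, 400, 200)
    informative_fraction: tuple[float, float, float] = (0.1, 0.1, 0.1)
    effect_size: float = 1.0
    subgroup_prob: float = 0.35
    hazard_ratio: float = 4.0
    baseline_scale: float = 300.0
    censor_scale: float = 20.0
    clinical_assoc: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples <= 0:
            raise ConfigError("n_samples must be > 0")
        if len(self.n_features) != 3 or any(f <= 0 for f in self.n_features):
            raise ConfigError("n_features must be three positive counts")
        if len(self.informative_fraction) != 3 or any(
            not 0.0 <= f <= 1.0 for f in self.informative_fraction
        ):
            raise ConfigError("informative_fraction entries must lie in [0, 1]")
        if not 0.0 < self.subgroup_prob < 1.0:
            raise ConfigError("subgroup_prob must lie in (0, 1)")
        if self.hazard_ratio <= 0:
            raise ConfigError("hazard_ratio must be > 0")
        if self.baseline_scale <= 0:
            raise ConfigError("baseline_scale must be > 0")
        if self.censor_scale <= 0:
            raise ConfigError("censor_scale must be > 0")


@dataclass
class Cohort:
    """A generated cohort with ground truth attached."""

    omics: list[OmicsMatrix]
    survival: SurvivalData
    clinical: pd.DataFrame
    truth: np.ndarray  # 1 = high-risk subgroup
    truth_features: dict[str, list[str]] = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return self.survival.sample_ids


def _feature_ids(kind: str, n: int) -> list[str]:
    prefix = {"expression": "gene", "methylation": "cg", "mirna": "mir"}[kind]
    width = len(str(n))
    return [f"{prefix}_{i:0{width}d}" for i in range(1, n + 1)]


def _shifted_categorical(
    rng: np.random.Generator,
    levels: tuple,
    base_logits: np.ndarray,
    subgroup: np.ndarray,
    shift: float,
) -> np.ndarray:
    """Sample per-subject categories whose odds tilt toward higher levels
    in the high-risk subgroup by ``shift`` log-odds per level step."""
    grade = np.arange(len(levels), dtype=float)
    out = np.empty(len(subgroup), dtype=object)
    for z in (0, 1):
        logits = base_logits + z * shift * grade
        p = np.exp(logits - logits.max())
        p /= p.sum()
        mask = subgroup == z
        out[mask] = rng.choice(np.asarray(levels, dtype=object), size=mask.sum(), p=p)
    return out


def generate_cohort(cfg: SimConfig) -> Cohort:
    """Draw one cohort from ``cfg``; identical seed gives an identical cohort."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    sample_ids = [f"S{i:04d}" for i in range(1, n + 1)]
    z = (rng.random(n) < cfg.subgroup_prob).astype(int)

    blocks: list[OmicsMatrix] = []
    truth_features: dict[str, list[str]] = {}
    for kind, n_feat, frac in zip(
        ("expression", "methylation", "mirna"), cfg.n_features, cfg.informative_fraction
    ):
        fids = _feature_ids(kind, n_feat)
        n_inf = int(round(frac * n_feat))
        inf_idx = rng.choice(n_feat, size=n_inf, replace=False)
        inf_idx.sort()
        latent = rng.standard_normal((n, n_feat))
        latent[:, inf_idx] += cfg.effect_size * z[:, None]
        if kind == "methylation":
            # logit-scale signal squashed to (0,1): beta-value-like marginals
            mu = rng.normal(0.0, 1.5, size=n_feat)
            values = 1.0 / (1.0 + np.exp(-(mu + latent)))
        else:
            # log-normal counts-like marginals
            mu = rng.normal(2.0, 1.0, size=n_feat)
            values = np.exp(mu + latent)
        blocks.append(OmicsMatrix(values, sample_ids, fids, kind))
        truth_features[kind] = [fids[i] for i in inf_idx]

    # exponential recurrence times; hazard multiplied by HR in high-risk group
    rate = (1.0 / cfg.baseline_scale) * np.where(z == 1, cfg.hazard_ratio, 1.0)
    t_event = rng.exponential(1.0 / rate)
    t_censor = rng.exponential(cfg.censor_scale, size=n)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    time = np.maximum(time, 1e-6)
    survival = SurvivalData(time, event, sample_ids)

    age = rng.normal(61.0, 7.0, size=n)
    log_shift = np.log(cfg.clinical_assoc) if cfg.clinical_assoc > 0 else 0.0
    gleason = _shifted_categorical(
        rng, GLEASONS, np.log(np.array([0.2, 0.45, 0.2, 0.1, 0.05])), z, log_shift
    ).astype(int)
    stage = _shifted_categorical(
        rng, STAGES, np.log(np.array([0.25, 0.45, 0.2, 0.1])), z, log_shift
    )
    psa = np.exp(rng.normal(1.8, 0.8, size=n) + 0.3 * log_shift * z)
    clinical = pd.DataFrame(
        {
            "time_months": time,
            "event": event,
            "age": age,
            "gleason": gleason,
            "stage": stage,
            "psa": psa,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return Cohort(blocks, survival, clinical, z, truth_features)


def _force_event_count(cohort: Cohort, target: int) -> Cohort:
    """Flip the minimal set of event indicators so that exactly ``target``
    events remain.  Candidates are ordered by |event time - censor time|
    margin proxy: the observed time of the flip candidates; observed times
    are left untouched, only indicators change."""
    event = cohort.survival.event.copy()
    time = cohort.survival.time
    n_events = int(event.sum())
    if n_events > target:
        # censor the events whose times are largest (least informative events)
        idx = np.nonzero(event == 1)[0]
        order = idx[np.argsort(-time[idx], kind="stable")]
        event[order[: n_events - target]] = 0
    elif n_events < target:
        # promote the censored subjects with the longest follow-up
        idx = np.nonzero(event == 0)[0]
        order = idx[np.argsort(-time[idx], kind="stable")]
        event[order[: target - n_events]] = 1
    survival = SurvivalData(time, event, cohort.survival.sample_ids)
    clinical = cohort.clinical.copy()
    clinical["event"] = event
    return Cohort(cohort.omics, survival, clinical, cohort.truth, cohort.truth_features)


PRAD_PRESET = SimConfig(
    n_samples=494,
    n_features=(400, 400, 200),
    informative_fraction=(0.1, 0.1, 0.1),
    effect_size=1.0,
    subgroup_prob=0.35,
    hazard_ratio=4.0,
    baseline_scale=300.0,
    censor_scale=20.0,
    clinical_assoc=1.5,
    seed=20210494,
)

PRAD_N_SAMPLES = 494
PRAD_N_EVENTS = 60


def prad_preset() -> Cohort:
    """The default cohort: 494 samples with exactly 60 recurrence events.

    The event count is forced deterministically (minimal indicator flips)
    so it is an exact structural property, not a stochastic one.
    """
    cohort = generate_cohort(PRAD_PRESET)
    return _force_event_count(cohort, PRAD_N_EVENTS)


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Write the TSV bundle: one file per omics block, clinical, truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for block in cohort.omics:
        p = outdir / f"{block.kind}.tsv"
        block.write_tsv(p)
        paths[block.kind] = p
    p = outdir / "clinical.tsv"
    cohort.clinical.to_csv(p, sep="\t")
    paths["clinical"] = p
    truth = pd.DataFrame(
        {"subgroup": cohort.truth}, index=pd.Index(cohort.sample_ids, name="sample_id")
    )
    p = outdir / "truth.tsv"
    truth.to_csv(p, sep="\t")
    paths["truth"] = p
    return paths


def read_cohort(indir: str | Path) -> Cohort:
    """Read a TSV bundle written by :func:`write_cohort`."""
    indir = Path(indir)
    blocks = [
        OmicsMatrix.read_tsv(indir / f"{kind}.tsv", kind)
        for kind in ("expression", "methylation", "mirna")
    ]
    clinical = pd.read_csv(indir / "clinical.tsv", sep="\t", index_col=0)
    clinical.index = clinical.index.astype(str)
    sample_ids = list(clinical.index)
    survival = SurvivalData(
        clinical["time_months"].to_numpy(float),
        clinical["event"].to_numpy(int),
        sample_ids,
    )
    truth_path = indir / "truth.tsv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path, sep="\t", index_col=0)["subgroup"].to_numpy(int)
    else:
        truth = np.full(len(sample_ids), -1)
    blocks = [b.subset_samples(sample_ids) for b in blocks]
    return Cohort(blocks, survival, clinical, truth)
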