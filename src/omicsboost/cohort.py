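"""Synthetic multiomics cohort generation.

Emulates a surgical colorectal-cancer cohort in which each patient carries
several "omics blocks" (clinical covariates, somatic-mutation indicators,
log2-normalised protein and phosphosite abundances) plus a binary
recurrence/metastasis outcome.  The generator plants a known informative
subset in every block so that downstream selection, reduction, augmentation
and classification stages can be tested for recovery and calibration
without any external patient data.

Model
-----
Continuous blocks: each feature is Gaussian with shared variance
``noise_sd**2``; informative features receive a between-class mean shift of
``effect_size * noise_sd`` (classes centred at ∓ shift/2), matching the
location-shift alternative assumed by the two-sample tests applied later.

Discrete blocks: binary 0/1 codes.  Non-informative features share one
Bernoulli rate across classes; informative features shift the baseline rate
on the log-odds scale by ``effect_size``.

Missing outcomes are encoded with the explicit sentinel
:data:`MISSING_LABEL`, never NaN, so the completeness filter has a crisp
contract.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for an absent outcome label.
MISSING_LABEL = -1

#: Baseline Bernoulli rate for informative discrete features (class 0).
_DISCRETE_BASE_RATE = 0.3


class ConfigurationError(ValueError):
    """Raised when a cohort configuration violates its invariants."""


@dataclass(frozen=True)
class BlockSpec:
    """Specification of one omics block in a synthetic cohort.

    Parameters
    ----------
    name:
        Block identifier (used in file names and feature ids).
    kind:
        ``"discrete"`` (small-cardinality integer codes) or
        ``"continuous"`` (finite reals).
    n_features, n_informative:
        Total width and number of outcome-associated features.
    effect_size:
        Standardised mean shift for continuous features, log-odds shift of
        the Bernoulli rate for discrete features.  Must be >= 0.
    noise_sd:
        Within-class standard deviation of continuous features (ignored for
        discrete blocks).
    """

    name: str
    kind: str
    n_features: int
    n_informative: int
    effect_size: float = 1.0
    noise_sd: float = 1.0

    def validate(self) -> None:
        if self.kind not in ("discrete", "continuous"):
            raise ConfigurationError(f"block {self.name!r}: unknown kind {self.kind!r}")
        if self.n_features < 0 or self.n_informative < 0:
            raise ConfigurationError(f"block {self.name!r}: negative feature counts")
        if self.n_informative > self.n_features:
            raise ConfigurationError(
                f"block {self.name!r}: n_informative ({self.n_informative}) "
                f"exceeds n_features ({self.n_features})"
            )
        if self.effect_size < 0:
            raise ConfigurationError(f"block {self.name!r}: effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ConfigurationError(f"block {self.name!r}: noise_sd must be > 0")


@dataclass(frozen=True)
class CohortConfig:
    """Full configuration of a synthetic cohort."""

    n_samples: int = 144
    class_balance: float = 70 / 144  # fraction of positive (recurrence) labels
    blocks: tuple[BlockSpec, ...] = ()
    label_missing_count: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ConfigurationError("n_samples must be >= 1")
        if not 0.0 < self.class_balance < 1.0:
            raise ConfigurationError("class_balance must be strictly between 0 and 1")
        if not 0 <= self.label_missing_count <= self.n_samples:
            raise ConfigurationError("label_missing_count out of range")
        if not self.blocks:
            raise ConfigurationError("at least one block is required")
        for spec in self.blocks:
            spec.validate()

    def to_dict(self) -> dict:
        return asdict(self)


def default_config(
    seed: int = 0,
    n_samples: int = 144,
    label_missing_count: int = 0,
    continuous_effect: float = 1.0,
    discrete_effect: float = 1.5,
) -> CohortConfig:
    """Desk-scale default cohort: the study's 144 labelled samples with the
    informative-feature counts of the real selection outcome (3 clinical,
    3 mutation, 89 protein, 15 phosphosite) embedded in reduced-width
    blocks so the whole pipeline stays fast."""
    blocks = (
        BlockSpec("clinical", "discrete", 10, 3, effect_size=discrete_effect),
        BlockSpec("mutation", "discrete", 20, 3, effect_size=discrete_effect),
        BlockSpec("proteomics", "continuous", 600, 89, effect_size=continuous_effect),
        BlockSpec("phospho", "continuous", 1000, 15, effect_size=continuous_effect),
    )
    return CohortConfig(
        n_samples=n_samples,
        class_balance=70 / 144,
        blocks=blocks,
        label_missing_count=label_missing_count,
        seed=seed,
    )


@dataclass
class OmicsBlock:
    """One typed feature table over the cohort's samples.

    ``values`` is a samples x features DataFrame indexed by sample id.
    ``informative_ids`` is populated only for synthetic blocks and records
    the planted ground truth for recovery tests.
    """

    name: str
    kind: str
    values: pd.DataFrame
    informative_ids: list[str] = field(default_factory=list)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return len(self.values)


@dataclass
class MultiOmicsCohort:
    """Aligned omics blocks plus binary outcome labels.

    ``labels[i]`` is 0, 1 or :data:`MISSING_LABEL`; every block shares the
    cohort's sample order.
    """

    sample_ids: list[str]
    labels: np.ndarray
    blocks: list[OmicsBlock]
    config: CohortConfig | None = None

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if len(self.labels) != n:
            raise ValueError("labels and sample_ids length mismatch")
        for block in self.blocks:
            if block.n_samples != n:
                raise ValueError(
                    f"block {block.name!r} has {block.n_samples} rows, expected {n}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def block(self, name: str) -> OmicsBlock:
        for b in self.blocks:
            if b.name == name:
                return b
        raise KeyError(name)

    def labelled_mask(self) -> np.ndarray:
        return self.labels != MISSING_LABEL

    # ------------------------------------------------------------------ I/O

    def to_dir(self, path: str | Path) -> None:
        """Write one CSV per block plus ``labels.csv`` and a ``truth.json``
        sidecar with the planted informative ids and the config."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for block in self.blocks:
            out = block.values.copy()
            out.insert(0, "sample_id", self.sample_ids)
            out.to_csv(path / f"{block.name}.csv", index=False)
        lab = pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "label": [
                    "" if v == MISSING_LABEL else str(int(v)) for v in self.labels
                ],
            }
        )
        lab.to_csv(path / "labels.csv", index=False)
        truth = {
            "blocks": {
                b.name: {"kind": b.kind, "informative_ids": b.informative_ids}
                for b in self.blocks
            },
            "config": self.config.to_dict() if self.config is not None else None,
        }
        with open(path / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)

    @classmethod
    def from_dir(cls, path: str | Path) -> "MultiOmicsCohort":
        path = Path(path)
        with open(path / "truth.json") as fh:
            truth = json.load(fh)
        lab = pd.read_csv(path / "labels.csv", dtype={"label": "string"})
        sample_ids = lab["sample_id"].astype(str).tolist()
        labels = np.array(
            [
                MISSING_LABEL if pd.isna(v) or v == "" else int(v)
                for v in lab["label"]
            ],
            dtype=int,
        )
        blocks = []
        for name, meta in truth["blocks"].items():
            df = pd.read_csv(path / f"{name}.csv")
            df = df.drop(columns=["sample_id"])
            df.index = pd.Index(sample_ids, name="sample_id")
            if meta["kind"] == "discrete":
                df = df.astype(int)
            blocks.append(
                OmicsBlock(name, meta["kind"], df, list(meta["informative_ids"]))
            )
        return cls(sample_ids, labels, blocks)


def _sigmoid(z: float) -> float:
    return 1.0 / (1.0 + np.exp(-z))


def generate_cohort(config: CohortConfig) -> MultiOmicsCohort:
    """Draw a cohort from *config*; bit-identical for a fixed seed.

    Labels are assigned deterministically in count (``round(balance * n)``
    positives) and shuffled; the samples flagged missing keep a latent
    label that drives their features but emit :data:`MISSING_LABEL`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples

    n_pos = int(round(config.class_balance * n))
    n_pos = min(max(n_pos, 1), n - 1)
    latent = np.zeros(n, dtype=int)
    latent[:n_pos] = 1
    rng.shuffle(latent)

    labels = latent.copy()
    if config.label_missing_count:
        miss_idx = rng.choice(n, size=config.label_missing_count, replace=False)
        labels[miss_idx] = MISSING_LABEL

    sample_ids = [f"S{i:04d}" for i in range(n)]
    blocks: list[OmicsBlock] = []
    for spec in config.blocks:
        feature_ids = [f"{spec.name}_f{j:04d}" for j in range(spec.n_features)]
        informative = sorted(
            rng.choice(spec.n_features, size=spec.n_informative, replace=False)
        )
        if spec.kind == "continuous":
            values = rng.normal(0.0, spec.noise_sd, size=(n, spec.n_features))
            shift = spec.effect_size * spec.noise_sd / 2.0
            signs = np.where(latent == 1, 1.0, -1.0)
            for j in informative:
                values[:, j] += signs * shift
            df = pd.DataFrame(values, columns=feature_ids)
        else:
            rates = rng.uniform(0.15, 0.85, size=spec.n_features)
            prob = np.tile(rates, (n, 1))
            base_logit = np.log(_DISCRETE_BASE_RATE / (1 - _DISCRETE_BASE_RATE))
            p0 = _DISCRETE_BASE_RATE
            p1 = _sigmoid(base_logit + spec.effect_size)
            for j in informative:
                prob[:, j] = np.where(latent == 1, p1, p0)
            values = (rng.random(size=(n, spec.n_features)) < prob).astype(int)
            df = pd.DataFrame(values, columns=feature_ids)
        df.index = pd.Index(sample_ids, name="sample_id")
        blocks.append(
            OmicsBlock(
                spec.name, spec.kind, df, [feature_ids[j] for j in informative]
            )
        )
    return MultiOmicsCohort(sample_ids, labels, blocks, config=config)


def filter_labelled(cohort: MultiOmicsCohort) -> MultiOmicsCohort:
    """Drop every sample whose outcome is missing, preserving order.

    Mirrors the study-design step of restricting the analysis to patients
    with a known postoperative outcome.
    """
    mask = cohort.labelled_mask()
    if mask.all():
        return cohort
    if not mask.any():
        logger.warning("filter_labelled: all labels missing; returning empty cohort")
    keep = np.flatnonzero(mask)
    sample_ids = [cohort.sample_ids[i] for i in keep]
    blocks = [
        OmicsBlock(
            b.name, b.kind, b.values.iloc[keep].copy(), list(b.informative_ids)
        )
        for b in cohort.blocks
    ]
    return MultiOmicsCohort(
        sample_ids, cohort.labels[keep].copy(), blocks, config=cohort.config
    )
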