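"""Sample-size estimation, SMOTE-style augmentation and the F1 overlap score.

The augmentation stage answers "is the cohort big enough for model
training, and if not, how do we grow it without corrupting the class
geometry?".  Three pieces:

* a per-feature two-sample size formula
  ``n = sigma^2 (1/Q1 + 1/Q2)(mu_alpha + mu_beta)^2 / delta^2``
  aggregated per omics block (default: maximum, the most demanding
  feature sets the requirement);
* whole-dataset SMOTE: every sample spawns ``m`` synthetic rows by linear
  interpolation towards one of its ``k`` same-label Euclidean nearest
  neighbours (a single uniform gap multiplier per row), so class balance
  is preserved exactly;
* the maximum Fisher's discriminant ratio F1 = max_i
  (mu1_i - mu2_i)^2 / (sigma1_i^2 + sigma2_i^2), a class-overlap score
  used as the augmentation quality gate (higher = less overlap).

A Gaussian-noise augmenter is provided as the baseline SMOTE is compared
against.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# sample-size estimation
# --------------------------------------------------------------------------


@dataclass
class SampleSizeEstimate:
    """Two-sample size requirement for one feature.

    ``n`` is ``math.inf`` when the between-class mean difference is zero
    (no finite sample size achieves the requested power).
    """

    feature_id: str
    n: float                      # ceil'd integer, or math.inf
    sigma: float
    delta: float
    q1: float
    q2: float
    mu_alpha: float
    mu_beta: float

    @property
    def insufficient(self) -> bool:
        return math.isinf(self.n)


def estimate_sample_size(
    values_class0,
    values_class1,
    alpha: float = 0.05,
    beta: float = 0.2,
    feature_id: str = "",
) -> SampleSizeEstimate:
    """Optimum two-sample size for detecting a feature's class difference.

    sigma is the pooled SD, delta the difference of class means, Q1/Q2 the
    class proportions, and mu_alpha/mu_beta the standard-normal critical
    values for the two error rates (alpha two-sided: 1.96; beta one-sided:
    0.8416 at the defaults).  The result is rounded up.
    """
    x0 = np.asarray(values_class0, dtype=float)
    x1 = np.asarray(values_class1, dtype=float)
    n0, n1 = len(x0), len(x1)
    if n0 < 2 or n1 < 2:
        raise ValueError("estimate_sample_size needs >= 2 values per class")
    sp2 = ((n0 - 1) * x0.var(ddof=1) + (n1 - 1) * x1.var(ddof=1)) / (n0 + n1 - 2)
    sigma = math.sqrt(sp2)
    if sigma == 0:
        raise ValueError("pooled standard deviation is zero")
    delta = x1.mean() - x0.mean()
    q1 = n0 / (n0 + n1)
    q2 = n1 / (n0 + n1)
    mu_alpha = float(stats.norm.ppf(1 - alpha / 2))
    mu_beta = float(stats.norm.ppf(1 - beta))
    if delta == 0:
        n = math.inf
    else:
        n = math.ceil(
            sigma**2 * (1 / q1 + 1 / q2) * (mu_alpha + mu_beta) ** 2 / delta**2
        )
    return SampleSizeEstimate(feature_id, n, sigma, delta, q1, q2, mu_alpha, mu_beta)


def estimate_feature_sizes(
    X: pd.DataFrame, y: np.ndarray, alpha: float = 0.05, beta: float = 0.2
) -> list[SampleSizeEstimate]:
    """Per-column size estimates of a feature table split by binary label."""
    y = np.asarray(y)
    out = []
    for col in X.columns:
        v = X[col].to_numpy(dtype=float)
        out.append(
            estimate_sample_size(v[y == 0], v[y == 1], alpha, beta, feature_id=col)
        )
    return out


def dataset_sample_size(estimates, agg: str = "max") -> float:
    """Aggregate per-feature requirements into one per-dataset n.

    Default aggregation is the maximum: only then is every selected
    feature adequately powered.  All-infinite estimates mean no amount of
    augmentation helps, which is an error.
    """
    if not estimates:
        raise ValueError("dataset_sample_size requires >= 1 estimate")
    ns = [e.n for e in estimates]
    finite = [v for v in ns if not math.isinf(v)]
    if not finite:
        raise ValueError("all features have zero class difference: "
                         "insufficient regardless of augmentation")
    if any(math.isinf(v) for v in ns):
        logger.warning("dataset_sample_size: ignoring %d infinite estimates",
                       len(ns) - len(finite))
    if agg == "max":
        return float(max(finite))
    if agg == "mean":
        return float(np.mean(finite))
    raise ValueError(f"unknown aggregation {agg!r}")


def estimate_block_sizes(
    cohort, selection, alpha: float = 0.05, beta: float = 0.2, agg: str = "max"
) -> dict[str, float]:
    """Per-block size requirement over each block's selected features.

    Blocks with no selected features are skipped.  The overall cohort
    requirement is ``max`` of the returned values.
    """
    out: dict[str, float] = {}
    y = cohort.labels
    for block in cohort.blocks:
        sel = selection.selected_ids(block.name)
        if not sel:
            continue
        ests = estimate_feature_sizes(block.values[sel], y, alpha, beta)
        try:
            out[block.name] = dataset_sample_size(ests, agg=agg)
        except ValueError:
            logger.warning("estimate_block_sizes: block %r has no informative "
                           "feature for sizing", block.name)
    return out


# --------------------------------------------------------------------------
# augmentation generators
# --------------------------------------------------------------------------


@dataclass
class AugmentationResult:
    """Original plus generated rows, with provenance and quality scores."""

    X: pd.DataFrame
    y: np.ndarray
    provenance: np.ndarray        # "original" | "smote" | "noise" per row
    method: str
    params: dict
    seed: int | None
    f1_before: float
    f1_after: float
    extras: dict = field(default_factory=dict)

    @property
    def n_original(self) -> int:
        return int((self.provenance == "original").sum())

    @property
    def n_generated(self) -> int:
        return len(self.y) - self.n_original

    def to_frame(self) -> pd.DataFrame:
        out = self.X.copy()
        out["label"] = self.y
        out["provenance"] = self.provenance
        return out


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"x{j}" for j in range(X.shape[1])])


def smote(
    X,
    y,
    m: int = 1,
    k: int = 5,
    seed: int | None = None,
    discrete_cols: list[str] | None = None,
) -> AugmentationResult:
    """Whole-dataset SMOTE augmentation.

    For every row x_i, find its ``k`` same-label Euclidean nearest
    neighbours, draw ``m`` of them without replacement, and emit
    ``x_new = x_i + u * (x_ij - x_i)`` with one uniform u ~ U(0,1) per
    generated row, labelled like its seed row.  Classes smaller than
    ``k + 1`` fall back to their attainable neighbour count with a
    warning.  ``discrete_cols`` are snapped back to the nearest original
    category after interpolation.
    """
    Xf = _as_frame(X)
    y = np.asarray(y)
    if m < 1:
        raise ValueError("m must be >= 1")
    if m > k:
        raise ValueError("m must not exceed k")
    rng = np.random.default_rng(seed)
    values = Xf.to_numpy(dtype=float)
    n = len(values)
    new_rows, new_labels = [], []
    # per-class neighbour structure
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) < 2:
            raise ValueError(f"class {cls!r} needs >= 2 members for SMOTE")
        k_cls = min(k, len(idx) - 1)
        if k_cls < k:
            logger.warning("smote: class %r has %d members; using k=%d",
                           cls, len(idx), k_cls)
        m_cls = min(m, k_cls)
        dist = cdist(values[idx], values[idx])
        np.fill_diagonal(dist, np.inf)
        # stable neighbour order: distance, then index
        order = np.argsort(dist, axis=1, kind="stable")
        for local_i, i in enumerate(idx):
            neigh = idx[order[local_i, :k_cls]]
            chosen = rng.choice(k_cls, size=m_cls, replace=False)
            for c in chosen:
                u = rng.uniform()
                xi, xj = values[i], values[neigh[c]]
                new_rows.append(xi + u * (xj - xi))
                new_labels.append(cls)
    gen = pd.DataFrame(np.asarray(new_rows), columns=Xf.columns)
    if discrete_cols:
        for col in discrete_cols:
            cats = np.unique(Xf[col].to_numpy(dtype=float))
            snapped = cats[np.argmin(np.abs(gen[col].to_numpy()[:, None] - cats), axis=1)]
            gen[col] = snapped
    combined = pd.concat([Xf.reset_index(drop=True), gen], ignore_index=True)
    labels = np.concatenate([y, np.asarray(new_labels)])
    provenance = np.array(["original"] * n + ["smote"] * len(gen))
    _, f1_before = fisher_ratio_f1(values, y)
    _, f1_after = fisher_ratio_f1(combined.to_numpy(dtype=float), labels)
    return AugmentationResult(
        combined, labels, provenance, "smote",
        {"m": m, "k": k, "discrete_cols": list(discrete_cols or [])},
        seed, f1_before, f1_after,
    )


def noise_augment(X, y, scale: float = 0.1, seed: int | None = None) -> AugmentationResult:
    """Gaussian-jitter baseline: one synthetic row per original,
    x_new = x_i + eps with per-feature eps ~ N(0, (scale * sd_feature)^2),
    labels copied."""
    if scale < 0:
        raise ValueError("scale must be >= 0")
    Xf = _as_frame(X)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    values = Xf.to_numpy(dtype=float)
    sds = values.std(axis=0, ddof=1)
    eps = rng.normal(size=values.shape) * sds * scale
    gen = pd.DataFrame(values + eps, columns=Xf.columns)
    combined = pd.concat([Xf.reset_index(drop=True), gen], ignore_index=True)
    labels = np.concatenate([y, y])
    provenance = np.array(["original"] * len(values) + ["noise"] * len(values))
    _, f1_before = fisher_ratio_f1(values, y)
    _, f1_after = fisher_ratio_f1(combined.to_numpy(dtype=float), labels)
    return AugmentationResult(
        combined, labels, provenance, "noise", {"scale": scale}, seed,
        f1_before, f1_after,
    )


# --------------------------------------------------------------------------
# F1 overlap metric
# --------------------------------------------------------------------------


def fisher_ratio_f1(
    X, y, use_standard_error: bool = False
) -> tuple[np.ndarray, float]:
    """Per-feature Fisher discriminant ratios and their maximum (F1).

    f_i = (mu1_i - mu2_i)^2 / (sigma1_i^2 + sigma2_i^2) with per-class
    sample variances (ddof = 1).  ``use_standard_error=True`` replaces the
    SDs by standard errors of the mean.  Zero denominator gives f_i = 0
    when the numerator is also zero, +inf otherwise.
    """
    X = _as_frame(X).to_numpy(dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("fisher_ratio_f1 requires exactly two classes")
    x1, x2 = X[y == classes[0]], X[y == classes[1]]
    if len(x1) < 2 or len(x2) < 2:
        raise ValueError("each class needs >= 2 samples")
    m1, m2 = x1.mean(axis=0), x2.mean(axis=0)
    v1, v2 = x1.var(axis=0, ddof=1), x2.var(axis=0, ddof=1)
    if use_standard_error:
        v1, v2 = v1 / len(x1), v2 / len(x2)
    num = (m1 - m2) ** 2
    denom = v1 + v2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = num / denom
    f = np.where(denom == 0, np.where(num == 0, 0.0, np.inf), f)
    return f, float(np.max(f))
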