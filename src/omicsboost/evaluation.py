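"""Stratified K-fold comparison of the ensemble against single-model baselines.

Computes the standard confusion-matrix measurements (accuracy, precision,
sensitivity, specificity, F-measure), ROC curves with trapezoidal AUC, and
paired two-sided t tests on per-fold accuracies of each baseline against
the ensemble.  Augmentation can be applied per training fold
(leakage-safe default), to the whole dataset before splitting (faithful to
the original workflow, in which augmentation precedes model training), or
not at all; synthetic rows are never scored — folds are formed over
original rows only and generated rows always stay on the training side.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

from .augmentation import smote
from .ensemble import EnsembleClassifier
from .reduction import ReducedDataset

logger = logging.getLogger(__name__)

AUGMENTATION_POLICIES = ("none", "train_folds_only", "whole_dataset_first")


@dataclass
class MetricSet:
    """Confusion counts and the classification measurements derived from
    them.  Ratios with a zero denominator are reported as 0 and flagged."""

    tp: int
    fp: int
    tn: int
    fn: int
    undefined: list[str] = field(default_factory=list)

    def _ratio(self, num: int, den: int, name: str) -> float:
        if den == 0:
            if name not in self.undefined:
                self.undefined.append(name)
            return 0.0
        return num / den

    @property
    def accuracy(self) -> float:
        return self._ratio(self.tp + self.tn, self.tp + self.tn + self.fp + self.fn,
                           "accuracy")

    @property
    def precision(self) -> float:
        return self._ratio(self.tp, self.tp + self.fp, "precision")

    @property
    def sensitivity(self) -> float:
        return self._ratio(self.tp, self.tp + self.fn, "sensitivity")

    @property
    def specificity(self) -> float:
        return self._ratio(self.tn, self.tn + self.fp, "specificity")

    @property
    def f_measure(self) -> float:
        p, r = self.precision, self.sensitivity
        if p + r == 0:
            if "f_measure" not in self.undefined:
                self.undefined.append("f_measure")
            return 0.0
        return 2 * p * r / (p + r)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "accuracy": self.accuracy, "precision": self.precision,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "f_measure": self.f_measure,
        }


def compute_metrics(y_true, y_pred) -> MetricSet:
    """Exact confusion-matrix arithmetic for binary labels."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred length mismatch")
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    return MetricSet(tp, fp, tn, fn)


def roc_and_auc(y_true, scores) -> tuple[pd.DataFrame, float]:
    """ROC by threshold sweep over the unique scores (tied scores enter
    simultaneously) and trapezoidal AUC."""
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(y_true)) < 2:
        raise ValueError("roc_and_auc requires both classes present")
    fpr, tpr, thresholds = roc_curve(y_true, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return points, auc


def default_model_factories(
    T: int = 10, stacking_mode: str = "out_of_fold"
) -> dict:
    """Model factories: name -> callable(seed) -> unfitted estimator.

    LR, SVM and Naive-Bayes are the single-model baselines, GDBT an
    off-the-shelf gradient-boosted-tree comparator, and ``ensemble`` the
    boosted-stacked model.
    """
    return {
        "LR": lambda seed: LogisticRegression(C=1.0, max_iter=1000),
        "SVM": lambda seed: SVC(kernel="rbf", C=1.0, gamma="scale"),
        "NB": lambda seed: GaussianNB(),
        "GDBT": lambda seed: GradientBoostingClassifier(random_state=seed),
        "ensemble": lambda seed: EnsembleClassifier(
            T=T, stacking_mode=stacking_mode, seed=seed
        ),
    }


def _model_scores(est, X) -> np.ndarray:
    if hasattr(est, "decision_function"):
        return np.asarray(est.decision_function(X), dtype=float)
    return np.asarray(est.predict_proba(X), dtype=float)[:, 1]


@dataclass
class EvalReport:
    """Cross-validated comparison results."""

    metrics: pd.DataFrame             # model x fold x metric rows
    summary: pd.DataFrame             # per-model mean/sd of each metric
    roc: dict[str, pd.DataFrame]      # pooled held-out ROC points per model
    auc: dict[str, float]
    p_values: dict[str, float]        # baseline name -> paired-t p vs ensemble
    K: int
    seed: int
    augmentation_policy: str

    def to_json(self, path: str | Path) -> None:
        payload = {
            "K": self.K,
            "seed": self.seed,
            "augmentation_policy": self.augmentation_policy,
            "summary": self.summary.to_dict(orient="index"),
            "auc": self.auc,
            "p_values_vs_ensemble": self.p_values,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    def metrics_csv(self, path: str | Path) -> None:
        self.metrics.to_csv(path, index=False)

    def roc_csvs(self, directory: str | Path) -> None:
        directory = Path(directory)
        for model, points in self.roc.items():
            points.to_csv(directory / f"roc_{model}.csv", index=False)


METRIC_COLS = ["accuracy", "precision", "sensitivity", "specificity", "f_measure"]


def kfold_evaluate(
    dataset: ReducedDataset,
    K: int = 5,
    seed: int = 0,
    augmentation_policy: str = "train_folds_only",
    models: dict | None = None,
    smote_m: int = 1,
    smote_k: int = 5,
) -> EvalReport:
    """Stratified K-fold evaluation of all models on a reduced design.

    Folds are stratified over the original rows; under either augmentation
    policy the SMOTE rows join only training sets, and held-out scoring is
    restricted to original rows by construction.
    """
    if augmentation_policy not in AUGMENTATION_POLICIES:
        raise ValueError(f"unknown augmentation policy {augmentation_policy!r}")
    if K < 2:
        raise ValueError("K must be >= 2")
    X = dataset.X.to_numpy(dtype=float)
    y = np.asarray(dataset.y, dtype=int)
    if np.bincount(y, minlength=2).min() < K:
        raise ValueError("stratification impossible: a class has fewer members than K")
    models = models if models is not None else default_model_factories()
    discrete_cols = dataset.passthrough_columns
    col_idx = [dataset.X.columns.get_loc(c) for c in discrete_cols]

    whole_aug = None
    if augmentation_policy == "whole_dataset_first":
        whole_aug = smote(dataset.X, y, m=smote_m, k=smote_k, seed=seed,
                          discrete_cols=discrete_cols)

    skf = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed)
    rows = []
    pooled_scores: dict[str, list] = {name: [] for name in models}
    pooled_truth: list = []
    fold_acc: dict[str, list] = {name: [] for name in models}
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        if augmentation_policy == "none":
            X_tr, y_tr = X[tr], y[tr]
        elif augmentation_policy == "train_folds_only":
            aug = smote(
                dataset.X.iloc[tr], y[tr], m=smote_m, k=smote_k,
                seed=seed + 1000 + fold, discrete_cols=discrete_cols,
            )
            X_tr, y_tr = aug.X.to_numpy(dtype=float), aug.y
        else:  # whole_dataset_first: originals of the training folds + every synthetic row
            syn = whole_aug.provenance != "original"
            X_syn = whole_aug.X.to_numpy(dtype=float)[syn]
            y_syn = whole_aug.y[syn]
            X_tr = np.vstack([X[tr], X_syn])
            y_tr = np.concatenate([y[tr], y_syn])
        pooled_truth.append(y[te])
        for name, factory in models.items():
            est = factory(seed + fold)
            est.fit(X_tr, y_tr)
            pred = np.asarray(est.predict(X[te]), dtype=int)
            ms = compute_metrics(y[te], pred)
            rows.append({"model": name, "fold": fold, **ms.as_dict()})
            fold_acc[name].append(ms.accuracy)
            pooled_scores[name].append(_model_scores(est, X[te]))

    metrics = pd.DataFrame(rows)
    summary = (
        metrics.groupby("model")[METRIC_COLS].mean().add_suffix("_mean")
        .join(metrics.groupby("model")[METRIC_COLS].std(ddof=1).add_suffix("_sd"))
    )
    y_pool = np.concatenate(pooled_truth)
    roc, auc = {}, {}
    for name in models:
        points, a = roc_and_auc(y_pool, np.concatenate(pooled_scores[name]))
        roc[name], auc[name] = points, a
    p_values = {}
    if "ensemble" in models:
        ens = np.asarray(fold_acc["ensemble"])
        for name in models:
            if name == "ensemble":
                continue
            other = np.asarray(fold_acc[name])
            if np.allclose(ens, other):
                p_values[name] = 1.0
            else:
                p_values[name] = float(stats.ttest_rel(ens, other).pvalue)
    return EvalReport(metrics, summary, roc, auc, p_values, K, seed,
                      augmentation_policy)


def plot_report(report: EvalReport, directory: str | Path) -> list[Path]:
    """Optional bar + ROC panels; requires matplotlib."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = []

    means = report.metrics.groupby("model")[METRIC_COLS].mean()
    fig, ax = plt.subplots(figsize=(8, 4))
    means.plot.bar(ax=ax, rot=0)
    ax.set_ylabel("mean over folds")
    ax.set_ylim(0, 1.05)
    fig.tight_layout()
    p = directory / "metrics_bar.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    out.append(p)

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, points in report.roc.items():
        ax.plot(points["fpr"], points["tpr"],
                label=f"{name} (AUC={report.auc[name]:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.5)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(fontsize=8)
    fig.tight_layout()
    p = directory / "roc.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    out.append(p)
    return out
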