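"""Boosted heterogeneous ensemble with a logistic stacking layer.

Three weak-learner families — logistic regression, RBF support-vector and
Gaussian naive Bayes — are each boosted with the classical AdaBoost
recursion:

* uniform initial sample weights D_1(i) = 1/n;
* per round, fit h_t under D_t, compute the weighted error
  eps_t = sum of D_t(i) over misclassified i, the round weight
  alpha_t = 1/2 ln((1 - eps_t)/eps_t), and the multiplicative weight
  update D_{t+1}(i) proportional to D_t(i) exp(-/+ alpha_t) for
  correct/incorrect samples, renormalised;
* each family's boosted score is the signed sum H_mT(x) = sum_t
  alpha_t h_t(x) with h_t(x) in {-1, +1}.

The three boosted scores are fused by a logistic meta-model
log(H/(1-H)) = c_0 + sum_m c_m H_mT(x).  The meta-fit can use in-sample
scores (faithful to the original procedure) or out-of-fold scores from an
internal stratified 5-fold split (leakage-safe default for evaluation).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

EPS_MIN = 1e-10
FAMILIES = ("logistic", "support_vector", "naive_bayes")


@dataclass(frozen=True)
class WeakLearnerSpec:
    """One weak-learner family and how it consumes sample weights.

    ``weight_mode="weighted_fit"`` passes the boosting distribution as
    ``sample_weight``; ``"resample"`` draws a weighted bootstrap instead
    (requires a seed).  ``family="custom"`` takes a zero-argument
    ``factory`` in ``params`` (used for stub learners in tests).
    """

    family: str
    params: tuple = ()
    weight_mode: str = "weighted_fit"
    factory: object = None

    def __post_init__(self):
        if self.family not in FAMILIES + ("custom",):
            raise ValueError(f"unknown weak-learner family {self.family!r}")
        if self.weight_mode not in ("weighted_fit", "resample"):
            raise ValueError(f"unknown weight mode {self.weight_mode!r}")


def default_specs() -> tuple[WeakLearnerSpec, ...]:
    return tuple(WeakLearnerSpec(f) for f in FAMILIES)


def _make_estimator(spec: WeakLearnerSpec, seed: int):
    params = dict(spec.params)
    if spec.family == "logistic":
        return LogisticRegression(C=1.0, max_iter=1000, **params)
    if spec.family == "support_vector":
        return SVC(kernel="rbf", C=1.0, gamma="scale", **params)
    if spec.family == "naive_bayes":
        return GaussianNB(**params)
    if spec.family == "custom":
        return spec.factory()
    raise AssertionError(spec.family)


@dataclass
class BoostRound:
    estimator: object
    alpha: float
    eps: float


@dataclass
class BoostedClassifier:
    """One family's boosted sequence (h_t, alpha_t) plus the weight-history
    D_t of the training distribution (each summing to 1)."""

    family: str
    rounds: list[BoostRound]
    weight_history: list[np.ndarray]
    n_features: int

    @property
    def T(self) -> int:
        return len(self.rounds)


def init_weights(n: int) -> np.ndarray:
    """Uniform initial boosting distribution D_1(i) = 1/n."""
    if n < 1:
        raise ValueError("init_weights requires n >= 1")
    return np.full(n, 1.0 / n)


def round_weight(eps: float, eps_min: float = EPS_MIN) -> float:
    """alpha = 1/2 ln((1 - eps)/eps), with eps clipped away from {0, 1}."""
    eps = min(max(eps, eps_min), 1.0 - eps_min)
    return 0.5 * float(np.log((1.0 - eps) / eps))


def boost(
    spec: WeakLearnerSpec,
    X,
    y,
    T: int = 10,
    seed: int = 0,
    eps_min: float = EPS_MIN,
) -> BoostedClassifier:
    """AdaBoost one weak-learner family for up to T rounds.

    A round with weighted error >= 0.5 (no better than chance under the
    current distribution) re-initialises the weights to uniform once; a
    second such round stops boosting.  A perfect round (eps <= eps_min)
    is kept — its alpha sits at the clip ceiling — and boosting stops,
    since the distribution no longer changes.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D and aligned with y")
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError("boost requires binary labels {0, 1} with both present")
    n = len(y)
    rng = np.random.default_rng(seed)
    D = init_weights(n)
    history = [D.copy()]
    rounds: list[BoostRound] = []
    reinitialised = False
    t = 0
    while len(rounds) < T:
        t += 1
        if t > 3 * T:  # safety against pathological non-progress
            break
        est = _make_estimator(spec, seed + t)
        try:
            if spec.weight_mode == "weighted_fit":
                est.fit(X, y, sample_weight=D * n)
            else:
                idx = rng.choice(n, size=n, replace=True, p=D)
                est.fit(X[idx], y[idx])
        except Exception as exc:  # noqa: BLE001 - a failed round is skipped loudly
            logger.warning("boost[%s]: round %d failed to fit (%s); skipped",
                           spec.family, t, exc)
            continue
        pred = np.asarray(est.predict(X), dtype=int)
        miss = pred != y
        eps = float(D[miss].sum())
        if eps >= 0.5:
            if not reinitialised:
                logger.warning("boost[%s]: eps=%.3f >= 0.5; re-initialising weights",
                               spec.family, eps)
                D = init_weights(n)
                history.append(D.copy())
                reinitialised = True
                continue
            logger.warning("boost[%s]: eps >= 0.5 again; early stop", spec.family)
            break
        alpha = round_weight(eps, eps_min)
        rounds.append(BoostRound(est, alpha, eps))
        D = D * np.exp(np.where(miss, alpha, -alpha))
        D = D / D.sum()
        history.append(D.copy())
        if eps <= eps_min:
            break
    if not rounds:
        raise RuntimeError(
            f"boost[{spec.family}]: no weak learner performed better than chance"
        )
    return BoostedClassifier(spec.family, rounds, history, X.shape[1])


def boosted_score(model: BoostedClassifier, X) -> np.ndarray:
    """Signed additive score H_mT(x) = sum_t alpha_t h_t(x), h_t in {-1,+1}."""
    if not model.rounds:
        raise ValueError("boosted_score requires a fitted model")
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"X has {X.shape[1]} columns, model expects {model.n_features}"
        )
    score = np.zeros(len(X))
    for r in model.rounds:
        h = 2 * np.asarray(r.estimator.predict(X), dtype=int) - 1
        score += r.alpha * h
    return score


@dataclass
class EnsembleModel:
    """Three boosted members plus the logistic stacking coefficients.

    ``coef`` is (c_0, c_1, c_2, c_3); members whose score column was
    degenerate (constant) during the meta-fit have c_m = 0 and are flagged
    in ``active``.
    """

    members: list[BoostedClassifier]
    coef: np.ndarray              # (4,): intercept + one weight per member
    active: np.ndarray            # (3,) bool
    T: int
    stacking_mode: str
    seed: int
    feature_names: list[str] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "T": self.T,
            "stacking_mode": self.stacking_mode,
            "seed": self.seed,
            "coef": self.coef.tolist(),
            "active": self.active.tolist(),
            "members": [
                {
                    "family": m.family,
                    "rounds": [{"alpha": r.alpha, "eps": r.eps} for r in m.rounds],
                }
                for m in self.members
            ],
            "feature_names": self.feature_names,
        }


def _score_matrix(members, X) -> np.ndarray:
    return np.column_stack([boosted_score(m, X) for m in members])


def fit_ensemble(
    X,
    y,
    T: int = 10,
    stacking_mode: str = "out_of_fold",
    seed: int = 0,
    specs=None,
    feature_names=None,
) -> EnsembleModel:
    """Boost all three families and fit the logistic stacking layer.

    ``stacking_mode="in_sample"`` fits the meta-model on the members' own
    training scores; ``"out_of_fold"`` (default) uses scores from an
    internal stratified 5-fold split so the meta-fit never sees a score
    produced by a member trained on that sample.
    """
    if stacking_mode not in ("in_sample", "out_of_fold"):
        raise ValueError(f"unknown stacking mode {stacking_mode!r}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    specs = tuple(specs) if specs is not None else default_specs()
    members = [
        boost(spec, X, y, T=T, seed=seed + 97 * m) for m, spec in enumerate(specs)
    ]
    if stacking_mode == "in_sample":
        S = _score_matrix(members, X)
    else:
        S = np.zeros((len(y), len(specs)))
        n_splits = min(5, int(np.bincount(y).min()))
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        for fold, (tr, va) in enumerate(skf.split(X, y)):
            for m, spec in enumerate(specs):
                member = boost(spec, X[tr], y[tr], T=T, seed=seed + 97 * m + 7 * fold)
                S[va, m] = boosted_score(member, X[va])
    # constant (degenerate) score columns, up to float fuzz in the alpha sums
    active = S.std(axis=0) > 1e-9 * np.maximum(1.0, np.abs(S).max(axis=0))
    if not active.all():
        logger.warning("fit_ensemble: %d degenerate (constant) score column(s) "
                       "excluded from the stacking fit", int((~active).sum()))
    if not active.any():
        raise RuntimeError("all boosted score columns are constant; cannot stack")
    meta = LogisticRegression(C=1.0, max_iter=1000)
    meta.fit(S[:, active], y)
    coef = np.zeros(1 + len(members))
    coef[0] = float(meta.intercept_[0])
    coef[1 + np.flatnonzero(active)] = meta.coef_[0]
    return EnsembleModel(
        members, coef, active, T, stacking_mode, seed,
        list(feature_names) if feature_names is not None else [],
    )


def ensemble_probability(model: EnsembleModel, X) -> np.ndarray:
    """H(x) in (0, 1) from the logistic fusion of the member scores."""
    X = np.asarray(X, dtype=float)
    if model.feature_names and X.shape[1] != len(model.feature_names):
        raise ValueError(
            f"X has {X.shape[1]} columns, model expects "
            f"{len(model.feature_names)}: {model.feature_names}"
        )
    S = _score_matrix(model.members, X)
    z = model.coef[0] + S @ model.coef[1:]
    return 1.0 / (1.0 + np.exp(-z))


def predict(model: EnsembleModel, X, threshold: float = 0.5):
    """Labels (1 iff H(x) >= threshold) and probabilities."""
    proba = ensemble_probability(model, X)
    return (proba >= threshold).astype(int), proba


class EnsembleClassifier:
    """Thin scikit-learn-style wrapper used by the evaluation stage."""

    def __init__(self, T: int = 10, stacking_mode: str = "out_of_fold",
                 seed: int = 0, specs=None):
        self.T = T
        self.stacking_mode = stacking_mode
        self.seed = seed
        self.specs = specs
        self.model_: EnsembleModel | None = None

    def fit(self, X, y):
        self.model_ = fit_ensemble(
            X, y, T=self.T, stacking_mode=self.stacking_mode, seed=self.seed,
            specs=self.specs,
        )
        return self

    def predict(self, X):
        labels, _ = predict(self.model_, X)
        return labels

    def predict_proba(self, X):
        p = ensemble_probability(self.model_, X)
        return np.column_stack([1 - p, p])

    def decision_function(self, X):
        p = ensemble_probability(self.model_, X)
        return np.log(p / (1 - p))


def save_model(model: EnsembleModel, directory: str | Path) -> None:
    """Serialise the stacking summary to ``model.json`` and each round's
    weak learner to a joblib artifact under ``rounds/``."""
    import joblib

    directory = Path(directory)
    (directory / "rounds").mkdir(parents=True, exist_ok=True)
    with open(directory / "model.json", "w") as fh:
        json.dump(model.summary(), fh, indent=2, sort_keys=True)
    for m in model.members:
        for t, r in enumerate(m.rounds):
            joblib.dump(r.estimator, directory / "rounds" / f"{m.family}_t{t}.joblib")


def load_model(directory: str | Path) -> EnsembleModel:
    import joblib

    directory = Path(directory)
    with open(directory / "model.json") as fh:
        d = json.load(fh)
    members = []
    for meta in d["members"]:
        rounds = [
            BoostRound(
                joblib.load(directory / "rounds" / f"{meta['family']}_t{t}.joblib"),
                r["alpha"],
                r["eps"],
            )
            for t, r in enumerate(meta["rounds"])
        ]
        n_features = getattr(rounds[0].estimator, "n_features_in_", 0)
        members.append(BoostedClassifier(meta["family"], rounds, [], int(n_features)))
    return EnsembleModel(
        members,
        np.asarray(d["coef"]),
        np.asarray(d["active"], dtype=bool),
        d["T"],
        d["stacking_mode"],
        d["seed"],
        d["feature_names"],
    )
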