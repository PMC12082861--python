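"""Univariate statistical feature selection for typed omics blocks.

Discrete blocks are screened with exact (Fisher) or asymptotic (chi-square)
contingency tests against the binary outcome; continuous blocks are split
by outcome and screened with three two-sample tests — pooled-variance
Student t, Mann-Whitney U with 0.5 tie scoring, and one-way ANOVA — whose
p-values are combined by a configurable integration rule (default: all
three below alpha).

The test statistics are computed from first principles here because their
exact arithmetic (hypergeometric enumeration, the pairwise U double sum,
the SS/DF decomposition) is part of the pipeline's contract; scipy supplies
only the reference distributions for p-values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import MultiOmicsCohort, OmicsBlock

logger = logging.getLogger(__name__)

INTEGRATION_RULES = ("all", "majority", "any")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 feature-by-outcome contingency table with cells

    ==============  ==========  ==========
    .               outcome +   outcome -
    feature +       a           b
    feature -       c           d
    ==============  ==========  ==========
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class TestResult:
    feature_id: str
    test_name: str
    statistic: float
    p_value: float
    degenerate: bool = False


# --------------------------------------------------------------------------
# primitive tests
# --------------------------------------------------------------------------


def fisher_exact_p(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p by full hypergeometric enumeration.

    Sums the point probabilities of every table with the observed margins
    whose probability does not exceed that of the observed table.  All
    arithmetic is in exact integers (binomial-coefficient numerators over a
    common denominator), so the comparison involves no floating-point
    tolerance.
    """
    if table.n == 0:
        logger.warning("fisher_exact_p: empty table, returning p = 1")
        return 1.0
    r1, r2 = table.a + table.b, table.c + table.d
    k = table.a + table.c
    lo, hi = max(0, k - r2), min(r1, k)
    num_obs = math.comb(r1, table.a) * math.comb(r2, table.c)
    total = math.comb(table.n, k)
    acc = 0
    for x in range(lo, hi + 1):
        w = math.comb(r1, x) * math.comb(r2, k - x)
        if w <= num_obs:
            acc += w
    return acc / total


def _chi2_stat(observed: np.ndarray) -> tuple[float, int]:
    """Pearson statistic sum((x - n p)^2 / (n p)) with expected cell
    probabilities from the margins; returns (statistic, df)."""
    observed = np.asarray(observed, dtype=float)
    n = observed.sum()
    rows = observed.sum(axis=1, keepdims=True)
    cols = observed.sum(axis=0, keepdims=True)
    expected = rows @ cols / n
    if np.any(expected == 0):
        raise ValueError(
            "chi-square undefined: zero expected cell; use Fisher's exact test"
        )
    stat = float(((observed - expected) ** 2 / expected).sum())
    df = (observed.shape[0] - 1) * (observed.shape[1] - 1)
    return stat, df


def chi_square_p(table: ContingencyTable2x2) -> tuple[float, float]:
    """Pearson chi-square statistic and p (1 df, no continuity correction)."""
    if table.n == 0:
        raise ValueError("chi-square undefined on an empty table")
    observed = np.array([[table.a, table.b], [table.c, table.d]], dtype=float)
    stat, df = _chi2_stat(observed)
    return stat, float(stats.chi2.sf(stat, df))


def student_t(x1, x2, feature_id: str = "") -> TestResult:
    """Two-sample pooled-variance t test.

    t = (mean1 - mean2) / (s_p * sqrt(1/n1 + 1/n2)) with the pooled SD
    s_p^2 = ((n1-1) s1^2 + (n2-1) s2^2) / (n1 + n2 - 2); two-sided p from
    the t distribution with n1 + n2 - 2 df.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    n1, n2 = len(x1), len(x2)
    if n1 < 2 or n2 < 2:
        raise ValueError("student_t requires at least 2 values per sample")
    sp2 = ((n1 - 1) * x1.var(ddof=1) + (n2 - 1) * x2.var(ddof=1)) / (n1 + n2 - 2)
    delta = x1.mean() - x2.mean()
    if sp2 == 0.0:
        if delta == 0.0:
            return TestResult(feature_id, "t", 0.0, 1.0, degenerate=True)
        return TestResult(
            feature_id, "t", math.copysign(math.inf, delta), 0.0, degenerate=True
        )
    t = delta / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * float(stats.t.sf(abs(t), n1 + n2 - 2))
    return TestResult(feature_id, "t", t, p)


def _tie_correction(pooled: np.ndarray) -> float:
    """sum(t^3 - t) over groups of tied values in the pooled sample."""
    _, counts = np.unique(pooled, return_counts=True)
    return float((counts**3 - counts).sum())


def mann_whitney_u(x, y, feature_id: str = "") -> TestResult:
    """Mann-Whitney U by the pairwise double sum with ties scored 0.5.

    U = sum_i sum_j S(x_i, y_j) where S is 1 if y < x, 0.5 on a tie, 0
    otherwise.  Two-sided p from the tie-corrected normal approximation
    (no continuity correction).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("mann_whitney_u requires non-empty samples")
    gt = x[:, None] > y[None, :]
    eq = x[:, None] == y[None, :]
    u = float(gt.sum() + 0.5 * eq.sum())
    pooled = np.concatenate([x, y])
    big_n = n + m
    ties = _tie_correction(pooled)
    var = n * m / 12.0 * ((big_n + 1) - ties / (big_n * (big_n - 1)))
    if var <= 0:
        return TestResult(feature_id, "mannwhitney", u, 1.0, degenerate=True)
    z = (u - n * m / 2.0) / math.sqrt(var)
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return TestResult(feature_id, "mannwhitney", u, min(p, 1.0))


def anova_f(groups, feature_id: str = "") -> TestResult:
    """One-way ANOVA F from the SS/DF decomposition.

    SS_total = SS_treatment + SS_error; F = MS_treatment / MS_error with
    MS = SS / DF; p from the F distribution.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("anova_f requires >= 2 non-empty groups")
    n_total = sum(len(g) for g in groups)
    df_treat = len(groups) - 1
    df_error = n_total - len(groups)
    if df_error < 1:
        raise ValueError("anova_f requires total error df >= 1")
    grand = np.concatenate(groups).mean()
    ss_treat = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_error = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ss_error == 0.0:
        if ss_treat == 0.0:
            return TestResult(feature_id, "anova", 0.0, 1.0, degenerate=True)
        return TestResult(feature_id, "anova", math.inf, 0.0, degenerate=True)
    f = (ss_treat / df_treat) / (ss_error / df_error)
    p = float(stats.f.sf(f, df_treat, df_error))
    return TestResult(feature_id, "anova", f, p)


# --------------------------------------------------------------------------
# vectorised two-group tests (used by select_continuous; equal to the
# scalar primitives above, asserted by the test suite)
# --------------------------------------------------------------------------


def _two_group_tests_matrix(x0: np.ndarray, x1: np.ndarray) -> pd.DataFrame:
    """t, U and F tests for every column of two class matrices.

    Returns a frame with columns t_stat, t_p, u_stat, u_p, f_stat, f_p.
    Degenerate columns (zero within- and between-class variance) get p = 1.
    """
    n0, n1 = x0.shape[0], x1.shape[0]
    m0, m1 = x0.mean(axis=0), x1.mean(axis=0)
    v0, v1 = x0.var(axis=0, ddof=1), x1.var(axis=0, ddof=1)
    delta = m1 - m0

    # pooled t
    sp2 = ((n0 - 1) * v0 + (n1 - 1) * v1) / (n0 + n1 - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / np.sqrt(sp2 * (1.0 / n0 + 1.0 / n1))
    t_p = 2.0 * stats.t.sf(np.abs(t), n0 + n1 - 2)
    zero_sp = sp2 == 0
    t = np.where(zero_sp, np.where(delta == 0, 0.0, np.inf * np.sign(delta)), t)
    t_p = np.where(zero_sp, np.where(delta == 0, 1.0, 0.0), t_p)

    # Mann-Whitney via average ranks (equivalent to the pairwise sum)
    pooled = np.vstack([x1, x0])
    ranks = stats.rankdata(pooled, axis=0)
    r1 = ranks[:n1].sum(axis=0)
    u = r1 - n1 * (n1 + 1) / 2.0
    big_n = n0 + n1
    ties = np.empty(pooled.shape[1])
    for j in range(pooled.shape[1]):
        _, counts = np.unique(pooled[:, j], return_counts=True)
        ties[j] = (counts**3 - counts).sum()
    var_u = n0 * n1 / 12.0 * ((big_n + 1) - ties / (big_n * (big_n - 1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (u - n0 * n1 / 2.0) / np.sqrt(var_u)
    u_p = np.where(var_u > 0, np.minimum(2.0 * stats.norm.sf(np.abs(z)), 1.0), 1.0)

    # one-way ANOVA, two groups
    grand = (n0 * m0 + n1 * m1) / big_n
    ss_treat = n0 * (m0 - grand) ** 2 + n1 * (m1 - grand) ** 2
    ss_error = (n0 - 1) * v0 + (n1 - 1) * v1
    df_error = big_n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_treat / 1.0) / (ss_error / df_error)
    f_p = stats.f.sf(f, 1, df_error)
    zero_err = ss_error == 0
    f = np.where(zero_err, np.where(ss_treat == 0, 0.0, np.inf), f)
    f_p = np.where(zero_err, np.where(ss_treat == 0, 1.0, 0.0), f_p)

    return pd.DataFrame(
        {
            "t_stat": t,
            "t_p": t_p,
            "u_stat": u,
            "u_p": u_p,
            "f_stat": f,
            "f_p": f_p,
        }
    )


# --------------------------------------------------------------------------
# block-level selection
# --------------------------------------------------------------------------


@dataclass
class SelectionReport:
    """Per-feature test results and selection decisions across blocks.

    ``frame`` has one row per tested feature with columns ``feature_id``,
    ``block``, ``kind``, the per-test statistics/p-values and a boolean
    ``selected`` column.
    """

    frame: pd.DataFrame
    alpha: float
    rule: str
    discrete_method: str = "auto"
    correction: str | None = None
    extras: dict = field(default_factory=dict)

    def selected_ids(self, block: str | None = None) -> list[str]:
        f = self.frame
        if block is not None:
            f = f[f["block"] == block]
        return f.loc[f["selected"], "feature_id"].tolist()

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, alpha: float, rule: str) -> "SelectionReport":
        return cls(pd.read_csv(path), alpha=alpha, rule=rule)


def _feature_label_table(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """categories x 2 contingency table of a discrete feature vs labels."""
    cats = np.unique(values)
    table = np.zeros((len(cats), 2), dtype=int)
    for r, cat in enumerate(cats):
        table[r, 0] = int(((values == cat) & (labels == 1)).sum())
        table[r, 1] = int(((values == cat) & (labels == 0)).sum())
    return table


def select_discrete(
    block: OmicsBlock,
    labels: np.ndarray,
    alpha: float = 0.05,
    method: str = "auto",
) -> pd.DataFrame:
    """Screen a discrete block feature-by-feature against the outcome.

    For each feature a feature x label contingency table is built; 2x2
    tables use Fisher's exact test when any expected count is below 5
    (``method="auto"``), the chi-square test otherwise.  ``method`` can
    force either test.  Constant features are degenerate (p = 1).
    """
    if block.kind != "discrete":
        raise ValueError("select_discrete requires a discrete block")
    if method not in ("auto", "fisher", "chi2"):
        raise ValueError(f"unknown method {method!r}")
    labels = np.asarray(labels)
    rows = []
    for fid in block.feature_ids:
        values = block.values[fid].to_numpy()
        table = _feature_label_table(values, labels)
        if table.shape[0] < 2:
            rows.append((fid, block.name, "degenerate", np.nan, 1.0, False))
            continue
        if table.shape[0] == 2:
            ct = ContingencyTable2x2(*table.ravel().tolist())
            n = ct.n
            expected_min = (
                min(ct.a + ct.b, ct.c + ct.d) * min(ct.a + ct.c, ct.b + ct.d) / n
            )
            use_fisher = method == "fisher" or (method == "auto" and expected_min < 5)
            if use_fisher:
                p = fisher_exact_p(ct)
                rows.append((fid, block.name, "fisher", np.nan, p, p < alpha))
            else:
                stat, p = chi_square_p(ct)
                rows.append((fid, block.name, "chi2", stat, p, p < alpha))
        else:
            stat, df = _chi2_stat(table)
            p = float(stats.chi2.sf(stat, df))
            rows.append((fid, block.name, "chi2", stat, p, p < alpha))
    return pd.DataFrame(
        rows,
        columns=["feature_id", "block", "test_name", "statistic", "p_value", "selected"],
    ).assign(kind="discrete")


def _apply_rule(pvals: pd.DataFrame, alpha: float, rule: str) -> np.ndarray:
    below = (pvals < alpha).to_numpy()
    if rule == "all":
        return below.all(axis=1)
    if rule == "majority":
        return below.sum(axis=1) >= (below.shape[1] // 2 + 1)
    if rule == "any":
        return below.any(axis=1)
    raise ValueError(f"unknown integration rule {rule!r}")


def select_continuous(
    block: OmicsBlock,
    labels: np.ndarray,
    alpha: float = 0.05,
    rule: str = "all",
    correction: str | None = None,
) -> pd.DataFrame:
    """Screen a continuous block with the integrated t / U / ANOVA battery.

    The block is split by outcome; each feature is tested with all three
    two-sample tests and kept according to *rule* (``"all"``: every p
    below alpha; ``"majority"``; ``"any"``).  ``correction="bh"`` applies a
    Benjamini-Hochberg adjustment per test across the block's features
    before the rule is evaluated.
    """
    if block.kind != "continuous":
        raise ValueError("select_continuous requires a continuous block")
    if rule not in INTEGRATION_RULES:
        raise ValueError(f"unknown integration rule {rule!r}")
    labels = np.asarray(labels)
    x0 = block.values.to_numpy()[labels == 0]
    x1 = block.values.to_numpy()[labels == 1]
    if len(x0) < 2 or len(x1) < 2:
        raise ValueError("each class needs at least 2 samples for continuous tests")
    res = _two_group_tests_matrix(x0, x1)
    res.insert(0, "feature_id", block.feature_ids)
    res.insert(1, "block", block.name)
    pcols = ["t_p", "u_p", "f_p"]
    pvals = res[pcols]
    if correction == "bh":
        pvals = pvals.apply(
            lambda col: stats.false_discovery_control(col, method="bh"), axis=0
        )
        for c in pcols:
            res[c + "_adj"] = pvals[c]
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    res["selected"] = _apply_rule(pvals, alpha, rule)
    res["kind"] = "continuous"
    return res


def select_features(
    cohort: MultiOmicsCohort,
    alpha: float = 0.05,
    rule: str = "all",
    discrete_method: str = "auto",
    correction: str | None = None,
) -> SelectionReport:
    """Run the full per-block selection over a labelled cohort."""
    if not cohort.labelled_mask().all():
        raise ValueError("cohort contains missing labels; run filter_labelled first")
    frames = []
    for block in cohort.blocks:
        if block.kind == "discrete":
            frames.append(
                select_discrete(block, cohort.labels, alpha, method=discrete_method)
            )
        else:
            frames.append(
                select_continuous(
                    block, cohort.labels, alpha, rule=rule, correction=correction
                )
            )
    frame = pd.concat(frames, ignore_index=True)
    return SelectionReport(
        frame,
        alpha=alpha,
        rule=rule,
        discrete_method=discrete_method,
        correction=correction,
    )
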