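"""Primitive statistical tests against independent oracles, and the
block-level selection contracts."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import omicsboost as ob
from omicsboost.selection import _two_group_tests_matrix

# --------------------------------------------------------------------------
# Fisher's exact test
# --------------------------------------------------------------------------


def _fisher_oracle_class(r1, r2, k):
    """Exact two-sided Fisher p for every table in a margin class, via the
    factorial point-mass formula and Fraction arithmetic (independent of
    the implementation's binomial-coefficient route)."""
    n = r1 + r2
    lo, hi = max(0, k - r2), min(r1, k)
    masses = {}
    for a in range(lo, hi + 1):
        b, c = r1 - a, k - a
        d = r2 - c
        masses[a] = Fraction(
            math.factorial(r1) * math.factorial(r2)
            * math.factorial(k) * math.factorial(n - k),
            math.factorial(a) * math.factorial(b) * math.factorial(c)
            * math.factorial(d) * math.factorial(n),
        )
    order = sorted(masses, key=masses.get)
    prefix, acc = {}, Fraction(0)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and masses[order[j + 1]] == masses[order[i]]:
            j += 1
        acc += sum(masses[order[t]] for t in range(i, j + 1))
        for t in range(i, j + 1):
            prefix[order[t]] = acc
        i = j + 1
    return {a: float(prefix[a]) for a in masses}


def test_fisher_matches_enumeration_oracle_small_n():
    """Every 2x2 table with n <= 25 agrees with the Fraction oracle to 1e-12
    (the full n <= 40 sweep runs in the acceptance suite)."""
    for n in range(1, 26):
        for r1 in range(n + 1):
            for k in range(n + 1):
                oracle = _fisher_oracle_class(r1, n - r1, k)
                for a, expected in oracle.items():
                    t = ob.ContingencyTable2x2(a, r1 - a, k - a, (n - r1) - (k - a))
                    assert abs(ob.fisher_exact_p(t) - expected) < 1e-12


def test_fisher_identical_rows_gives_one():
    assert ob.fisher_exact_p(ob.ContingencyTable2x2(4, 7, 4, 7)) == pytest.approx(1.0)


def test_fisher_five_zero_table_by_enumeration():
    # margins (5,5|5,5): 6 tables; p(observed extreme) = 2 / C(10,5)
    p = ob.fisher_exact_p(ob.ContingencyTable2x2(5, 0, 0, 5))
    assert p == pytest.approx(2 / math.comb(10, 5), abs=1e-15)


def test_fisher_empty_table_degenerate(caplog):
    with caplog.at_level("WARNING"):
        assert ob.fisher_exact_p(ob.ContingencyTable2x2(0, 0, 0, 0)) == 1.0


@settings(deadline=None, derandomize=True, max_examples=200)
@given(st.tuples(*[st.integers(0, 30)] * 4))
def test_fisher_transpose_symmetry_and_range(cells):
    a, b, c, d = cells
    p = ob.fisher_exact_p(ob.ContingencyTable2x2(a, b, c, d))
    pt = ob.fisher_exact_p(ob.ContingencyTable2x2(a, c, b, d))
    assert 0.0 <= p <= 1.0
    assert p == pytest.approx(pt, abs=1e-12)


# --------------------------------------------------------------------------
# chi-square
# --------------------------------------------------------------------------


def test_chi2_zero_when_observed_equals_expected():
    stat, p = ob.chi_square_p(ob.ContingencyTable2x2(10, 10, 10, 10))
    assert stat == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_chi2_matches_ad_bc_textbook_form():
    a, b, c, d = 10, 20, 30, 40
    n = a + b + c + d
    expected = n * (a * d - b * c) ** 2 / (
        (a + b) * (c + d) * (a + c) * (b + d)
    )
    stat, _ = ob.chi_square_p(ob.ContingencyTable2x2(a, b, c, d))
    assert stat == pytest.approx(expected, rel=1e-12)


def test_chi2_homogeneous_in_counts():
    s1, _ = ob.chi_square_p(ob.ContingencyTable2x2(10, 20, 30, 40))
    s2, _ = ob.chi_square_p(ob.ContingencyTable2x2(20, 40, 60, 80))
    assert s2 == pytest.approx(2 * s1, rel=1e-12)


def test_chi2_zero_expected_cell_directs_to_fisher():
    with pytest.raises(ValueError, match="Fisher"):
        ob.chi_square_p(ob.ContingencyTable2x2(0, 0, 5, 5))


# --------------------------------------------------------------------------
# Student t
# --------------------------------------------------------------------------


def test_t_identical_samples():
    r = ob.student_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert r.statistic == pytest.approx(0.0)
    assert r.p_value == pytest.approx(1.0)


def test_t_hand_arithmetic():
    # direct substitution: means 2 and 5, s1^2 = s2^2 = 1,
    # sp = sqrt((2*1 + 2*1)/4) = 1, t = -3 / sqrt(1/3 + 1/3)
    r = ob.student_t([1, 2, 3], [4, 5, 6])
    assert r.statistic == pytest.approx(-3 / math.sqrt(2 / 3), rel=1e-12)


def test_t_antisymmetric_in_samples(rng):
    x, y = rng.normal(size=9), rng.normal(size=12)
    r1, r2 = ob.student_t(x, y), ob.student_t(y, x)
    assert r1.statistic == pytest.approx(-r2.statistic, rel=1e-12)
    assert r1.p_value == pytest.approx(r2.p_value, rel=1e-12)


def test_t_degenerate_zero_variance():
    r = ob.student_t([2.0, 2.0], [5.0, 5.0])
    assert r.degenerate and r.p_value == 0.0
    with pytest.raises(ValueError):
        ob.student_t([1.0], [2.0, 3.0])


# --------------------------------------------------------------------------
# Mann-Whitney U
# --------------------------------------------------------------------------


def _u_brute_force(x, y):
    u = 0.0
    for xi in x:
        for yj in y:
            u += 1.0 if yj < xi else (0.5 if yj == xi else 0.0)
    return u


def test_u_complete_separation():
    r = ob.mann_whitney_u([10, 11, 12], [1, 2])
    assert r.statistic == 6.0  # n * m


def test_u_identical_multisets_all_ties():
    r = ob.mann_whitney_u([1, 2, 2, 3], [1, 2, 2, 3])
    assert r.statistic == pytest.approx(16 / 2)
    assert r.p_value == pytest.approx(1.0)


@pytest.mark.parametrize("seed", range(5))
def test_u_matches_brute_force_double_sum(seed):
    rng = np.random.default_rng(seed)
    # mixed continuous + tied integer values
    x = np.round(rng.normal(size=8), 1)
    y = np.round(rng.normal(size=8), 1)
    r = ob.mann_whitney_u(x, y)
    assert r.statistic == pytest.approx(_u_brute_force(x, y), abs=1e-12)


def test_u_constant_pooled_sample_degenerate():
    r = ob.mann_whitney_u([3, 3, 3], [3, 3])
    assert r.degenerate and r.p_value == 1.0


# --------------------------------------------------------------------------
# ANOVA
# --------------------------------------------------------------------------


def test_anova_degenerate_all_constant():
    r = ob.anova_f([[2, 2, 2], [2, 2, 2]])
    assert r.degenerate and r.statistic == 0.0


@pytest.mark.parametrize("seed", range(5))
def test_anova_two_groups_equals_t_squared(seed):
    rng = np.random.default_rng(100 + seed)
    x, y = rng.normal(size=10), rng.normal(1.0, 1.0, size=14)
    f = ob.anova_f([x, y])
    t = ob.student_t(x, y)
    assert f.statistic == pytest.approx(t.statistic**2, rel=1e-10)
    assert f.p_value == pytest.approx(t.p_value, rel=1e-10)


def test_anova_ss_decomposition(rng):
    groups = [rng.normal(size=7), rng.normal(size=5), rng.normal(2, 1, size=6)]
    allv = np.concatenate(groups)
    ss_total = ((allv - allv.mean()) ** 2).sum()
    grand = allv.mean()
    ss_treat = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_error = sum(((g - g.mean()) ** 2).sum() for g in groups)
    assert ss_total == pytest.approx(ss_treat + ss_error, rel=1e-12)
    # and F reproduces the decomposition arithmetic
    r = ob.anova_f(groups)
    assert r.statistic == pytest.approx(
        (ss_treat / 2) / (ss_error / (len(allv) - 3)), rel=1e-12
    )


# --------------------------------------------------------------------------
# block-level selection
# --------------------------------------------------------------------------


def test_vectorised_tests_match_scalar_primitives(rng):
    x0 = np.round(rng.normal(size=(20, 15)), 1)  # rounding induces ties
    x1 = np.round(rng.normal(0.5, 1.2, size=(25, 15)), 1)
    res = _two_group_tests_matrix(x0, x1)
    for j in range(15):
        t = ob.student_t(x1[:, j], x0[:, j])
        u = ob.mann_whitney_u(x1[:, j], x0[:, j])
        f = ob.anova_f([x0[:, j], x1[:, j]])
        assert res["t_stat"][j] == pytest.approx(t.statistic, rel=1e-10)
        assert res["t_p"][j] == pytest.approx(t.p_value, rel=1e-10)
        assert res["u_stat"][j] == pytest.approx(u.statistic, abs=1e-9)
        assert res["u_p"][j] == pytest.approx(u.p_value, rel=1e-9)
        assert res["f_stat"][j] == pytest.approx(f.statistic, rel=1e-10)
        assert res["f_p"][j] == pytest.approx(f.p_value, rel=1e-10)


def _block_from_matrix(name, kind, X):
    import pandas as pd

    df = pd.DataFrame(X, columns=[f"{name}_f{j}" for j in range(X.shape[1])])
    return ob.OmicsBlock(name, kind, df)


def test_select_discrete_perfect_association_and_constant(rng):
    labels = np.repeat([0, 1], 30)
    perfect = labels.copy()
    constant = np.ones(60, dtype=int)
    noise = rng.integers(0, 2, size=60)
    X = np.column_stack([perfect, constant, noise])
    frag = ob.select_discrete(_block_from_matrix("d", "discrete", X), labels)
    assert frag.loc[0, "selected"] and frag.loc[0, "p_value"] < 1e-10
    assert not frag.loc[1, "selected"] and frag.loc[1, "p_value"] == 1.0


def test_select_discrete_zero_features():
    frag = ob.select_discrete(
        _block_from_matrix("d", "discrete", np.empty((10, 0), dtype=int)),
        np.repeat([0, 1], 5),
    )
    assert len(frag) == 0


def test_select_discrete_switches_to_fisher_for_small_expected():
    labels = np.repeat([0, 1], [56, 8])
    feat = np.zeros(64, dtype=int)
    feat[-4:] = 1  # expected count for (feature=1, label=1) well below 5
    frag = ob.select_discrete(_block_from_matrix("d", "discrete", feat[:, None]), labels)
    assert frag.loc[0, "test_name"] == "fisher"
    frag2 = ob.select_discrete(
        _block_from_matrix("d", "discrete", feat[:, None]), labels, method="chi2"
    )
    assert frag2.loc[0, "test_name"] == "chi2"


def test_select_continuous_shift_invariance(rng):
    labels = np.repeat([0, 1], [25, 25])
    base = rng.normal(size=50)
    X = np.column_stack([base, base + 100.0])
    frag = ob.select_continuous(
        _block_from_matrix("c", "continuous", X), labels, alpha=0.5
    )
    # a feature plus a constant offset: identical statistics and decision
    assert frag.loc[0, "t_p"] == pytest.approx(frag.loc[1, "t_p"], rel=1e-9)
    assert frag.loc[0, "u_stat"] == frag.loc[1, "u_stat"]
    assert frag.loc[0, "selected"] == frag.loc[1, "selected"]


def test_select_continuous_requires_two_per_class(rng):
    labels = np.array([0, 1, 1, 1])
    X = rng.normal(size=(4, 3))
    with pytest.raises(ValueError, match="at least 2"):
        ob.select_continuous(_block_from_matrix("c", "continuous", X), labels)


@pytest.mark.parametrize("rule,expected", [("all", 1), ("majority", 1), ("any", 2)])
def test_integration_rules_nest(rule, expected, rng):
    # feature 0: strong signal passes all tests; feature 1 carries a clear
    # location shift plus one huge outlier that cancels the mean difference
    # and inflates the variance, silencing t and F while the rank test
    # still fires -- so only the "any" rule picks it up
    labels = np.repeat([0, 1], [40, 40])
    strong = np.where(labels == 1, 2.0, 0.0) + rng.normal(size=80) * 0.5
    weak = rng.normal(size=80)
    weak[labels == 1] += 0.9
    weak[-1] -= 50
    X = np.column_stack([strong, weak])
    frag = ob.select_continuous(
        _block_from_matrix("c", "continuous", X), labels, alpha=0.01, rule=rule
    )
    assert int(frag["selected"].sum()) == expected


def test_bh_correction_is_more_conservative(default_cohort):
    block = default_cohort.block("proteomics")
    plain = ob.select_continuous(block, default_cohort.labels, correction=None)
    bh = ob.select_continuous(block, default_cohort.labels, correction="bh")
    assert set(bh.loc[bh["selected"], "feature_id"]) <= set(
        plain.loc[plain["selected"], "feature_id"]
    )


def test_select_features_report_structure(default_cohort, default_selection):
    frame = default_selection.frame
    assert set(frame["block"]) == {b.name for b in default_cohort.blocks}
    total = sum(len(b.feature_ids) for b in default_cohort.blocks)
    assert len(frame) == total
    assert frame.loc[frame["selected"]].shape[0] > 0
    # every selected continuous feature satisfies the integration rule
    cont = frame[(frame["kind"] == "continuous") & frame["selected"]]
    assert (cont[["t_p", "u_p", "f_p"]] < default_selection.alpha).all().all()


def test_select_features_rejects_missing_labels():
    c = ob.generate_cohort(
        ob.CohortConfig(
            n_samples=30, class_balance=0.5,
            blocks=(ob.BlockSpec("p", "continuous", 5, 1),),
            label_missing_count=1, seed=0,
        )
    )
    with pytest.raises(ValueError, match="missing labels"):
        ob.select_features(c)
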