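"""Statistical kernel: exact tests against enumeration oracles, odds-ratio
conventions against published contingency tables, CMH and inflation checks."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from qvburden.stats import (AssociationResult, ContingencyTable2x2,
                            SeparationError, cmh_test, conditional_exact_ci,
                            fisher_exact_two_sided, lambda_gc, linear_assoc,
                            logistic_covar_assoc, nof1_permutation,
                            odds_ratio_ci, permute_labels)


def fisher_enumeration_oracle(a, b, c, d):
    """Exact-rational full enumeration of the two-sided Fisher p-value
    (point-probability criterion), independent of scipy."""
    r1, c1, n = a + b, a + c, a + b + c + d
    def pmf(k):
        return Fraction(math.comb(r1, k) * math.comb(n - r1, c1 - k),
                        math.comb(n, c1))
    p_obs = pmf(a)
    total = Fraction(0)
    for k in range(max(0, c1 - (n - r1)), min(r1, c1) + 1):
        if pmf(k) <= p_obs:
            total += pmf(k)
    return float(total)


def test_fisher_matches_enumeration_on_random_small_tables():
    rng = np.random.default_rng(2024)
    checked = 0
    while checked < 1200:
        n = int(rng.integers(4, 41))
        cells = rng.multinomial(n, rng.dirichlet(np.ones(4)))
        a, b, c, d = (int(x) for x in cells)
        if min(a + b, c + d, a + c, b + d) == 0:
            continue
        t = ContingencyTable2x2(a, b, c, d)
        assert fisher_exact_two_sided(t) == pytest.approx(
            fisher_enumeration_oracle(a, b, c, d), rel=1e-9)
        checked += 1


@settings(deadline=None, derandomize=True, max_examples=200)
@given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30),
       st.integers(0, 30))
def test_fisher_symmetries(a, b, c, d):
    """The exact p is invariant under swapping rows (case/control exchange)
    and under transposing the table (carrier/status exchange)."""
    p = fisher_exact_two_sided(ContingencyTable2x2(a, b, c, d))
    assert fisher_exact_two_sided(ContingencyTable2x2(c, d, a, b)) == \
        pytest.approx(p, rel=1e-12)
    assert fisher_exact_two_sided(ContingencyTable2x2(a, c, b, d)) == \
        pytest.approx(p, rel=1e-12)
    assert 0 < p <= 1


def test_fisher_degenerate_and_proportional_tables():
    assert fisher_exact_two_sided(ContingencyTable2x2(0, 10, 0, 20)) == 1.0
    assert fisher_exact_two_sided(ContingencyTable2x2(1, 9, 10, 90)) == pytest.approx(1.0)
    # full-enumeration value for (3,7,0,10): 240/1140
    assert fisher_exact_two_sided(ContingencyTable2x2(3, 7, 0, 10)) == pytest.approx(
        240 / 1140, rel=1e-9)


@pytest.mark.parametrize(
    "table, p_2sf, or_1dp, ci_1dp",
    [
        # gene-level carrier table: 54/7,276 cases vs 634/236,741 controls
        ((54, 7222, 634, 236107), 2.4e-10, 2.8, (2.1, 3.7)),
        # single-variant dominant table: 21/7,274 vs 116/236,659
        ((21, 7253, 116, 236543), 9.3e-10, 5.9, (3.7, 9.4)),
        # protein-truncating burden: 10 case vs 2 control carriers
        ((10, 7266, 2, 236739), 3.5e-14, 162.9, (35.7, 743.7)),
    ],
)
def test_published_tables_reproduce(table, p_2sf, or_1dp, ci_1dp):
    t = ContingencyTable2x2(*table)
    p = fisher_exact_two_sided(t)
    assert float(f"{p:.1e}") == pytest.approx(p_2sf, rel=1e-9)
    or_, lo, hi = odds_ratio_ci(t)
    assert round(or_, 1) == pytest.approx(or_1dp)
    assert (round(lo, 1), round(hi, 1)) == pytest.approx(ci_1dp)


def test_odds_ratio_haldane_correction_on_zero_cell():
    or_, lo, hi = odds_ratio_ci(ContingencyTable2x2(3, 7, 0, 10))
    assert or_ == pytest.approx((3.5 * 10.5) / (7.5 * 0.5))
    assert lo < or_ < hi


def test_odds_ratio_ci_ordering_holds_for_positive_cells():
    rng = np.random.default_rng(7)
    for _ in range(50):
        t = ContingencyTable2x2(*(int(x) for x in rng.integers(1, 200, 4)))
        or_, lo, hi = odds_ratio_ci(t)
        assert lo <= or_ <= hi


def test_conditional_exact_ci_is_distinct_convention():
    # sparse-table cross-check: conditional-MLE interval is wider below
    or_w, lo_w, _ = odds_ratio_ci(ContingencyTable2x2(33, 7222, 518, 236107))
    or_c, lo_c, _ = conditional_exact_ci(ContingencyTable2x2(33, 7222, 518, 236107))
    assert lo_c < lo_w
    assert or_c == pytest.approx(or_w, rel=0.01)


def test_cmh_single_stratum_matches_plain_table():
    t = ContingencyTable2x2(54, 7222, 634, 236107)
    p, common_or = cmh_test([t])
    assert common_or == pytest.approx(odds_ratio_ci(t)[0])
    chi2 = sps.chi2_contingency(t.as_array(), correction=False)
    # CMH uses the hypergeometric variance (factor n/(n-1)); huge n -> equal
    assert p == pytest.approx(chi2.pvalue, rel=1e-3)


def test_cmh_duplicated_stratum_increases_evidence():
    t = ContingencyTable2x2(54, 7222, 634, 236107)
    p1, or1 = cmh_test([t])
    p2, or2 = cmh_test([t, t])
    assert or2 == pytest.approx(or1)
    assert p2 < p1


def test_cmh_null_strata_formula_oracle():
    strata = [ContingencyTable2x2(10, 90, 10, 90), ContingencyTable2x2(5, 95, 5, 95)]
    p, common_or = cmh_test(strata)
    assert common_or == pytest.approx(1.0)
    assert p == pytest.approx(1.0)
    # hand CMH on unbalanced toy strata
    strata = [ContingencyTable2x2(12, 38, 5, 45), ContingencyTable2x2(8, 12, 2, 18)]
    num = sum(t.a - (t.a + t.b) * (t.a + t.c) / t.total for t in strata)
    var = sum((t.a + t.b) * (t.c + t.d) * (t.a + t.c) * (t.b + t.d)
              / (t.total ** 2 * (t.total - 1)) for t in strata)
    p_hand = sps.chi2.sf(num ** 2 / var, 1)
    p_impl, _ = cmh_test(strata)
    assert p_impl == pytest.approx(p_hand, rel=1e-9)


def test_lambda_gc_definition_and_quantile_identity():
    assert lambda_gc([0.5] * 10) == pytest.approx(1.0)
    n = 10_001
    grid = (np.arange(1, n + 1) - 0.5) / n
    assert lambda_gc(grid) == pytest.approx(1.0, abs=1e-3)
    # p-values from a chi-square inflated exactly 2x at the median
    null_median = sps.chi2.isf(0.5, 1)
    p2 = sps.chi2.sf([2 * null_median], 1)
    assert lambda_gc(p2) == pytest.approx(2.0)


def test_lambda_gc_invariances():
    rng = np.random.default_rng(0)
    p = rng.uniform(0.01, 1, 501)
    assert lambda_gc(p) == pytest.approx(lambda_gc(rng.permutation(p)))
    assert lambda_gc(p * 0.5) > lambda_gc(p)
    with pytest.raises(ValueError):
        lambda_gc([])


def test_linear_assoc_exact_fit_and_degenerate():
    rng = np.random.default_rng(1)
    x = rng.normal(size=100)
    res = linear_assoc(2.0 * x, x)
    assert res.beta == pytest.approx(2.0)
    assert res.p < 1e-30
    with pytest.raises(ValueError, match="x"):
        linear_assoc(rng.normal(size=50), np.ones(50))


def test_linear_assoc_null_p_uniform():
    rng = np.random.default_rng(11)
    ps = []
    for _ in range(400):
        y = rng.normal(size=60)
        x = rng.normal(size=60)
        ps.append(linear_assoc(y, x).p)
    assert sps.kstest(ps, "uniform").pvalue > 0.001


def test_logistic_null_power_and_separation():
    rng = np.random.default_rng(5)
    ps = []
    for _ in range(150):
        y = rng.integers(0, 2, 400)
        x = (rng.random(400) < 0.3).astype(float)
        ps.append(logistic_covar_assoc(y, x).p)
    assert sps.kstest(ps, "uniform").pvalue > 0.001

    hits = 0
    reps = 40
    for _ in range(reps):
        n = 10_000
        x = (rng.random(n) < 0.05).astype(float)
        logit = -1.0 + math.log(5.0) * x
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
        if logistic_covar_assoc(y, x).p < 0.05:
            hits += 1
    assert hits >= 0.95 * reps

    y = np.array([1, 1, 1, 0, 0, 0])
    x = np.array([1, 1, 1, 0, 0, 0])
    with pytest.raises(SeparationError):
        logistic_covar_assoc(y, x)


def test_nof1_permutation_conserves_cases_and_is_seeded():
    labels = np.array([True] * 30 + [False] * 70)
    p1 = permute_labels(labels, 9)
    p2 = permute_labels(labels, 9)
    assert p1.sum() == 30
    assert np.array_equal(p1, p2)
    assert not np.array_equal(p1, permute_labels(labels, 10))


def test_nof1_null_battery_calibrated():
    rng = np.random.default_rng(3)
    traits = rng.normal(size=(1200, 200))
    labels = np.array([True] * 100 + [False] * 100)

    def battery(lab):
        return [sps.ttest_ind(row[lab], row[~lab]).pvalue for row in traits]

    report = nof1_permutation(labels, battery, seed=17)
    assert report.n_tests == 1200
    assert 0.85 <= report.lambda_gc <= 1.15
    assert 0.85 <= lambda_gc(report.expected_p) <= 1.15
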