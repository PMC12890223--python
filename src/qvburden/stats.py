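"""Shared statistical kernel for case-control association testing.

Every association in the pipeline — variant-level and gene-level — reduces to
a 2x2 carrier-by-status contingency table tested with a two-sided Fisher exact
test (point-probability convention: the p-value sums the probabilities of all
tables, with margins fixed, whose hypergeometric point probability does not
exceed that of the observed table).  Odds ratios are the raw cross-product
estimate with a Woolf (log-scale normal) 95% confidence interval; a
Haldane-Anscombe 0.5 correction is applied to every cell only when some cell
is zero.  Stratified (pan-ancestry / cross-cohort) evidence is combined with
the Cochran-Mantel-Haenszel chi-square test and Mantel-Haenszel common odds
ratio.  Test-statistic calibration is summarised by the genomic inflation
factor lambda_GC and an "n-of-1" permutation of case/control labels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats as sps
from scipy.stats.contingency import odds_ratio as _conditional_odds_ratio
from statsmodels.stats.contingency_tables import StratifiedTable

logger = logging.getLogger(__name__)

#: Median of the chi-square(1 df) distribution; the null expectation of the
#: median association statistic.
CHI2_NULL_MEDIAN = float(sps.chi2.isf(0.5, 1))  # 0.4549364...

#: Reported p-values are floored here to avoid log-scale underflow.
P_FLOOR = 1e-300

#: z for a two-sided 95% interval.  The conventional two-decimal 1.96 (rather
#: than the exact normal quantile 1.95996...) reproduces published Woolf
#: bounds to the printed precision, e.g. an upper bound of 743.7 for the
#: (10, 7266, 2, 236739) table where 1.95996 gives 743.64.
Z_95 = 1.96


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Carrier/non-carrier by case/control counts.

    ``a`` case carriers, ``b`` case non-carriers, ``c`` control carriers,
    ``d`` control non-carriers.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v}")

    @property
    def n_cases(self) -> int:
        return self.a + self.b

    @property
    def n_controls(self) -> int:
        return self.c + self.d

    @property
    def total(self) -> int:
        return self.n_cases + self.n_controls

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass
class AssociationResult:
    """One association test: p-value, odds ratio with 95% CI, and its table."""

    p: float
    or_: float
    ci_low: float
    ci_high: float
    table: ContingencyTable2x2
    model: str
    target: str

    def to_record(self) -> dict:
        t = self.table
        return {
            "target": self.target,
            "model": self.model,
            "p": self.p,
            "or": self.or_,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "a": t.a,
            "b": t.b,
            "c": t.c,
            "d": t.d,
            "n_cases": t.n_cases,
            "n_controls": t.n_controls,
        }


@dataclass
class RegressionResult:
    beta: float
    se: float
    p: float
    n: int


@dataclass
class InflationReport:
    """Genomic-inflation summary: observed lambda_GC plus a permutation null."""

    lambda_gc: float
    n_tests: int
    expected_p: np.ndarray = field(default_factory=lambda: np.array([]))


class SeparationError(ValueError):
    """Raised when a logistic model is not estimable because the carrier
    indicator perfectly (or quasi-perfectly) separates the outcome; an exact
    test should be used instead."""


def fisher_exact_two_sided(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table.

    Uses the point-probability definition of two-sidedness.  A degenerate
    table (any margin zero) carries no information and returns p = 1.
    """
    t = table if isinstance(table, ContingencyTable2x2) else ContingencyTable2x2(*table)
    if min(t.a + t.b, t.c + t.d, t.a + t.c, t.b + t.d) == 0:
        logger.debug("degenerate 2x2 table with a zero margin: %s; p set to 1", t)
        return 1.0
    p = float(sps.fisher_exact(t.as_array(), alternative="two-sided")[1])
    return max(min(p, 1.0), P_FLOOR)


def odds_ratio_ci(
    table: ContingencyTable2x2, z: float = Z_95
) -> tuple[float, float, float]:
    """Cross-product odds ratio with Woolf log-scale confidence interval.

    On tables with a zero cell the Haldane-Anscombe correction (add 0.5 to
    every cell) is applied to both the estimate and the interval.
    """
    t = table if isinstance(table, ContingencyTable2x2) else ContingencyTable2x2(*table)
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    if min(a, b, c, d) == 0.0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(or_)
    return or_, math.exp(log_or - z * se), math.exp(log_or + z * se)


def conditional_exact_ci(
    table: ContingencyTable2x2, confidence_level: float = 0.95
) -> tuple[float, float, float]:
    """Conditional maximum-likelihood odds ratio with exact CI.

    The convention of R's ``fisher.test``; provided as a cross-check on the
    Woolf interval for sparse tables.
    """
    t = table if isinstance(table, ContingencyTable2x2) else ContingencyTable2x2(*table)
    res = _conditional_odds_ratio(t.as_array(), kind="conditional")
    ci = res.confidence_interval(confidence_level=confidence_level)
    return float(res.statistic), float(ci.low), float(ci.high)


def association_test(table: ContingencyTable2x2, model: str, target: str) -> AssociationResult:
    """Convenience: exact p plus Woolf OR/CI in one AssociationResult."""
    p = fisher_exact_two_sided(table)
    or_, lo, hi = odds_ratio_ci(table)
    return AssociationResult(p=p, or_=or_, ci_low=lo, ci_high=hi,
                             table=table, model=model, target=target)


def cmh_test(strata: Sequence[ContingencyTable2x2]) -> tuple[float, float]:
    """Cochran-Mantel-Haenszel test across 2x2 strata.

    Returns the two-sided p-value of the 1-df CMH chi-square statistic
    (no continuity correction) and the Mantel-Haenszel common odds ratio
    sum(a*d/n) / sum(b*c/n).
    """
    tables = [t if isinstance(t, ContingencyTable2x2) else ContingencyTable2x2(*t)
              for t in strata]
    if not tables:
        raise ValueError("cmh_test requires at least one stratum")
    informative = [t for t in tables if t.total > 0]
    if not informative:
        raise ValueError("all strata are empty")
    num = sum(t.a * t.d / t.total for t in informative)
    den = sum(t.b * t.c / t.total for t in informative)
    if num == 0 and den == 0:
        # no carriers anywhere: the strata carry no information
        logger.debug("all strata carrier-free; CMH p set to 1")
        return 1.0, float("nan")
    common_or = math.inf if den == 0 else num / den
    st = StratifiedTable([t.as_array() for t in informative])
    res = st.test_null_odds(correction=False)
    p = float(res.pvalue)
    if math.isnan(p):
        return 1.0, common_or
    return max(min(p, 1.0), P_FLOOR), common_or


def linear_assoc(
    y: np.ndarray, x: np.ndarray, covariates: Optional[np.ndarray] = None
) -> RegressionResult:
    """OLS of a quantitative trait on a predictor with optional covariates.

    Wald t-test on the predictor coefficient.  Raises on a singular design
    (e.g. constant predictor) naming the offending column.
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    cols = [np.ones_like(x), x]
    names = ["intercept", "x"]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] == len(y) and cov.shape[1] != len(y):
            cov = cov.T
        for i, row in enumerate(cov):
            cols.append(row)
            names.append(f"cov{i}")
    design = np.column_stack(cols)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify a collinear column by leave-one-out rank (blame the
        # predictor/covariates before the intercept)
        for j in list(range(1, len(names))) + [0]:
            sub = np.delete(design, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                raise ValueError(
                    f"singular design: column '{names[j]}' is collinear")
        raise ValueError("singular design")
    fit = sm.OLS(y, design).fit()
    return RegressionResult(beta=float(fit.params[1]), se=float(fit.bse[1]),
                            p=float(fit.pvalues[1]), n=len(y))


def logistic_covar_assoc(
    case_status: np.ndarray,
    carrier: np.ndarray,
    covariates: Optional[np.ndarray] = None,
) -> RegressionResult:
    """ML logistic regression of case status on carrier status plus covariates.

    Wald p-value for the carrier coefficient.  Complete or quasi-complete
    separation of a binary carrier indicator (a zero cell in the carrier-by-
    status table) makes the MLE infinite; that raises SeparationError with
    advice to fall back to the exact test.
    """
    import statsmodels.api as sm

    y = np.asarray(case_status, dtype=float)
    x = np.asarray(carrier, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    if set(np.unique(x)) <= {0.0, 1.0}:
        a = int(np.sum((x == 1) & (y == 1)))
        b = int(np.sum((x == 0) & (y == 1)))
        c = int(np.sum((x == 1) & (y == 0)))
        d = int(np.sum((x == 0) & (y == 0)))
        if min(a, b, c, d) == 0 and (a + c) > 0:
            raise SeparationError(
                "carrier status separates the outcome (zero cell in "
                f"table ({a},{b},{c},{d})); use the exact test instead"
            )
    cols = [np.ones_like(x), x]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] == len(y) and cov.shape[1] != len(y):
            cov = cov.T
        cols.extend(list(cov))
    design = np.column_stack(cols)
    try:
        fit = sm.Logit(y, design).fit(disp=0)
    except Exception as exc:  # PerfectSeparation or convergence failure
        raise SeparationError(f"logistic fit failed ({exc}); use the exact test") from exc
    return RegressionResult(beta=float(fit.params[1]), se=float(fit.bse[1]),
                            p=float(fit.pvalues[1]), n=len(y))


def lambda_gc(p_values: Sequence[float]) -> float:
    """Genomic inflation factor: median chi-square(1) quantile of the observed
    p-values divided by the null median 0.4549."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("lambda_gc requires at least one p-value")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi = sps.chi2.isf(p, 1)
    return float(np.median(chi) / CHI2_NULL_MEDIAN)


def permute_labels(labels: np.ndarray, seed: int) -> np.ndarray:
    """One seeded permutation of a boolean case/control label vector; the
    number of cases is conserved exactly."""
    labels = np.asarray(labels, dtype=bool)
    rng = np.random.default_rng(seed)
    return labels[rng.permutation(labels.size)]


def nof1_permutation(
    labels: np.ndarray,
    test_runner: Callable[[np.ndarray], Sequence[float]],
    seed: int,
) -> InflationReport:
    """Single-permutation ("n-of-1") empirical null for a test battery.

    ``test_runner`` maps a case/control label vector to a list of p-values.
    The battery is run on the observed labels (lambda_GC is computed on
    those) and once more on a seeded permutation of the labels, whose
    p-values form the expected/null distribution for QQ comparison.
    """
    observed = np.asarray(test_runner(np.asarray(labels, dtype=bool)), dtype=float)
    permuted = np.asarray(test_runner(permute_labels(labels, seed)), dtype=float)
    return InflationReport(
        lambda_gc=lambda_gc(observed),
        n_tests=observed.size,
        expected_p=np.sort(permuted),
    )
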