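"""Variant- and genotype-call-level quality control.

Two QC profiles are supported, mirroring the two association stages:

* ``exwas`` — variant-level tests: depth >= 10, GQ >= 20, heterozygous
  alternate-read fraction >= 0.20, allele-balance binomial p >= 1e-6,
  QUAL >= 30, FS <= 60 (SNV) / <= 200 (indel), MQ >= 40, RPRS >= -2,
  MQRS >= -8, caller FILTER == PASS, cohort missingness <= 10%, external
  reference coverage (>=10x fraction) >= 0.30 and, when the variant is
  present externally, filtered AC >= 50% of the raw AC.

* ``collapsing`` — gene-level qualifying-variant tests: the same core site
  filters plus CCDS membership, heterozygous alternate fraction within
  [0.25, 0.8], homozygous alternate fraction >= 0.8, external coverage
  >= 0.25 and, when present externally, external RPRS >= -2 and MQ >= 30.

Metrics with missing values pass the corresponding filter.  Calls failing QC
are treated as missing genotypes downstream, never as excluded samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

PROFILES = ("exwas", "collapsing")


@dataclass
class QCOutcome:
    passed: bool
    failed_filters: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.passed != (len(self.failed_filters) == 0):
            raise ValueError("passed flag inconsistent with failed_filters")


@dataclass
class QCThresholds:
    """Numeric thresholds for both profiles; defaults are the study values."""

    min_depth: int = 10
    min_gq: int = 20
    min_het_alt_fraction_exwas: float = 0.20
    het_alt_fraction_band: tuple = (0.25, 0.80)
    min_hom_alt_fraction: float = 0.80
    min_allele_balance_p: float = 1e-6
    min_qual: float = 30.0
    max_fs_snv: float = 60.0
    max_fs_indel: float = 200.0
    min_mq: float = 40.0
    min_rprs: float = -2.0
    min_mqrs: float = -8.0
    max_missingness: float = 0.10
    min_ext_cov10_exwas: float = 0.30
    min_ext_cov10_collapsing: float = 0.25
    min_ext_ac_ratio: float = 0.5
    min_ext_rprs: float = -2.0
    min_ext_mq: float = 30.0
    hwe_midp_min: float = 1e-5
    apply_hwe: bool = False


DEFAULT_THRESHOLDS = QCThresholds()


def allele_balance_test(alt_reads: int, depth: int) -> float:
    """Two-sided exact binomial test of heterozygous allele balance against
    0.5 (point-probability convention)."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if alt_reads > depth or alt_reads < 0:
        raise ValueError("alt_reads must lie in [0, depth]")
    return float(sps.binomtest(int(alt_reads), int(depth), 0.5).pvalue)


def allele_balance_pvalues(alt_reads: np.ndarray, depth: np.ndarray) -> np.ndarray:
    """Vectorized equivalent of :func:`allele_balance_test`.

    For the symmetric null p0 = 0.5 the point-probability two-sided p-value
    reduces to 2 * P(X <= min(k, n-k)), capped at 1.
    """
    k = np.asarray(alt_reads, dtype=np.int64)
    n = np.asarray(depth, dtype=np.int64)
    if np.any(k > n) or np.any(k < 0) or np.any(n < 1):
        raise ValueError("invalid alt_reads/depth")
    m = np.minimum(k, n - k)
    p = 2.0 * sps.binom.cdf(m, n, 0.5)
    return np.minimum(p, 1.0)


def qc_call(genotype: str, gq: float, depth: float, alt_reads: float,
            profile: str, thresholds: QCThresholds = DEFAULT_THRESHOLDS) -> QCOutcome:
    """QC one genotype call.  ``genotype`` is 'het', 'hom-alt', 'hom-ref' or
    'missing'; hom-ref and missing calls are not filtered."""
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}")
    if genotype in ("hom-ref", "missing"):
        return QCOutcome(True, [])
    t = thresholds
    failed = []
    if not (math.isnan(depth) if isinstance(depth, float) else False):
        if depth < t.min_depth:
            failed.append("depth")
    if not (math.isnan(gq) if isinstance(gq, float) else False):
        if gq < t.min_gq:
            failed.append("gq")
    if depth and depth >= 1 and not math.isnan(float(alt_reads)):
        frac = alt_reads / depth
        if genotype == "het":
            if profile == "exwas":
                if frac < t.min_het_alt_fraction_exwas:
                    failed.append("het_alt_fraction")
            else:
                lo, hi = t.het_alt_fraction_band
                if not (lo <= frac <= hi):
                    failed.append("het_alt_fraction")
            if allele_balance_test(int(alt_reads), int(depth)) < t.min_allele_balance_p:
                failed.append("allele_balance")
        elif genotype == "hom-alt" and profile == "collapsing":
            if frac < t.min_hom_alt_fraction:
                failed.append("hom_alt_fraction")
    return QCOutcome(len(failed) == 0, failed)


def apply_call_qc(calls: pd.DataFrame, profile: str,
                  thresholds: QCThresholds = DEFAULT_THRESHOLDS) -> pd.Series:
    """Vectorized call QC over a long-format call table (columns gt, gq, dp,
    alt_reads).  Returns a boolean pass mask aligned to ``calls``; failing
    calls should be treated as missing genotypes."""
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}")
    t = thresholds
    gt = calls["gt"].to_numpy()
    dp = calls["dp"].to_numpy(dtype=float)
    gq = calls["gq"].to_numpy(dtype=float)
    alt = calls["alt_reads"].to_numpy(dtype=float)
    frac = np.divide(alt, dp, out=np.full_like(dp, np.nan), where=dp > 0)

    ok = np.ones(len(calls), dtype=bool)
    ok &= ~(dp < t.min_depth)
    ok &= ~(gq < t.min_gq)
    het = gt == 1
    hom = gt == 2
    if profile == "exwas":
        ok &= ~(het & (frac < t.min_het_alt_fraction_exwas))
    else:
        lo, hi = t.het_alt_fraction_band
        ok &= ~(het & ((frac < lo) | (frac > hi)))
        ok &= ~(hom & (frac < t.min_hom_alt_fraction))
    valid_het = het & (dp >= 1) & np.isfinite(alt)
    if valid_het.any():
        ab = np.ones(len(calls))
        ab[valid_het] = allele_balance_pvalues(alt[valid_het], dp[valid_het])
        ok &= ~(valid_het & (ab < t.min_allele_balance_p))
    return pd.Series(ok, index=calls.index, name="call_pass")


def _fail(mask: np.ndarray, name: str, failed: list[list]) -> None:
    for i in np.flatnonzero(mask):
        failed[i].append(name)


def apply_site_qc(
    variants: pd.DataFrame,
    profile: str,
    missingness: "pd.Series | None" = None,
    thresholds: QCThresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Site-level QC over a variant annotation table.

    Returns a frame indexed like ``variants`` with columns ``site_pass``
    (bool) and ``failed_filters`` (list of filter names).  ``missingness``
    is the per-variant fraction of missing genotypes after call QC (only
    used by the exwas profile).  NaN metric values pass their filter.
    """
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}")
    t = thresholds
    n = len(variants)
    failed: list[list] = [[] for _ in range(n)]

    def col(name, default=np.nan):
        if name in variants.columns:
            return pd.to_numeric(variants[name], errors="coerce").to_numpy(dtype=float)
        return np.full(n, default)

    qual, fs, mq = col("qual"), col("fs"), col("mq")
    rprs, mqrs = col("rprs"), col("mqrs")
    is_indel = variants.get("variant_class", pd.Series(["SNV"] * n)).eq("indel").to_numpy()

    _fail(qual < t.min_qual, "qual", failed)
    fs_cap = np.where(is_indel, t.max_fs_indel, t.max_fs_snv)
    _fail(fs > fs_cap, "fs", failed)
    _fail(mq < t.min_mq, "mq", failed)
    _fail(rprs < t.min_rprs, "rprs", failed)
    _fail(mqrs < t.min_mqrs, "mqrs", failed)
    if "filter_status" in variants.columns:
        _fail(variants["filter_status"].ne("PASS").to_numpy(), "filter_status", failed)

    ext_present = variants.get(
        "ext_present", pd.Series([False] * n, index=variants.index)
    ).fillna(False).to_numpy(dtype=bool)
    ext_cov = col("ext_cov10_frac")
    cov_min = t.min_ext_cov10_exwas if profile == "exwas" else t.min_ext_cov10_collapsing
    _fail(ext_cov < cov_min, "ext_cov10", failed)

    if profile == "exwas":
        if missingness is not None:
            miss = missingness.reindex(variants.index).to_numpy(dtype=float)
            _fail(miss > t.max_missingness, "missingness", failed)
        ext_ac, ext_raw = col("ext_ac"), col("ext_ac_raw")
        bad = ext_present & (ext_ac < t.min_ext_ac_ratio * ext_raw)
        _fail(np.nan_to_num(bad, nan=0).astype(bool), "ext_ac_ratio", failed)
    else:
        if "ccds" in variants.columns:
            in_ccds = variants["ccds"].fillna(True).to_numpy(dtype=bool)
            _fail(~in_ccds, "ccds", failed)
        ext_rprs, ext_mq = col("ext_rprs"), col("ext_mq")
        _fail(ext_present & (ext_rprs < t.min_ext_rprs), "ext_rprs", failed)
        _fail(ext_present & (ext_mq < t.min_ext_mq), "ext_mq", failed)

    return pd.DataFrame(
        {
            "site_pass": [len(f) == 0 for f in failed],
            "failed_filters": failed,
        },
        index=variants.index,
    )


def qc_site(variant: "pd.Series | dict", profile: str,
            missingness: float = np.nan,
            thresholds: QCThresholds = DEFAULT_THRESHOLDS) -> QCOutcome:
    """QC a single site; see :func:`apply_site_qc`."""
    row = pd.DataFrame([dict(variant)])
    miss = pd.Series([missingness], index=row.index)
    res = apply_site_qc(row, profile, missingness=miss, thresholds=thresholds)
    fails = list(res["failed_filters"].iloc[0])
    return QCOutcome(len(fails) == 0, fails)


def exwas_inclusion(n_carriers: int, n_failed_calls: int,
                    min_carriers: int = 6, max_failed_calls: int = 20_000) -> bool:
    """Variant-level inclusion gate: at least ``min_carriers`` samples carry
    the minor allele after call QC, and no more than ``max_failed_calls``
    samples had their call set to missing by QC."""
    return n_carriers >= min_carriers and n_failed_calls <= max_failed_calls


def hwe_exact_midp(n_het: int, n_hom_minor: int, n_total: int) -> float:
    """Exact Hardy-Weinberg mid-p value (optional replication-profile filter).

    Enumerates the conditional distribution of heterozygote counts given the
    minor-allele count; the mid-p assigns half weight to the observed
    heterozygote count's probability.
    """
    n_minor = 2 * n_hom_minor + n_het
    if n_minor > n_total:
        raise ValueError("minor allele count exceeds chromosome count")
    rare = n_minor
    # log-probabilities over all feasible het counts with the same parity
    hets = np.arange(rare % 2, min(rare, 2 * n_total - rare) + 1, 2)
    from scipy.special import gammaln

    def logp(h):
        hom_r = (rare - h) // 2
        hom_c = n_total - h - hom_r
        return (h * math.log(2)
                + gammaln(n_total + 1) - gammaln(h + 1) - gammaln(hom_r + 1)
                - gammaln(hom_c + 1)
                + gammaln(rare + 1) + gammaln(2 * n_total - rare + 1)
                - gammaln(2 * n_total + 1))

    lp = np.array([logp(int(h)) for h in hets])
    probs = np.exp(lp - lp.max())
    probs /= probs.sum()
    obs = probs[hets == n_het]
    if obs.size == 0:
        raise ValueError("observed het count infeasible for allele count")
    p_obs = float(obs[0])
    return float(probs[probs <= p_obs + 1e-12].sum() - 0.5 * p_obs)
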