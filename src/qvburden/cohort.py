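"""Case-control cohort construction.

Builds the analysis-ready cohort from sample metadata: union phenotype
definitions over ICD-10-style code prefixes, exclusion of controls with any
eye-disease (Chapter VII) diagnosis, sample-level sequencing QC gates,
ancestry-probability and principal-component outlier filters, greedy kinship
pruning, sex rebalancing of controls, and the derived mean spherical
equivalent (MSE) refractive-error trait.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

#: ICD-10 Chapter VII (diseases of the eye and adnexa): codes H00-H59.
CHAPTER_VII_PREFIXES = tuple(f"H{i:02d}" for i in range(60))


class ConfigurationError(ValueError):
    pass


class RebalanceError(RuntimeError):
    """Sex rebalancing cannot reach the target odds by removing controls."""


@dataclass(frozen=True)
class PhenotypeDefinition:
    """A union phenotype: case iff any diagnosis code starts with an include
    prefix; controls must match no exclusion prefix."""

    name: str
    include_prefixes: frozenset
    control_exclusion_prefixes: frozenset = frozenset(CHAPTER_VII_PREFIXES)

    def __post_init__(self) -> None:
        if not self.include_prefixes:
            raise ConfigurationError("include_prefixes must be non-empty")


RD_UNION = PhenotypeDefinition("retinal_detachment", frozenset({"H33"}))
RD_RHEGMATOGENOUS = PhenotypeDefinition("rhegmatogenous_rd", frozenset({"H330"}))
RD_SEROUS = PhenotypeDefinition("serous_rd", frozenset({"H332"}))


@dataclass
class CaseControlCohort:
    case_ids: set
    control_ids: set
    phenotype: PhenotypeDefinition
    rebalance_seed: Optional[int] = None

    def __post_init__(self) -> None:
        overlap = self.case_ids & self.control_ids
        if overlap:
            raise ConfigurationError(f"case/control overlap: {sorted(overlap)[:5]}")

    @property
    def n_cases(self) -> int:
        return len(self.case_ids)

    @property
    def n_controls(self) -> int:
        return len(self.control_ids)


def normalize_code(code: str) -> str:
    return code.replace(".", "").strip().upper()


def _sample_codes(samples: pd.DataFrame) -> pd.Series:
    """icd_codes column (';'-joined) -> list of normalized codes per sample."""
    raw = samples["icd_codes"].fillna("")
    return raw.map(lambda s: [normalize_code(c) for c in s.split(";") if c.strip()])


def _matches_any_prefix(codes: Iterable[str], prefixes) -> bool:
    return any(code.startswith(p) for code in codes for p in prefixes)


def build_union_phenotype(samples: pd.DataFrame, definition: PhenotypeDefinition) -> set:
    """Case identifiers: samples with any code under an include prefix."""
    prefixes = tuple(normalize_code(p) for p in definition.include_prefixes)
    if not prefixes:
        raise ConfigurationError("empty include prefix set")
    codes = _sample_codes(samples)
    is_case = codes.map(lambda cs: _matches_any_prefix(cs, prefixes))
    return set(samples.loc[is_case.to_numpy(), "sample_id"])


def select_controls(samples: pd.DataFrame, definition: PhenotypeDefinition) -> set:
    """Control identifiers: samples with no code under any exclusion prefix."""
    prefixes = tuple(normalize_code(p) for p in definition.control_exclusion_prefixes)
    codes = _sample_codes(samples)
    excluded = codes.map(lambda cs: _matches_any_prefix(cs, prefixes))
    return set(samples.loc[(~excluded).to_numpy(), "sample_id"])


def sample_qc_filter(
    samples: pd.DataFrame,
    freemix_max: float = 0.04,
    cov10_min: float = 0.945,
    ancestry_prob_min: float = 0.90,
    pc_sd_max: float = 4.0,
) -> set:
    """Sequencing / ancestry sample QC.

    Retains samples with contamination (FREEMIX) < 0.04, >=10x coverage over
    >=94.5% of CCDS bases, >=0.90 ancestry-assignment probability, and all of
    the first four genetic PCs within 4 SD of the mean.  PC means and SDs are
    computed per ancestry group over the ancestry-probability-passing subset
    (the probability gate is applied before the PC gate).
    """
    if len(samples) < 2:
        raise ConfigurationError("need >= 2 samples to estimate PC dispersion")
    ok = (
        (samples["freemix"] < freemix_max)
        & (samples["ccds_cov10_fraction"] >= cov10_min)
        & (samples["ancestry_prob"] >= ancestry_prob_min)
    )
    passing = samples.loc[ok].copy()
    keep = pd.Series(True, index=passing.index)
    pc_cols = ["pc1", "pc2", "pc3", "pc4"]
    for _, grp in passing.groupby("ancestry"):
        mu = grp[pc_cols].mean()
        sd = grp[pc_cols].std(ddof=1)
        within = pd.Series(True, index=grp.index)
        for c in pc_cols:
            if sd[c] == 0 or not np.isfinite(sd[c]):
                continue
            within &= (grp[c] - mu[c]).abs() <= pc_sd_max * sd[c]
        keep.loc[grp.index] = within
    return set(passing.loc[keep, "sample_id"])


def _greedy_prune(ids: set, edges: list[tuple[str, str]]) -> set:
    """Iteratively drop the sample with the highest relatedness degree (ties
    broken toward the lexicographically larger id) until no edge remains."""
    adj: dict[str, set] = {}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    removed = set()
    while True:
        degrees = {s: len(nb - removed) for s, nb in adj.items()
                   if s not in removed and len(nb - removed) > 0}
        if not degrees:
            break
        worst = max(degrees.items(), key=lambda kv: (kv[1], kv[0]))[0]
        removed.add(worst)
    return ids - removed


def prune_related(
    ids: set,
    kinship_pairs: pd.DataFrame,
    threshold: float = 0.3536,
    case_ids: Optional[set] = None,
) -> set:
    """Greedy kinship pruning in three steps: resolve case-case pairs, drop
    controls related to remaining cases, then resolve control-control pairs.
    No retained pair exceeds the kinship threshold."""
    if threshold <= 0:
        raise ConfigurationError("kinship threshold must be > 0")
    case_ids = set(case_ids or set())
    over = kinship_pairs.loc[kinship_pairs["kinship"] > threshold]
    edges = [(a, b) for a, b in zip(over["sample_a"], over["sample_b"])
             if a in ids and b in ids and a != b]
    if not edges:
        return set(ids)

    retained = set(ids)
    # (1) case-case
    cc = [(a, b) for a, b in edges if a in case_ids and b in case_ids]
    retained = _greedy_prune(retained, cc)
    # (2) controls related to remaining cases
    for a, b in edges:
        if a in retained and b in retained:
            if a in case_ids and b not in case_ids:
                retained.discard(b)
            elif b in case_ids and a not in case_ids:
                retained.discard(a)
    # (3) control-control
    ctrl = [(a, b) for a, b in edges
            if a in retained and b in retained
            and a not in case_ids and b not in case_ids]
    retained = _greedy_prune(retained, ctrl)
    return retained


def compute_mse(
    sph_r: float = np.nan, cyl_r: float = np.nan,
    sph_l: float = np.nan, cyl_l: float = np.nan,
) -> float:
    """Mean spherical equivalent in diopters.

    Per-eye MSE = spherical power + 0.5 x cylindrical power; the sample value
    is the mean over eyes with complete data.  NaN when no eye is complete.
    """
    eyes = []
    if np.isfinite(sph_r) and np.isfinite(cyl_r):
        eyes.append(sph_r + 0.5 * cyl_r)
    if np.isfinite(sph_l) and np.isfinite(cyl_l):
        eyes.append(sph_l + 0.5 * cyl_l)
    return float(np.mean(eyes)) if eyes else float("nan")


def compute_mse_column(samples: pd.DataFrame) -> pd.Series:
    """Vectorized MSE over a sample table."""
    right = samples["sph_r"] + 0.5 * samples["cyl_r"]
    left = samples["sph_l"] + 0.5 * samples["cyl_l"]
    both = pd.concat([right, left], axis=1)
    return both.mean(axis=1, skipna=True)


def sex_rebalance(
    cohort: CaseControlCohort,
    samples: pd.DataFrame,
    alpha: float = 0.05,
    seed: int = 0,
) -> CaseControlCohort:
    """Down-sample controls of the over-represented sex until the control
    male:female odds match the case odds (as nearly as integers allow).

    Triggered only when the two-sided Fisher exact p on the sex-by-status
    table is below ``alpha``; cases are never removed.
    """
    sex = samples.set_index("sample_id")["sex"]
    cm = sum(1 for s in cohort.case_ids if sex.get(s) == "male")
    cf = len(cohort.case_ids) - cm
    ctl_m = [s for s in cohort.control_ids if sex.get(s) == "male"]
    ctl_f = [s for s in cohort.control_ids if sex.get(s) != "male"]
    p = sps.fisher_exact([[cm, cf], [len(ctl_m), len(ctl_f)]])[1]
    if p >= alpha:
        return cohort

    if cm == 0 or cf == 0:
        raise RebalanceError(
            "cases are single-sex; control odds cannot be matched by down-sampling"
        )
    case_odds = cm / cf
    ctrl_odds = len(ctl_m) / len(ctl_f) if ctl_f else math.inf
    rng = np.random.default_rng(seed)
    if ctrl_odds > case_odds:
        target = int(round(len(ctl_f) * case_odds))
        keep_m = sorted(rng.choice(sorted(ctl_m), size=target, replace=False))
        new_controls = set(keep_m) | set(ctl_f)
    else:
        target = int(round(len(ctl_m) / case_odds))
        keep_f = sorted(rng.choice(sorted(ctl_f), size=target, replace=False))
        new_controls = set(ctl_m) | set(keep_f)

    nm = sum(1 for s in new_controls if sex.get(s) == "male")
    nf = len(new_controls) - nm
    p_after = sps.fisher_exact([[cm, cf], [nm, nf]])[1]
    if p_after < alpha:
        raise RebalanceError(f"rebalancing failed to equalize odds (p={p_after:.3g})")
    logger.info("sex rebalance: controls %d -> %d (p %.3g -> %.3g)",
                cohort.n_controls, len(new_controls), p, p_after)
    return CaseControlCohort(
        case_ids=set(cohort.case_ids),
        control_ids=new_controls,
        phenotype=cohort.phenotype,
        rebalance_seed=seed,
    )


def build_cohort(
    samples: pd.DataFrame,
    definition: PhenotypeDefinition,
    kinship_pairs: Optional[pd.DataFrame] = None,
    kinship_threshold: float = 0.3536,
    rebalance: bool = True,
    rebalance_alpha: float = 0.05,
    rebalance_seed: int = 0,
    apply_sample_qc: bool = True,
) -> CaseControlCohort:
    """Full cohort construction: phenotype union, control exclusion, sample
    QC, kinship pruning, and optional sex rebalancing."""
    usable = samples
    missing = usable["sex"].isna() | usable["icd_codes"].isna()
    if missing.any():
        logger.warning("excluding %d samples with missing sex or codes", int(missing.sum()))
        usable = usable.loc[~missing]

    retained = set(usable["sample_id"])
    if apply_sample_qc:
        retained = sample_qc_filter(usable)
    cases = build_union_phenotype(usable, definition) & retained
    controls = select_controls(usable, definition) & retained

    if kinship_pairs is not None and len(kinship_pairs):
        kept = prune_related(cases | controls, kinship_pairs,
                             threshold=kinship_threshold, case_ids=cases)
        cases &= kept
        controls &= kept

    cohort = CaseControlCohort(case_ids=cases, control_ids=controls,
                               phenotype=definition)
    if rebalance:
        cohort = sex_rebalance(cohort, usable, alpha=rebalance_alpha,
                               seed=rebalance_seed)
    return cohort
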