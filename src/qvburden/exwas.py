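"""Variant-level exome-wide association study (ExWAS).

Each QC-passing variant seen in at least six carriers is tested for
case-control association under three genetic models — allelic (one row per
allele), dominant (carriers of >= 1 minor allele) and recessive (homozygous
minor) — with the two-sided Fisher exact test and Woolf odds-ratio CIs from
the stats kernel.  Tables are oriented to the minor allele: if the alternate
allele frequency exceeds 0.5 the reference allele is counted instead.
Genotype calls failing QC become missing and drop out of the table
denominators.  For quantitative traits a genotypic dosage model (0/1/2
linear term, optionally a 2-df factor coding) is fitted by OLS with age and
sex as covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import CaseControlCohort
from .stats import (AssociationResult, ContingencyTable2x2, lambda_gc,
                    association_test, RegressionResult, linear_assoc)
from .variant_qc import (DEFAULT_THRESHOLDS, QCThresholds, apply_call_qc,
                         apply_site_qc, exwas_inclusion)

logger = logging.getLogger(__name__)

BINARY_MODELS = ("allelic", "dominant", "recessive")


@dataclass
class VariantCounts:
    """Per-variant genotype tallies after call QC, split by arm."""

    het_case: int
    hom_case: int
    het_control: int
    hom_control: int
    missing_case: int
    missing_control: int
    n_cases: int
    n_controls: int
    n_failed_calls: int = 0

    @property
    def nonmissing_cases(self) -> int:
        return self.n_cases - self.missing_case

    @property
    def nonmissing_controls(self) -> int:
        return self.n_controls - self.missing_control

    @property
    def alt_frequency(self) -> float:
        alleles = 2 * (self.nonmissing_cases + self.nonmissing_controls)
        if alleles == 0:
            return 0.0
        alt = (self.het_case + self.het_control
               + 2 * (self.hom_case + self.hom_control))
        return alt / alleles

    @property
    def minor_allele_carriers(self) -> int:
        """Samples carrying >= 1 minor allele, used by the inclusion gate."""
        if self.alt_frequency <= 0.5:
            return self.het_case + self.hom_case + self.het_control + self.hom_control
        return (self.nonmissing_cases - self.hom_case
                + self.nonmissing_controls - self.hom_control)


def genotype_table(counts: VariantCounts, model: str) -> ContingencyTable2x2:
    """Build the case/control 2x2 table for one binary genetic model.

    Missing genotypes contribute neither to allele counts nor to the
    dominant/recessive sample denominators (the tables are over samples with
    a non-missing post-QC genotype).
    """
    if model not in BINARY_MODELS:
        raise ValueError(f"unknown genetic model {model!r}")
    nc, nt = counts.nonmissing_cases, counts.nonmissing_controls
    flip = counts.alt_frequency > 0.5
    het_ca, hom_ca = counts.het_case, counts.hom_case
    het_co, hom_co = counts.het_control, counts.hom_control
    if flip:
        hom_ca = nc - het_ca - hom_ca  # hom for the (minor) reference allele
        hom_co = nt - het_co - hom_co

    if model == "allelic":
        a = 2 * hom_ca + het_ca
        c = 2 * hom_co + het_co
        return ContingencyTable2x2(a, 2 * nc - a, c, 2 * nt - c)
    if model == "dominant":
        a = hom_ca + het_ca
        c = hom_co + het_co
        return ContingencyTable2x2(a, nc - a, c, nt - c)
    # recessive: homozygous minor vs all other genotypes
    return ContingencyTable2x2(hom_ca, nc - hom_ca, hom_co, nt - hom_co)


def tally_frame(
    calls: pd.DataFrame,
    call_pass: pd.Series,
    cohort: CaseControlCohort,
    variant_ids: Sequence[str],
) -> pd.DataFrame:
    """Vectorized per-variant genotype tallies (one row per variant id).

    Calls failing QC count as missing genotypes; genotype -1 is missing from
    the caller itself.  Variants with no calls get all-zero rows.
    """
    case_ids = cohort.case_ids
    in_cohort = calls["sample_id"].isin(case_ids | cohort.control_ids)
    sub = calls.loc[in_cohort]
    is_case = sub["sample_id"].isin(case_ids).to_numpy()
    ok = (call_pass.reindex(sub.index).fillna(False).to_numpy()
          & (sub["gt"] > 0).to_numpy())
    gt = sub["gt"].to_numpy()
    miss = ~ok

    flags = pd.DataFrame({
        "het_case": (gt == 1) & ok & is_case,
        "hom_case": (gt == 2) & ok & is_case,
        "het_control": (gt == 1) & ok & ~is_case,
        "hom_control": (gt == 2) & ok & ~is_case,
        "missing_case": miss & is_case,
        "missing_control": miss & ~is_case,
        "n_failed": miss & (gt > 0),
        "variant_id": sub["variant_id"].to_numpy(),
    })
    agg = (flags.groupby("variant_id").sum().astype(np.int64)
           if len(sub) else pd.DataFrame(
               columns=["het_case", "hom_case", "het_control", "hom_control",
                        "missing_case", "missing_control", "n_failed"]))
    return agg.reindex(pd.Index(variant_ids, name="variant_id"),
                       fill_value=0).astype(np.int64)


def internal_maf(tallies: pd.DataFrame, cohort: CaseControlCohort) -> pd.Series:
    """In-cohort minor allele frequency per variant from post-QC tallies."""
    n = cohort.n_cases + cohort.n_controls
    nonmiss = n - tallies["missing_case"] - tallies["missing_control"]
    alleles = (2 * nonmiss).astype(float)
    alt = (tallies["het_case"] + tallies["het_control"]
           + 2 * (tallies["hom_case"] + tallies["hom_control"]))
    af = np.divide(alt, alleles, out=np.zeros(len(tallies)),
                   where=alleles.to_numpy() > 0)
    return pd.Series(np.minimum(af, 1 - af), index=tallies.index, name="maf")


def tally_variants(
    calls: pd.DataFrame,
    call_pass: pd.Series,
    cohort: CaseControlCohort,
    variant_ids: Sequence[str],
) -> dict[str, VariantCounts]:
    """Per-variant VariantCounts keyed by variant id; see :func:`tally_frame`."""
    agg = tally_frame(calls, call_pass, cohort, variant_ids)
    nc, nt = cohort.n_cases, cohort.n_controls
    return {
        vid: VariantCounts(
            het_case=r[0], hom_case=r[1], het_control=r[2], hom_control=r[3],
            missing_case=r[4], missing_control=r[5],
            n_cases=nc, n_controls=nt, n_failed_calls=r[6],
        )
        for vid, r in zip(agg.index, agg[
            ["het_case", "hom_case", "het_control", "hom_control",
             "missing_case", "missing_control", "n_failed"]].to_numpy())
    }


def run_exwas(
    variants: pd.DataFrame,
    calls: pd.DataFrame,
    cohort: CaseControlCohort,
    models: Sequence[str] = BINARY_MODELS,
    thresholds: QCThresholds = DEFAULT_THRESHOLDS,
    min_carriers: int = 6,
    max_failed_calls: int = 20_000,
) -> tuple[list[AssociationResult], dict[str, float]]:
    """Run the variant-level scan; returns (results, per-model lambda_GC).

    Results are sorted by variant id then model, so the output is invariant
    to the input ordering of variants.
    """
    for m in models:
        if m not in BINARY_MODELS:
            raise ValueError(f"unknown genetic model {m!r}")
    call_pass = apply_call_qc(calls, "exwas", thresholds)
    counts = tally_variants(calls, call_pass, cohort,
                            variants["variant_id"].tolist())
    n_samples = cohort.n_cases + cohort.n_controls
    missing = pd.Series(
        [
            (counts[v].missing_case + counts[v].missing_control) / n_samples
            for v in variants["variant_id"]
        ],
        index=variants.index,
    )
    site = apply_site_qc(variants, "exwas", missingness=missing,
                         thresholds=thresholds)

    results: list[AssociationResult] = []
    for idx, vid in sorted(zip(variants.index, variants["variant_id"]),
                           key=lambda t: t[1]):
        if not site.loc[idx, "site_pass"]:
            continue
        vc = counts[vid]
        if not exwas_inclusion(vc.minor_allele_carriers, vc.n_failed_calls,
                               min_carriers, max_failed_calls):
            continue
        for model in models:
            table = genotype_table(vc, model)
            results.append(association_test(table, model=model, target=vid))

    lambdas = {}
    for model in models:
        ps = [r.p for r in results if r.model == model]
        if ps:
            lambdas[model] = lambda_gc(ps)
    return results, lambdas


def genotypic_assoc(
    trait: np.ndarray,
    dosage: np.ndarray,
    age: Optional[np.ndarray] = None,
    sex: Optional[np.ndarray] = None,
) -> RegressionResult:
    """Quantitative-trait genotypic test: OLS of the trait on allele dosage
    (0/1/2 linear coding) correcting for age and sex."""
    covs = []
    if age is not None:
        covs.append(np.asarray(age, dtype=float))
    if sex is not None:
        s = np.asarray(sex)
        covs.append((s == "male").astype(float) if s.dtype.kind in "UO"
                    else s.astype(float))
    cov = np.vstack(covs) if covs else None
    return linear_assoc(np.asarray(trait, dtype=float),
                        np.asarray(dosage, dtype=float), cov)
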