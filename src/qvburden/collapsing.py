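"""Gene-level collapsing analysis.

For each gene and each qualifying-variant (QV) model, samples are collapsed
to a carrier/non-carrier indicator — carrying at least one QV under the
dominant coding, or a homozygous QV / two distinct heterozygous QVs
(putative compound heterozygote) under the recessive coding — and the
difference in carrier proportion between cases and controls is tested with
the two-sided Fisher exact test.  A QV model is a declarative predicate over
consequence class, internal and external minor-allele-frequency caps, a
missense-tolerance (MTR) sub-region rule, a predicted-deleteriousness rule,
and zygosity.  A synonymous-variant model serves as an empirical negative
control.  Stratified (pan-ancestry) evidence is combined per gene with the
Cochran-Mantel-Haenszel test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import CaseControlCohort, PhenotypeDefinition, build_union_phenotype
from .exwas import internal_maf, tally_frame
from .stats import (AssociationResult, ContingencyTable2x2, cmh_test,
                    lambda_gc, odds_ratio_ci, association_test)
from .synthetic import PTV_CONSEQUENCES
from .variant_qc import (DEFAULT_THRESHOLDS, QCThresholds, apply_call_qc,
                         apply_site_qc)

logger = logging.getLogger(__name__)

#: Significance threshold for the genome-wide collapsing scan.
SIGNIFICANCE_P = 1e-8

_CLASS_BY_TERM = {
    **{t: "PTV" for t in PTV_CONSEQUENCES},
    "missense_variant": "missense",
    "synonymous_variant": "synonymous",
    "inframe_deletion": "other_nonsyn",
    "inframe_insertion": "other_nonsyn",
    "protein_altering_variant": "other_nonsyn",
}


@dataclass(frozen=True)
class QVModel:
    """Declarative qualifying-variant rule set.

    ``require_mtr``: missense variants must fall in a missense-intolerant
    sub-region (exome-wide MTR percentile <= 25 OR intragenic percentile
    <= 50); protein-truncating variants are exempt.  ``require_damaging``:
    missense variants must carry a predicted-deleterious annotation.
    ``require_external_absent``: the variant must be absent from the external
    reference (ultra-rare models).
    """

    name: str
    consequence_classes: frozenset
    max_maf_internal: float = 0.001
    max_maf_external: float = 0.001
    require_mtr: bool = False
    require_damaging: bool = False
    require_external_absent: bool = False
    zygosity: str = "dominant"

    def __post_init__(self) -> None:
        if not 0 <= self.max_maf_internal <= 1 or not 0 <= self.max_maf_external <= 1:
            raise ValueError("MAF caps must lie in [0,1]")
        if self.zygosity not in ("dominant", "recessive"):
            raise ValueError(f"unknown zygosity {self.zygosity!r}")


_NONSYN = frozenset({"PTV", "missense"})

#: The ten default QV models.  Thresholds not fixed by the analysis itself
#: are package defaults and are meant to be overridden from configuration.
DEFAULT_QV_MODELS: dict[str, QVModel] = {m.name: m for m in [
    QVModel("ptv", frozenset({"PTV"})),
    QVModel("UR", _NONSYN, require_external_absent=True),
    QVModel("URmtr", _NONSYN, require_external_absent=True, require_mtr=True),
    QVModel("raredmg", frozenset({"missense"}), require_damaging=True),
    QVModel("raredmgmtr", frozenset({"missense"}), require_damaging=True,
            require_mtr=True),
    QVModel("flexdmg", _NONSYN, require_damaging=True),
    QVModel("flexnonsynmtr", _NONSYN, require_mtr=True),
    QVModel("ptvraredmg", _NONSYN, require_damaging=True, max_maf_external=0.0005),
    QVModel("rec", _NONSYN, require_damaging=True, zygosity="recessive"),
    QVModel("syn", frozenset({"synonymous"})),
]}

#: Models excluded from enrichment aggregation (empirical negative control).
NEGATIVE_CONTROL_MODELS = ("syn",)


def consequence_class(term: str) -> Optional[str]:
    cls = _CLASS_BY_TERM.get(term)
    if cls is None:
        logger.warning("unknown consequence term %r: treated as non-qualifying", term)
    return cls


def select_qualifying_variants(
    variants: pd.DataFrame,
    model: QVModel,
    internal_maf: Optional[pd.Series] = None,
) -> pd.Series:
    """Boolean mask over ``variants`` of sites qualifying under ``model``.

    ``internal_maf`` is indexed by variant_id; when absent the internal cap
    is not evaluated (annotation-only selection).
    """
    classes = variants["consequence"].map(consequence_class)
    mask = classes.isin(model.consequence_classes)

    ext_af = pd.to_numeric(variants.get("ext_af", np.nan), errors="coerce")
    ext_present = variants.get("ext_present")
    if ext_present is None:
        ext_present = ext_af.notna() & (ext_af > 0)
    mask &= ~(ext_af > model.max_maf_external)  # NaN passes
    if model.require_external_absent:
        mask &= ~ext_present.fillna(False).astype(bool)

    if internal_maf is not None:
        maf = variants["variant_id"].map(internal_maf)
        mask &= ~(maf > model.max_maf_internal)

    is_missense = classes.eq("missense")
    if model.require_mtr:
        ex = pd.to_numeric(variants.get("mtr_exome_pct", np.nan), errors="coerce")
        gn = pd.to_numeric(variants.get("mtr_gene_pct", np.nan), errors="coerce")
        intolerant = (ex <= 25) | (gn <= 50)  # NaN percentiles do not qualify
        mask &= ~is_missense | intolerant
    if model.require_damaging:
        dmg = variants.get("predicted_damaging")
        dmg = (dmg.fillna(False).astype(bool) if dmg is not None
               else pd.Series(False, index=variants.index))
        mask &= ~is_missense | dmg
    return mask


def carrier_set(
    qv_calls: pd.DataFrame,
    zygosity: str = "dominant",
) -> set:
    """Sample ids carrying qualifying variants in one gene.

    ``qv_calls``: post-QC calls restricted to the gene's QVs (columns
    sample_id, variant_id, gt).  Dominant: any het or hom-alt QV genotype.
    Recessive: any hom-alt QV, or het genotypes at >= 2 distinct QVs.
    Duplicate (variant, sample) rows are ignored, so the result is
    idempotent under record duplication.
    """
    dedup = qv_calls.drop_duplicates(["variant_id", "sample_id"])
    dedup = dedup.loc[dedup["gt"] > 0]
    if zygosity == "dominant":
        return set(dedup["sample_id"])
    if zygosity != "recessive":
        raise ValueError(f"unknown zygosity {zygosity!r}")
    hom = set(dedup.loc[dedup["gt"] == 2, "sample_id"])
    het = dedup.loc[dedup["gt"] == 1]
    multi = het.groupby("sample_id")["variant_id"].nunique()
    return hom | set(multi.index[multi >= 2])


def carrier_flags(qv_calls: pd.DataFrame, sample_ids: Sequence[str],
                  zygosity: str = "dominant") -> pd.Series:
    """Per-sample carrier indicator over a fixed sample ordering."""
    carriers = carrier_set(qv_calls, zygosity)
    idx = pd.Index(sample_ids, name="sample_id")
    return pd.Series(idx.isin(carriers), index=idx, name="carrier")


def gene_table(carriers: set, cohort: CaseControlCohort) -> ContingencyTable2x2:
    a = len(carriers & cohort.case_ids)
    c = len(carriers & cohort.control_ids)
    return ContingencyTable2x2(a, cohort.n_cases - a, c, cohort.n_controls - c)


class CollapsingRun:
    """QC'd inputs shared by all models of one collapsing run."""

    def __init__(
        self,
        variants: pd.DataFrame,
        calls: pd.DataFrame,
        cohort: CaseControlCohort,
        thresholds: QCThresholds = DEFAULT_THRESHOLDS,
    ) -> None:
        self.cohort = cohort
        site = apply_site_qc(variants, "collapsing", thresholds=thresholds)
        self.variants = variants.loc[site["site_pass"]].copy()
        self.site_report = site

        members = cohort.case_ids | cohort.control_ids
        call_pass = apply_call_qc(calls, "collapsing", thresholds)
        ok = (call_pass & calls["sample_id"].isin(members)
              & calls["variant_id"].isin(set(self.variants["variant_id"]))
              & (calls["gt"] > 0))
        self.calls = calls.loc[ok, ["variant_id", "sample_id", "gt"]].copy()

        tallies = tally_frame(calls, call_pass, cohort,
                              self.variants["variant_id"].tolist())
        self.internal_maf = internal_maf(tallies, cohort)
        self.genes = sorted(variants["gene"].unique())

    def qv_mask(self, model: QVModel) -> pd.Series:
        return select_qualifying_variants(self.variants, model, self.internal_maf)

    def qv_table(self, models: Mapping[str, QVModel]) -> pd.DataFrame:
        """Long (gene, variant_id, model) listing of qualifying variants."""
        rows = []
        for name, model in models.items():
            sel = self.variants.loc[self.qv_mask(model), ["gene", "variant_id"]]
            sel = sel.assign(model=name)
            rows.append(sel)
        return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
            columns=["gene", "variant_id", "model"])

    def gene_carriers(self, model: QVModel) -> dict[str, set]:
        qv = self.variants.loc[self.qv_mask(model), ["variant_id", "gene"]]
        merged = self.calls.merge(qv, on="variant_id", how="inner")
        out: dict[str, set] = {g: set() for g in self.genes}
        for gene, grp in merged.groupby("gene"):
            out[gene] = carrier_set(grp, model.zygosity)
        return out


def run_collapsing(
    variants: pd.DataFrame,
    calls: pd.DataFrame,
    cohort: CaseControlCohort,
    models: Optional[Mapping[str, QVModel]] = None,
    thresholds: QCThresholds = DEFAULT_THRESHOLDS,
) -> tuple[list[AssociationResult], dict[str, float]]:
    """Gene-by-model collapsing scan; returns (results, per-model lambda_GC)."""
    models = dict(models if models is not None else DEFAULT_QV_MODELS)
    run = CollapsingRun(variants, calls, cohort, thresholds)
    results: list[AssociationResult] = []
    lambdas: dict[str, float] = {}
    for name, model in models.items():
        carriers = run.gene_carriers(model)
        ps = []
        for gene in run.genes:
            table = gene_table(carriers[gene], cohort)
            res = association_test(table, model=name, target=gene)
            results.append(res)
            ps.append(res.p)
        if ps:
            lambdas[name] = lambda_gc(ps)
    return results, lambdas


def exclude_variant_rerun(
    variants: pd.DataFrame,
    calls: pd.DataFrame,
    cohort: CaseControlCohort,
    gene: str,
    model: QVModel,
    variant_id: str,
    model_name: Optional[str] = None,
    thresholds: QCThresholds = DEFAULT_THRESHOLDS,
) -> AssociationResult:
    """Leave-one-variant-out sensitivity re-run.

    Carriers of ``variant_id`` are removed from both cohort arms entirely
    (numerators and denominators) and the gene test is recomputed on the
    reduced cohort.
    """
    run = CollapsingRun(variants, calls, cohort, thresholds)
    qv = run.variants.loc[run.qv_mask(model)]
    qv_gene = qv.loc[qv["gene"] == gene, "variant_id"]
    if variant_id not in set(qv_gene):
        raise ValueError(f"{variant_id} is not a qualifying variant of "
                         f"({gene}, {model.name})")
    excluded = set(run.calls.loc[run.calls["variant_id"] == variant_id, "sample_id"])
    reduced = CaseControlCohort(
        case_ids=cohort.case_ids - excluded,
        control_ids=cohort.control_ids - excluded,
        phenotype=cohort.phenotype,
    )
    gene_calls = run.calls.merge(
        qv_gene[qv_gene != variant_id].to_frame("variant_id"), on="variant_id")
    carriers = carrier_set(gene_calls, model.zygosity) & (
        reduced.case_ids | reduced.control_ids)
    table = gene_table(carriers, reduced)
    return association_test(table, model=model_name or model.name, target=gene)


def run_pan_ancestry(
    cohorts: Mapping[str, CaseControlCohort],
    variants: pd.DataFrame,
    calls: pd.DataFrame,
    models: Optional[Mapping[str, QVModel]] = None,
    thresholds: QCThresholds = DEFAULT_THRESHOLDS,
) -> list[AssociationResult]:
    """Stratified collapsing meta-analysis across ancestry cohorts.

    Per gene and model, one carrier table per stratum (zero-carrier strata
    included) combined with the CMH test; the reported odds ratio is the
    Mantel-Haenszel common OR and the CI is the Woolf interval of the
    margin-summed table (descriptive).
    """
    if not cohorts:
        raise ValueError("at least one ancestry cohort is required")
    models = dict(models if models is not None else DEFAULT_QV_MODELS)
    runs = {label: CollapsingRun(variants, calls, c, thresholds)
            for label, c in cohorts.items()}
    genes = sorted(variants["gene"].unique())
    results = []
    for name, model in models.items():
        carrier_maps = {label: run.gene_carriers(model)
                        for label, run in runs.items()}
        for gene in genes:
            strata = [gene_table(carrier_maps[label][gene], cohorts[label])
                      for label in cohorts]
            p, common_or = cmh_test(strata)
            pooled = ContingencyTable2x2(
                sum(t.a for t in strata), sum(t.b for t in strata),
                sum(t.c for t in strata), sum(t.d for t in strata))
            _, lo, hi = odds_ratio_ci(pooled)
            results.append(AssociationResult(
                p=p, or_=common_or, ci_low=lo, ci_high=hi,
                table=pooled, model=name, target=gene))
    return results


def run_subtype(
    samples: pd.DataFrame,
    cohort: CaseControlCohort,
    subtype: PhenotypeDefinition,
    variants: pd.DataFrame,
    calls: pd.DataFrame,
    models: Optional[Mapping[str, QVModel]] = None,
    thresholds: QCThresholds = DEFAULT_THRESHOLDS,
) -> tuple[list[AssociationResult], dict[str, float]]:
    """Re-run collapsing with the case set restricted to a phenotype subtype;
    the control set is reused unchanged."""
    sub_cases = build_union_phenotype(samples, subtype) & cohort.case_ids
    if not sub_cases:
        raise ValueError(f"subtype {subtype.name!r} selects no cases")
    sub_cohort = CaseControlCohort(case_ids=sub_cases,
                                   control_ids=set(cohort.control_ids),
                                   phenotype=subtype)
    return run_collapsing(variants, calls, sub_cohort, models, thresholds)
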