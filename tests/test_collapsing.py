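"""Qualifying-variant selection, carrier collapsing, leave-one-variant-out,
pan-ancestry CMH and subtype re-analysis."""

import numpy as np
import pandas as pd
import pytest

from qvburden.cohort import CaseControlCohort, PhenotypeDefinition
from qvburden.collapsing import (DEFAULT_QV_MODELS, QVModel, carrier_flags,
                                 carrier_set, exclude_variant_rerun,
                                 run_collapsing, run_pan_ancestry, run_subtype,
                                 select_qualifying_variants)
from qvburden.exwas import run_exwas
from qvburden.synthetic import GeneScenario, SyntheticConfig, simulate_cohort

from conftest import make_samples


def mkvariant(**kw):
    base = dict(variant_id="v1", chrom="chr1", pos=100, ref="G", alt="T",
                gene="G1", consequence="missense_variant", variant_class="SNV",
                qual=100.0, fs=5.0, mq=55.0, rprs=0.0, mqrs=0.0,
                filter_status="PASS", ccds=True, ext_present=True, ext_af=2e-4,
                ext_ac=10, ext_ac_raw=10, ext_cov10_frac=0.9, ext_rprs=0.0,
                ext_mq=50.0, mtr=0.4, mtr_exome_pct=20.0, mtr_gene_pct=40.0,
                predicted_damaging=True)
    base.update(kw)
    return base


RELAXED = {  # toy-cohort variants exceed the 0.1% internal cap by design
    "dom": QVModel("dom", frozenset({"PTV", "missense"}),
                   max_maf_internal=0.5, max_maf_external=0.5),
    "recm": QVModel("recm", frozenset({"PTV", "missense"}),
                    max_maf_internal=0.5, max_maf_external=0.5,
                    zygosity="recessive"),
}


def test_qv_selection_consequence_and_mtr_rules():
    variants = pd.DataFrame([
        mkvariant(variant_id="ptv", consequence="stop_gained",
                  ext_af=2e-4, mtr_exome_pct=90.0, mtr_gene_pct=90.0),
        mkvariant(variant_id="mis_intolerant", mtr_exome_pct=20.0, mtr_gene_pct=70.0),
        mkvariant(variant_id="mis_tolerant", mtr_exome_pct=60.0, mtr_gene_pct=70.0),
        mkvariant(variant_id="syn", consequence="synonymous_variant"),
        mkvariant(variant_id="common_mis", ext_af=0.05),
    ])
    flex = select_qualifying_variants(variants, DEFAULT_QV_MODELS["flexnonsynmtr"])
    assert set(variants.loc[flex, "variant_id"]) == {"ptv", "mis_intolerant"}
    ptv = select_qualifying_variants(variants, DEFAULT_QV_MODELS["ptv"])
    assert set(variants.loc[ptv, "variant_id"]) == {"ptv"}
    syn = select_qualifying_variants(variants, DEFAULT_QV_MODELS["syn"])
    assert set(variants.loc[syn, "variant_id"]) == {"syn"}
    # the synonymous variant qualifies under no non-synonymous model
    for name, model in DEFAULT_QV_MODELS.items():
        if name == "syn":
            continue
        sel = select_qualifying_variants(variants, model)
        assert "syn" not in set(variants.loc[sel, "variant_id"])


def test_qv_selection_ur_and_damaging_rules():
    variants = pd.DataFrame([
        mkvariant(variant_id="absent", ext_present=False, ext_af=0.0,
                  ext_ac=0, ext_ac_raw=0),
        mkvariant(variant_id="present"),
        mkvariant(variant_id="benign", predicted_damaging=False,
                  ext_present=False, ext_af=0.0),
    ])
    ur = select_qualifying_variants(variants, DEFAULT_QV_MODELS["UR"])
    assert set(variants.loc[ur, "variant_id"]) == {"absent", "benign"}
    dmg = select_qualifying_variants(variants, DEFAULT_QV_MODELS["flexdmg"])
    assert set(variants.loc[dmg, "variant_id"]) == {"absent", "present"}


def test_unknown_consequence_is_nonqualifying():
    variants = pd.DataFrame([mkvariant(consequence="mystery_term")])
    for model in DEFAULT_QV_MODELS.values():
        assert not select_qualifying_variants(variants, model).any()


def test_qv_sets_nest_under_tightened_caps():
    rng = np.random.default_rng(0)
    variants = pd.DataFrame([
        mkvariant(variant_id=f"v{i}",
                  consequence=rng.choice(["stop_gained", "missense_variant",
                                          "synonymous_variant"]),
                  ext_af=float(10 ** rng.uniform(-6, -2)),
                  mtr_exome_pct=float(rng.uniform(0, 100)),
                  mtr_gene_pct=float(rng.uniform(0, 100)),
                  predicted_damaging=bool(rng.random() < 0.5))
        for i in range(200)])
    flex = DEFAULT_QV_MODELS["flexnonsynmtr"]
    loose = select_qualifying_variants(variants, flex)
    tight = select_qualifying_variants(
        variants, QVModel("t", flex.consequence_classes,
                          max_maf_external=1e-4, require_mtr=True))
    assert (loose | ~tight).all()  # tight subset of loose
    # ptv QVs are a subset of flexnonsynmtr QVs under equal caps
    ptv = select_qualifying_variants(variants, DEFAULT_QV_MODELS["ptv"])
    assert (flex.max_maf_external == DEFAULT_QV_MODELS["ptv"].max_maf_external)
    assert (loose | ~ptv).all()


def test_carrier_set_dominant_and_recessive_rules():
    calls = pd.DataFrame({
        "variant_id": ["v1", "v1", "v2", "v1", "v2"],
        "sample_id": ["het1", "hom1", "het2", "comphet", "comphet"],
        "gt": [1, 2, 1, 1, 1],
    })
    assert carrier_set(calls, "dominant") == {"het1", "hom1", "het2", "comphet"}
    assert carrier_set(calls, "recessive") == {"hom1", "comphet"}
    # duplicated record does not create a spurious compound het
    dup = pd.concat([calls, calls.iloc[[0]]], ignore_index=True)
    assert carrier_set(dup, "recessive") == {"hom1", "comphet"}
    assert carrier_set(calls.iloc[:0], "dominant") == set()
    flags = carrier_flags(calls, ["het1", "none", "comphet"], "dominant")
    assert list(flags) == [True, False, True]


def _two_variant_gene(case_a=4, ctrl_a=2, case_b=3, ctrl_b=1):
    """One gene, two missense QVs with disjoint carriers."""
    case_ids = [f"A{i}" for i in range(40)]
    ctrl_ids = [f"B{i}" for i in range(160)]
    cohort = CaseControlCohort(set(case_ids), set(ctrl_ids),
                               PhenotypeDefinition("p", frozenset({"H33"})))
    rows = []
    for s in case_ids[:case_a] + ctrl_ids[:ctrl_a]:
        rows.append(("v1", s, 1, 50, 40, 20))
    for s in case_ids[10:10 + case_b] + ctrl_ids[50:50 + ctrl_b]:
        rows.append(("v2", s, 1, 50, 40, 20))
    calls = pd.DataFrame(rows, columns=["variant_id", "sample_id", "gt",
                                        "gq", "dp", "alt_reads"])
    variants = pd.DataFrame([mkvariant(variant_id="v1", pos=100),
                             mkvariant(variant_id="v2", pos=200)])
    return variants, calls, cohort


def test_run_collapsing_counts_carriers_per_gene():
    variants, calls, cohort = _two_variant_gene()
    results, lambdas = run_collapsing(variants, calls, cohort, models=RELAXED)
    dom = next(r for r in results if r.model == "dom")
    assert (dom.table.a, dom.table.b, dom.table.c, dom.table.d) == (7, 33, 3, 157)
    rec = next(r for r in results if r.model == "recm")
    assert rec.table.a == 0
    assert set(lambdas) == {"dom", "recm"}


def test_exclude_variant_rerun_removes_carriers_from_both_margins():
    variants, calls, cohort = _two_variant_gene()
    model = RELAXED["dom"]
    res = exclude_variant_rerun(variants, calls, cohort, "G1", model, "v1")
    # v1 carriers (4 cases, 2 controls) leave numerators and denominators
    assert (res.table.a, res.table.b, res.table.c, res.table.d) == (3, 33, 1, 157)
    with pytest.raises(ValueError):
        exclude_variant_rerun(variants, calls, cohort, "G1", model, "v99")


def test_exclude_variant_with_no_carriers_is_a_noop():
    variants, calls, cohort = _two_variant_gene()
    variants = pd.concat(
        [variants, pd.DataFrame([mkvariant(variant_id="v3", pos=300)])],
        ignore_index=True)
    model = RELAXED["dom"]
    base = run_collapsing(variants, calls, cohort, models={"dom": model})[0][0]
    res = exclude_variant_rerun(variants, calls, cohort, "G1", model, "v3")
    assert res.table == base.table
    assert res.p == base.p


def test_single_variant_gene_matches_exwas_dominant_exactly():
    cfg = SyntheticConfig(
        n_cases=800, n_controls=3200,
        genes=[GeneScenario("ONE", 0.02, 0.006, n_variants=1,
                            consequence_mix=(1.0, 0.0, 0.0),
                            background_carrier_freq=0.0)],
        seed=31)
    sim = simulate_cohort(cfg)
    s = sim.samples
    cohort = CaseControlCohort(
        set(s.loc[s["arm"] == "case", "sample_id"]),
        set(s.loc[s["arm"] == "control", "sample_id"]),
        PhenotypeDefinition("p", frozenset({"H33"})))
    ex_results, _ = run_exwas(sim.variants, sim.calls, cohort, models=["dominant"])
    col_results, _ = run_collapsing(sim.variants, sim.calls, cohort,
                                    models={"dom": RELAXED["dom"]})
    ex = ex_results[0]
    col = col_results[0]
    assert ex.table == col.table
    assert ex.p == col.p
    assert ex.or_ == col.or_
    assert (ex.ci_low, ex.ci_high) == (col.ci_low, col.ci_high)


def test_pan_ancestry_single_stratum_identity_and_stratified_or():
    variants, calls, cohort = _two_variant_gene()
    plain = run_collapsing(variants, calls, cohort, models=RELAXED)[0]
    single = run_pan_ancestry({"EUR": cohort}, variants, calls, models=RELAXED)
    for p_res, s_res in zip(plain, single):
        assert p_res.table == s_res.table
        if p_res.table.a + p_res.table.c > 0:  # MH OR defined
            assert s_res.or_ == pytest.approx(p_res.or_)

    # two strata with the same implanted effect: common OR inside strata range
    case_ids2 = {f"C{i}" for i in range(40)}
    ctrl_ids2 = {f"D{i}" for i in range(160)}
    rows2 = ([("v1", f"C{i}", 1, 50, 40, 20) for i in range(8)]
             + [("v1", f"D{i}", 1, 50, 40, 20) for i in range(4)])
    calls2 = pd.concat([calls, pd.DataFrame(
        rows2, columns=calls.columns)], ignore_index=True)
    cohort2 = CaseControlCohort(case_ids2, ctrl_ids2, cohort.phenotype)
    combined = run_pan_ancestry({"EUR": cohort, "SAS": cohort2},
                                variants, calls2, models={"dom": RELAXED["dom"]})
    res = next(r for r in combined if r.target == "G1")
    strata_ors = []
    for coh in (cohort, cohort2):
        r = run_collapsing(variants, calls2, coh, models={"dom": RELAXED["dom"]})[0][0]
        strata_ors.append(r.or_)
    assert min(strata_ors) <= res.or_ <= max(strata_ors)

    # a carrier-free stratum never flips the direction of effect
    empty_cohort = CaseControlCohort({f"E{i}" for i in range(20)},
                                     {f"F{i}" for i in range(80)},
                                     cohort.phenotype)
    with_null = run_pan_ancestry(
        {"EUR": cohort, "SAS": cohort2, "AFR": empty_cohort},
        variants, calls2, models={"dom": RELAXED["dom"]})
    res_null = next(r for r in with_null if r.target == "G1")
    assert (res_null.or_ > 1) == (res.or_ > 1)


def test_subtype_rerun_restricts_cases_only():
    variants, calls, cohort = _two_variant_gene()
    rows = []
    for sid in sorted(cohort.case_ids):
        code = "H332" if sid in {"A0", "A1", "A2", "A10", "A11"} else "H330"
        rows.append({"sample_id": sid, "icd_codes": code, "arm": "case"})
    for sid in sorted(cohort.control_ids):
        rows.append({"sample_id": sid, "icd_codes": "", "arm": "control"})
    samples = make_samples(rows)

    parent = PhenotypeDefinition("rd", frozenset({"H33"}))
    same, _ = run_subtype(samples, cohort, parent, variants, calls, models=RELAXED)
    base = run_collapsing(variants, calls, cohort, models=RELAXED)[0]
    assert [(r.p, r.table) for r in same] == [(r.p, r.table) for r in base]

    serous = PhenotypeDefinition("serous", frozenset({"H332"}))
    sub, _ = run_subtype(samples, cohort, serous, variants, calls, models=RELAXED)
    dom = next(r for r in sub if r.model == "dom")
    # serous cases are A0-A2 (v1 carriers) and A10-A11 (v2 carriers): the
    # carrier signal concentrates, controls unchanged
    assert dom.table.n_cases == 5
    assert dom.table.a == 5
    assert dom.table.c == 3
    base_dom = next(r for r in base if r.model == "dom")
    assert dom.or_ > base_dom.or_

    with pytest.raises(ValueError):
        run_subtype(samples, cohort,
                    PhenotypeDefinition("none", frozenset({"H339"})),
                    variants, calls, models=RELAXED)
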