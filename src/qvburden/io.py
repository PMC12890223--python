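"""Input/output: VCF 4.2 genotypes + annotations (via pysam), sample / kinship
/ panel metadata TSVs, fixture round-trips, and results tables.

The VCF carries variant annotations as INFO keys (GENE, CSQ, EXT_AF, EXT_AC,
EXT_AC_RAW, EXT_COV10_FRAC, EXT_RPRS, EXT_MQ, EXT_PRESENT, MTR,
MTR_EXOME_PCT, MTR_GENE_PCT, FS, MQ, RPRS, MQRS, CCDS, DMG, QCFAIL) and
per-sample calls as FORMAT GT:GQ:DP:AD.  Multiallelic records are decomposed
into biallelic variant records on read, with AD re-attributed per alternate
allele.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .stats import AssociationResult
from .synthetic import SyntheticCohort

SAMPLE_COLUMNS = [
    "sample_id", "arm", "sex", "age", "ancestry", "ancestry_prob",
    "pc1", "pc2", "pc3", "pc4", "icd_codes",
    "sph_r", "cyl_r", "sph_l", "cyl_l", "freemix", "ccds_cov10_fraction",
]

# float INFO keys and the decimal precision they are restored to on read
# (pysam stores INFO floats as float32)
_FLOAT_INFO = {
    "ext_af": ("EXT_AF", 8), "ext_cov10_frac": ("EXT_COV10_FRAC", 4),
    "ext_rprs": ("EXT_RPRS", 3), "ext_mq": ("EXT_MQ", 2),
    "mtr": ("MTR", 4), "mtr_exome_pct": ("MTR_EXOME_PCT", 2),
    "mtr_gene_pct": ("MTR_GENE_PCT", 2),
    "fs": ("FS", 2), "mq": ("MQ", 2), "rprs": ("RPRS", 3), "mqrs": ("MQRS", 3),
}
_INT_INFO = {"ext_ac": "EXT_AC", "ext_ac_raw": "EXT_AC_RAW"}


def _vcf_header(variants: pd.DataFrame, sample_ids: Sequence[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line('##fileformat=VCFv4.2')
    for contig in pd.unique(variants["chrom"]):
        header.add_line(f"##contig=<ID={contig}>")
    header.add_line('##FILTER=<ID=LowQual,Description="Low quality site">')
    header.add_line('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">')
    header.add_line('##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence term">')
    for _, (key, _p) in _FLOAT_INFO.items():
        header.add_line(f'##INFO=<ID={key},Number=1,Type=Float,Description="{key}">')
    for key in _INT_INFO.values():
        header.add_line(f'##INFO=<ID={key},Number=1,Type=Integer,Description="{key}">')
    header.add_line('##INFO=<ID=EXT_PRESENT,Number=0,Type=Flag,Description="Present in external reference">')
    header.add_line('##INFO=<ID=CCDS,Number=0,Type=Flag,Description="In CCDS">')
    header.add_line('##INFO=<ID=DMG,Number=0,Type=Flag,Description="Predicted damaging">')
    header.add_line('##INFO=<ID=QVTRUTH,Number=0,Type=Flag,Description="Simulated qualifying-class site">')
    header.add_line('##INFO=<ID=QCFAIL,Number=1,Type=String,Description="Designated failing QC filter (simulation)">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
    for sid in sample_ids:
        header.add_sample(str(sid))
    return header


def write_vcf(
    variants: pd.DataFrame,
    calls: pd.DataFrame,
    sample_ids: Sequence[str],
    path: "str | Path",
) -> Path:
    """Write variants + long-format calls as an uncompressed VCF.

    Samples without a call row at a site are emitted as homozygous reference
    with nominal quality metrics; gt = -1 rows become missing genotypes.
    """
    path = Path(path)
    header = _vcf_header(variants, sample_ids)
    by_variant = {vid: grp for vid, grp in calls.groupby("variant_id")}
    order = variants.sort_values(["chrom", "pos"]).index
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for idx in order:
            row = variants.loc[idx]
            rec = vcf.new_record(
                contig=row["chrom"], start=int(row["pos"]) - 1,
                stop=int(row["pos"]) - 1 + len(row["ref"]),
                alleles=(row["ref"], row["alt"]),
            )
            rec.id = row["variant_id"]
            rec.qual = float(row["qual"])
            rec.filter.add(str(row.get("filter_status", "PASS")))
            rec.info["GENE"] = str(row["gene"])
            rec.info["CSQ"] = str(row["consequence"])
            for col, (key, _prec) in _FLOAT_INFO.items():
                if col in row.index and np.isfinite(row[col]):
                    rec.info[key] = float(row[col])
            for col, key in _INT_INFO.items():
                if col in row.index and pd.notna(row[col]):
                    rec.info[key] = int(row[col])
            if bool(row.get("ext_present", False)):
                rec.info["EXT_PRESENT"] = True
            if bool(row.get("ccds", False)):
                rec.info["CCDS"] = True
            if bool(row.get("predicted_damaging", False)):
                rec.info["DMG"] = True
            if bool(row.get("is_qualifying_truth", False)):
                rec.info["QVTRUTH"] = True
            fail = row.get("qc_fail_filter")
            if isinstance(fail, str) and fail:
                rec.info["QCFAIL"] = fail

            grp = by_variant.get(row["variant_id"])
            nonref = ({} if grp is None else
                      {s: (int(g), int(q), int(d), int(a))
                       for s, g, q, d, a in zip(grp["sample_id"], grp["gt"],
                                                grp["gq"], grp["dp"],
                                                grp["alt_reads"])})
            for sid in sample_ids:
                sm = rec.samples[str(sid)]
                if sid in nonref:
                    gt, gq, dp, alt = nonref[sid]
                    if gt < 0:
                        sm["GT"] = (None, None)
                    else:
                        sm["GT"] = (0, 1) if gt == 1 else (1, 1)
                        sm["GQ"] = gq
                        sm["DP"] = dp
                        sm["AD"] = (dp - alt, alt)
                else:
                    sm["GT"] = (0, 0)
                    sm["GQ"] = 50
                    sm["DP"] = 40
                    sm["AD"] = (40, 0)
            vcf.write(rec)
    return path


def read_vcf(path: "str | Path") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a VCF into (variants, calls) frames; multiallelic records are
    decomposed into biallelic rows."""
    path = Path(path)
    vrows, crows = [], []
    with pysam.VariantFile(str(path)) as vcf:
        sample_ids = list(vcf.header.samples)
        for rec in vcf:
            alts = rec.alts or ()
            for ai, alt in enumerate(alts, start=1):
                info = rec.info
                vid = (rec.id if rec.id and len(alts) == 1
                       else f"{rec.contig}-{rec.pos}-{rec.ref}-{alt}")
                row = {
                    "variant_id": vid,
                    "chrom": rec.contig, "pos": rec.pos,
                    "ref": rec.ref, "alt": alt,
                    "gene": info.get("GENE"),
                    "consequence": info.get("CSQ"),
                    "variant_class": ("indel" if len(rec.ref) != len(alt) else "SNV"),
                    "qual": round(rec.qual, 1) if rec.qual is not None else np.nan,
                    "filter_status": (list(rec.filter)[0] if list(rec.filter) else "PASS"),
                    "ccds": "CCDS" in info,
                    "ext_present": "EXT_PRESENT" in info,
                    "predicted_damaging": "DMG" in info,
                    "is_qualifying_truth": "QVTRUTH" in info,
                    "qc_fail_filter": info.get("QCFAIL"),
                }
                for col, (key, prec) in _FLOAT_INFO.items():
                    v = info.get(key)
                    row[col] = round(float(v), prec) if v is not None else np.nan
                for col, key in _INT_INFO.items():
                    v = info.get(key)
                    row[col] = int(v) if v is not None else 0
                vrows.append(row)
                for sid in sample_ids:
                    sm = rec.samples[sid]
                    gt_t = sm.get("GT")
                    if gt_t is None or all(g is None for g in gt_t):
                        if gt_t is not None:  # explicit missing call
                            crows.append((vid, sid, -1, 0, 0, 0))
                        continue
                    dose = sum(1 for g in gt_t if g == ai)
                    if dose == 0:
                        continue
                    ad = sm.get("AD")
                    alt_reads = int(ad[ai]) if ad is not None and ad[ai] is not None else 0
                    crows.append((vid, sid, dose, int(sm.get("GQ") or 0),
                                  int(sm.get("DP") or 0), alt_reads))
    variants = pd.DataFrame(vrows)
    calls = pd.DataFrame(crows, columns=["variant_id", "sample_id", "gt",
                                         "gq", "dp", "alt_reads"])
    calls = calls.sort_values(["variant_id", "sample_id"], ignore_index=True)
    return variants, calls


def write_samples_tsv(samples: pd.DataFrame, path: "str | Path") -> Path:
    path = Path(path)
    cols = [c for c in SAMPLE_COLUMNS if c in samples.columns]
    samples.to_csv(path, sep="\t", index=False, columns=cols)
    return path


def read_samples_tsv(path: "str | Path") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = {"sample_id", "sex", "icd_codes"} - set(df.columns)
    if missing:
        raise ValueError(f"sample table {path} missing columns: {sorted(missing)}")
    df["icd_codes"] = df["icd_codes"].fillna("")
    return df


def write_kinship_tsv(kinship: pd.DataFrame, path: "str | Path") -> Path:
    path = Path(path)
    kinship.to_csv(path, sep="\t", index=False,
                   columns=["sample_a", "sample_b", "kinship"])
    return path


def read_kinship_tsv(path: "str | Path") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_a": str, "sample_b": str})
    missing = {"sample_a", "sample_b", "kinship"} - set(df.columns)
    if missing:
        raise ValueError(f"kinship table {path} missing columns: {sorted(missing)}")
    return df


def write_panel_tsv(panel: pd.DataFrame, path: "str | Path") -> Path:
    path = Path(path)
    panel.to_csv(path, sep="\t", index=False,
                 columns=["gene", "inheritance", "panel_name"])
    return path


def read_panel_tsv(path: "str | Path") -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_fixture(cohort: SyntheticCohort, directory: "str | Path") -> dict:
    """Persist a synthetic cohort as VCF + TSVs; returns the file paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": directory / "cohort.vcf",
        "samples": directory / "samples.tsv",
        "kinship": directory / "kinship.tsv",
        "panel": directory / "panel.tsv",
    }
    write_vcf(cohort.variants, cohort.calls,
              cohort.samples["sample_id"].tolist(), paths["vcf"])
    write_samples_tsv(cohort.samples, paths["samples"])
    write_kinship_tsv(cohort.kinship, paths["kinship"])
    panel_rows = [
        {"gene": s.gene, "inheritance": s.inheritance, "panel_name": s.panel}
        for s in cohort.config.genes if s.inheritance
    ]
    write_panel_tsv(pd.DataFrame(panel_rows,
                                 columns=["gene", "inheritance", "panel_name"]),
                    paths["panel"])
    return {k: str(v) for k, v in paths.items()}


def read_inputs(paths: dict) -> dict:
    """Read a fixture directory's files back into in-memory frames."""
    variants, calls = read_vcf(paths["vcf"])
    out = {
        "variants": variants,
        "calls": calls,
        "samples": read_samples_tsv(paths["samples"]),
    }
    if "kinship" in paths and os.path.exists(paths["kinship"]):
        out["kinship"] = read_kinship_tsv(paths["kinship"])
    if "panel" in paths and os.path.exists(paths["panel"]):
        out["panel"] = read_panel_tsv(paths["panel"])
    return out


def results_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_record() for r in results])


def write_results_tsv(results: Sequence[AssociationResult], path: "str | Path") -> Path:
    path = Path(path)
    results_frame(results).to_csv(path, sep="\t", index=False,
                                  float_format="%.6g")
    return path
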