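"""Run orchestration: JSON configuration, stage sequencing and manifests.

``run_all`` executes cohort construction -> variant QC -> variant-level
ExWAS -> gene-level collapsing -> panel enrichment on either a simulated
cohort or files on disk, writing results TSVs, a QC report, QQ data and a
run manifest (seeds, thresholds, config hash).  All randomness flows from
named seeds in the configuration; reruns with the same configuration are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as qio
from .cohort import (CHAPTER_VII_PREFIXES, CaseControlCohort,
                     PhenotypeDefinition, build_cohort)
from .collapsing import DEFAULT_QV_MODELS, run_collapsing
from .enrichment import GenePanel, run_enrichment
from .exwas import BINARY_MODELS, run_exwas
from .synthetic import (ConfigurationError, GeneScenario, SyntheticConfig,
                        simulate_cohort)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    phenotype_name: str
    include_prefixes: list
    control_exclusion_prefixes: Optional[list] = None
    input_paths: Optional[dict] = None
    simulate: Optional[dict] = None
    qv_models: Optional[list] = None
    exwas_models: list = field(default_factory=lambda: list(BINARY_MODELS))
    seed: int = 0
    rebalance: bool = True
    apply_sample_qc: bool = True
    kinship_threshold: float = 0.3536
    enrichment_alpha: float = 0.05
    enrichment_exclude_genes: list = field(default_factory=list)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        if "phenotype" not in raw:
            raise ConfigurationError("config missing required field 'phenotype'")
        ph = raw["phenotype"]
        if "include_prefixes" not in ph or not ph["include_prefixes"]:
            raise ConfigurationError(
                "config field 'phenotype.include_prefixes' is required and non-empty")
        if "inputs" not in raw and "simulate" not in raw:
            raise ConfigurationError(
                "config must provide either 'inputs' (file paths) or 'simulate'")
        qv = raw.get("qv_models")
        if qv is not None:
            unknown = [m for m in qv if m not in DEFAULT_QV_MODELS]
            if unknown:
                raise ConfigurationError(f"unknown qv_models: {unknown}")
        ex = raw.get("exwas_models", list(BINARY_MODELS))
        unknown = [m for m in ex if m not in BINARY_MODELS]
        if unknown:
            raise ConfigurationError(f"unknown exwas_models: {unknown}")
        return cls(
            phenotype_name=ph.get("name", "phenotype"),
            include_prefixes=list(ph["include_prefixes"]),
            control_exclusion_prefixes=ph.get("control_exclusion_prefixes"),
            input_paths=raw.get("inputs"),
            simulate=raw.get("simulate"),
            qv_models=qv,
            exwas_models=ex,
            seed=int(raw.get("seed", 0)),
            rebalance=bool(raw.get("rebalance", True)),
            apply_sample_qc=bool(raw.get("apply_sample_qc", True)),
            kinship_threshold=float(raw.get("kinship_threshold", 0.3536)),
            enrichment_alpha=float(raw.get("enrichment", {}).get("alpha", 0.05)),
            enrichment_exclude_genes=list(
                raw.get("enrichment", {}).get("exclude_genes", [])),
        )

    def phenotype_definition(self) -> PhenotypeDefinition:
        excl = (frozenset(self.control_exclusion_prefixes)
                if self.control_exclusion_prefixes
                else frozenset(CHAPTER_VII_PREFIXES))
        return PhenotypeDefinition(self.phenotype_name,
                                   frozenset(self.include_prefixes), excl)


def synthetic_config_from_dict(raw: dict, seed: int) -> SyntheticConfig:
    genes = [GeneScenario(**g) for g in raw.get("genes", [])]
    return SyntheticConfig(
        n_cases=int(raw["n_cases"]),
        n_controls=int(raw["n_controls"]),
        genes=genes,
        n_strata=int(raw.get("n_strata", 1)),
        seed=int(raw.get("seed", seed)),
        qc_fail_fraction=float(raw.get("qc_fail_fraction", 0.0)),
        n_related_pairs=int(raw.get("n_related_pairs", 0)),
    )


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_all(config: RunConfig, output_dir: "str | Path") -> dict:
    """Execute the full pipeline; returns a bundle of in-memory results and
    writes TSV/JSON artifacts under ``output_dir``."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulate is not None:
        sim = simulate_cohort(synthetic_config_from_dict(config.simulate, config.seed))
        samples, variants, calls = sim.samples, sim.variants, sim.calls
        kinship = sim.kinship
        panel_df = pd.DataFrame(
            [{"gene": s.gene, "inheritance": s.inheritance, "panel_name": s.panel}
             for s in sim.config.genes if s.inheritance])
    else:
        data = qio.read_inputs(config.input_paths)
        samples, variants, calls = data["samples"], data["variants"], data["calls"]
        kinship = data.get("kinship", pd.DataFrame(
            columns=["sample_a", "sample_b", "kinship"]))
        panel_df = data.get("panel", pd.DataFrame(
            columns=["gene", "inheritance", "panel_name"]))

    definition = config.phenotype_definition()
    cohort = build_cohort(
        samples, definition, kinship_pairs=kinship,
        kinship_threshold=config.kinship_threshold,
        rebalance=config.rebalance, rebalance_seed=config.seed,
        apply_sample_qc=config.apply_sample_qc,
    )
    logger.info("cohort: %d cases / %d controls", cohort.n_cases, cohort.n_controls)

    exwas_results, exwas_lambdas = run_exwas(
        variants, calls, cohort, models=config.exwas_models)
    qio.write_results_tsv(exwas_results, out / "exwas_results.tsv")

    models = (DEFAULT_QV_MODELS if config.qv_models is None
              else {m: DEFAULT_QV_MODELS[m] for m in config.qv_models})
    collapse_results, collapse_lambdas = run_collapsing(
        variants, calls, cohort, models=models)
    qio.write_results_tsv(collapse_results, out / "collapsing_results.tsv")

    enrichment_results = []
    if len(panel_df):
        panel = GenePanel.from_frame(panel_df, name="panel")
        background = set(variants["gene"].unique())
        enrichment_results = run_enrichment(
            collapse_results, [panel], background,
            alpha=config.enrichment_alpha,
            exclude_genes=config.enrichment_exclude_genes)
        pd.DataFrame([{
            "panel": r.panel, "overlap": r.overlap, "or": r.or_,
            "ci_low": r.ci_low, "ci_high": r.ci_high, "p": r.p, "q": r.q,
        } for r in enrichment_results]).to_csv(
            out / "enrichment_results.tsv", sep="\t", index=False,
            float_format="%.6g")

    # QQ data per collapsing model (observed vs uniform-order expected)
    qq_rows = []
    df = qio.results_frame(collapse_results)
    for model, grp in df.groupby("model"):
        obs = np.sort(grp["p"].to_numpy())
        exp = (np.arange(1, len(obs) + 1) - 0.5) / len(obs)
        qq_rows.append(pd.DataFrame({"model": model, "observed_p": obs,
                                     "expected_p": exp}))
    if qq_rows:
        pd.concat(qq_rows, ignore_index=True).to_csv(
            out / "qq_data.tsv", sep="\t", index=False, float_format="%.6g")

    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "n_cases": cohort.n_cases,
        "n_controls": cohort.n_controls,
        "n_variants": int(len(variants)),
        "n_genes": int(variants["gene"].nunique()),
        "exwas_lambda_gc": exwas_lambdas,
        "collapsing_lambda_gc": collapse_lambdas,
        "qv_models": sorted(models),
        "kinship_threshold": config.kinship_threshold,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return {
        "cohort": cohort,
        "exwas": exwas_results,
        "exwas_lambdas": exwas_lambdas,
        "collapsing": collapse_results,
        "collapsing_lambdas": collapse_lambdas,
        "enrichment": enrichment_results,
        "manifest": manifest,
    }


def load_config(path: "str | Path") -> RunConfig:
    raw = json.loads(Path(path).read_text())
    return RunConfig.from_dict(raw)
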