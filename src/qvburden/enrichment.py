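"""Overrepresentation of collapsing hits among Mendelian gene panels.

Genes nominally associated (p < 0.05 in any non-synonymous qualifying-variant
model) are intersected with curated disease-gene panels, split by inheritance
(AR / AD), and tested for enrichment over the tested-gene background with a
Fisher exact test; q-values are Benjamini-Hochberg across panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd
from statsmodels.stats.multitest import multipletests

from .collapsing import NEGATIVE_CONTROL_MODELS
from .stats import AssociationResult, ContingencyTable2x2, fisher_exact_two_sided, odds_ratio_ci


@dataclass
class GenePanel:
    """A curated gene panel; ``inheritance`` maps gene -> set of labels in
    {"AR", "AD"} (biallelic -> AR, monoallelic -> AD; both allowed)."""

    name: str
    inheritance: dict

    def __post_init__(self) -> None:
        if not self.inheritance:
            raise ValueError("panel must contain at least one gene")

    @property
    def genes(self) -> set:
        return set(self.inheritance)

    def subset(self, label: str) -> set:
        return {g for g, labs in self.inheritance.items() if label in labs}

    @classmethod
    def from_frame(cls, df: pd.DataFrame, name: str = "panel") -> "GenePanel":
        inh: dict = {}
        for gene, lab in zip(df["gene"], df["inheritance"]):
            labels = {s.strip() for s in str(lab).replace("|", ",").split(",") if s.strip()}
            inh.setdefault(gene, set()).update(labels)
        return cls(name=name, inheritance=inh)


@dataclass
class EnrichmentResult:
    panel: str
    overlap: int
    or_: float
    ci_low: float
    ci_high: float
    p: float
    q: float = float("nan")
    table: Optional[ContingencyTable2x2] = None


def nominal_gene_set(
    results: Sequence[AssociationResult],
    alpha: float = 0.05,
    exclude_models: Iterable[str] = NEGATIVE_CONTROL_MODELS,
) -> set:
    """Genes reaching p < alpha in at least one non-excluded model."""
    excluded = set(exclude_models)
    return {r.target for r in results
            if r.model not in excluded and r.p < alpha}


def overrepresentation_test(
    nominal_set: set,
    panel_genes: set,
    background: set,
    panel_name: str = "panel",
    exclude_genes: Iterable[str] = (),
) -> EnrichmentResult:
    """Fisher exact enrichment of a panel within the nominal set over the
    tested-gene background.  ``exclude_genes`` (e.g. syndromes with known
    trait associations) are dropped from every set before testing."""
    if not background:
        raise ValueError("background gene set is empty")
    drop = set(exclude_genes)
    bg = set(background) - drop
    nom = (set(nominal_set) & bg)
    pan = (set(panel_genes) & bg)
    a = len(nom & pan)
    b = len(nom - pan)
    c = len(pan - nom)
    d = len(bg - nom - pan)
    table = ContingencyTable2x2(a, b, c, d)
    p = fisher_exact_two_sided(table)
    or_, lo, hi = odds_ratio_ci(table)
    return EnrichmentResult(panel=panel_name, overlap=a, or_=or_,
                            ci_low=lo, ci_high=hi, p=p, table=table)


def run_enrichment(
    results: Sequence[AssociationResult],
    panels: Sequence[GenePanel],
    background: set,
    alpha: float = 0.05,
    exclude_genes: Iterable[str] = (),
    split_inheritance: bool = True,
) -> list[EnrichmentResult]:
    """Enrichment across panels (optionally split AR/AD) with BH q-values."""
    nominal = nominal_gene_set(results, alpha=alpha)
    out: list[EnrichmentResult] = []
    for panel in panels:
        targets = ([("AR", panel.subset("AR")), ("AD", panel.subset("AD"))]
                   if split_inheritance else [("all", panel.genes)])
        for label, genes in targets:
            if not genes:
                continue
            out.append(overrepresentation_test(
                nominal, genes, background,
                panel_name=f"{panel.name}:{label}",
                exclude_genes=exclude_genes))
    if out:
        qs = multipletests([r.p for r in out], method="fdr_bh")[1]
        for r, q in zip(out, qs):
            r.q = float(q)
    return out
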