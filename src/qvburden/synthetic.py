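"""Synthetic case-control cohort generator.

Emulates the statistical structure a biobank rare-variant association study
consumes — per-arm carrier frequencies of qualifying-class alleles in each
gene, consequence / allele-frequency / missense-tolerance annotation
structure, site- and call-level QC metric distributions, ancestry strata and
ICD-style diagnosis codes — without any haplotype or read-level realism.

Carrier status is assigned per sample first (Bernoulli by case/control arm),
then each carrier is placed on one qualifying-class variant of the gene
chosen uniformly, so the marginal carrier frequency the downstream collapsing
test consumes is exactly the configured rate.  Non-qualifying variant classes
(synonymous; tolerant or common missense) receive background carriers at an
arm-independent rate so that negative-control models have signal-free counts
to work with.  A configurable fraction of variants is given metrics that
violate exactly one named QC filter (assigned round-robin), which lets QC
tests assert per-filter behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

PTV_CONSEQUENCES = frozenset({
    "stop_gained", "frameshift_variant", "splice_acceptor_variant",
    "splice_donor_variant", "start_lost", "stop_lost",
})

# site-level filters a variant can be made to fail, cycled round-robin
QC_FAIL_FILTERS = ("qual", "fs", "mq", "rprs", "mqrs", "filter_status", "ext_cov10")

_CASE_CODES = ["H330", "H332", "H334", "H338", "H33"]
_CASE_CODE_P = [0.38, 0.22, 0.02, 0.08, 0.30]
_BENIGN_CODES = ["I10", "E119", "J45", "M545", "K219"]
_ANCESTRIES = ["EUR", "SAS", "AFR", "EAS"]
_ANCESTRY_W = [0.90, 0.04, 0.04, 0.02]


class ConfigurationError(ValueError):
    pass


@dataclass
class GeneScenario:
    """Carrier-frequency and annotation structure for one simulated gene.

    ``case_carrier_freq`` / ``control_carrier_freq`` are the probabilities
    that a case / control sample carries at least one qualifying-class allele
    (PTV or missense-intolerant missense, rare in the external reference).
    ``consequence_mix`` gives the proportions of PTV / missense / synonymous
    variants among the gene's ``n_variants`` sites.
    """

    gene: str
    case_carrier_freq: float
    control_carrier_freq: float
    n_variants: int = 8
    consequence_mix: tuple[float, float, float] = (0.25, 0.5, 0.25)
    background_carrier_freq: Optional[float] = None  # default: control rate
    zygosity_mode: str = "het"  # het | hom | compound_het
    damaging_fraction: float = 0.6
    inheritance: Optional[str] = None  # AR / AD, for the panel fixture
    panel: str = "synthetic_eye_panel"

    def __post_init__(self) -> None:
        for f in (self.case_carrier_freq, self.control_carrier_freq):
            if not 0.0 <= f <= 1.0:
                raise ConfigurationError(f"carrier frequency {f} outside [0,1]")
        if self.n_variants < 1:
            raise ConfigurationError("n_variants must be >= 1")
        if abs(sum(self.consequence_mix) - 1.0) > 1e-9:
            raise ConfigurationError("consequence_mix must sum to 1")
        if self.zygosity_mode not in {"het", "hom", "compound_het"}:
            raise ConfigurationError(f"unknown zygosity_mode {self.zygosity_mode!r}")

    @property
    def effective_background_freq(self) -> float:
        if self.background_carrier_freq is None:
            return self.control_carrier_freq
        return self.background_carrier_freq


@dataclass
class SyntheticConfig:
    n_cases: int
    n_controls: int
    genes: Sequence[GeneScenario]
    n_strata: int = 1
    seed: int = 0
    qc_fail_fraction: float = 0.0
    n_related_pairs: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ConfigurationError("n_cases and n_controls must be >= 1")
        if not 0 <= self.qc_fail_fraction <= 1:
            raise ConfigurationError("qc_fail_fraction outside [0,1]")
        if not 1 <= self.n_strata <= len(_ANCESTRIES):
            raise ConfigurationError(f"n_strata must be in [1,{len(_ANCESTRIES)}]")


@dataclass
class SyntheticCohort:
    """In-memory bundle: sample metadata, variant annotations, genotype calls
    (long format: one row per non-reference call), kinship pairs."""

    samples: pd.DataFrame
    variants: pd.DataFrame
    calls: pd.DataFrame
    kinship: pd.DataFrame
    config: SyntheticConfig

    @property
    def case_ids(self) -> set:
        return set(self.samples.loc[self.samples["arm"] == "case", "sample_id"])

    @property
    def control_ids(self) -> set:
        return set(self.samples.loc[self.samples["arm"] == "control", "sample_id"])


def _simulate_samples(cfg: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_cases + cfg.n_controls
    arm = np.array(["case"] * cfg.n_cases + ["control"] * cfg.n_controls)
    sample_id = np.array([f"S{i:06d}" for i in range(n)])
    sex = np.where(rng.random(n) < 0.56, "male", "female")
    age = np.round(np.clip(rng.normal(60, 8, n), 40, 85)).astype(int)
    w = np.asarray(_ANCESTRY_W[: cfg.n_strata])
    ancestry = rng.choice(_ANCESTRIES[: cfg.n_strata], size=n, p=w / w.sum())
    ancestry_prob = np.round(0.92 + 0.08 * rng.random(n), 4)
    pcs = np.round(rng.normal(0, 1, size=(n, 4)), 4)
    freemix = np.round(rng.uniform(0, 0.03, n), 4)
    cov10 = np.round(rng.uniform(0.95, 1.0, n), 4)

    case_codes = rng.choice(_CASE_CODES, size=n, p=_CASE_CODE_P)
    benign = rng.choice(_BENIGN_CODES, size=n)
    has_benign = rng.random(n) < 0.30
    codes = np.where(arm == "case", case_codes, np.where(has_benign, benign, ""))

    has_refr = rng.random(n) < 0.5
    sph = np.round(rng.normal(-0.5, 2.0, size=(n, 2)), 2)
    cyl = np.round(rng.normal(-0.25, 0.5, size=(n, 2)), 2)

    df = pd.DataFrame({
        "sample_id": sample_id,
        "arm": arm,
        "sex": sex,
        "age": age,
        "ancestry": ancestry,
        "ancestry_prob": ancestry_prob,
        "pc1": pcs[:, 0], "pc2": pcs[:, 1], "pc3": pcs[:, 2], "pc4": pcs[:, 3],
        "icd_codes": codes,
        "sph_r": np.where(has_refr, sph[:, 0], np.nan),
        "cyl_r": np.where(has_refr, cyl[:, 0], np.nan),
        "sph_l": np.where(has_refr, sph[:, 1], np.nan),
        "cyl_l": np.where(has_refr, cyl[:, 1], np.nan),
        "freemix": freemix,
        "ccds_cov10_fraction": cov10,
    })
    return df


def _simulate_gene_variants(
    scen: GeneScenario, gene_index: int, rng: np.random.Generator
) -> pd.DataFrame:
    n = scen.n_variants
    n_ptv = int(round(scen.consequence_mix[0] * n))
    n_syn = int(round(scen.consequence_mix[2] * n))
    n_mis = n - n_ptv - n_syn
    if n_mis < 0:
        n_mis, n_syn = 0, n - n_ptv
    cons = (["stop_gained", "frameshift_variant"] * ((n_ptv + 1) // 2))[:n_ptv]
    cons += ["missense_variant"] * n_mis + ["synonymous_variant"] * n_syn

    chrom = f"chr{(gene_index % 22) + 1}"
    pos = 1_000_000 + 50_000 * gene_index + 120 * np.arange(n)
    is_indel = np.array([c == "frameshift_variant" for c in cons])
    ref = np.where(is_indel, "AT", "G")
    alt = np.where(is_indel, "A", "T")

    mtr_exome_pct = np.round(rng.uniform(0, 100, n), 2)
    mtr_gene_pct = np.round(rng.uniform(0, 100, n), 2)
    mtr = np.round(0.2 + 0.75 * mtr_exome_pct / 100 + rng.normal(0, 0.02, n), 4)

    is_ptv = np.array([c in PTV_CONSEQUENCES for c in cons])
    is_mis = np.array([c == "missense_variant" for c in cons])
    mtr_ok = (mtr_exome_pct <= 25) | (mtr_gene_pct <= 50)
    qualifying = is_ptv | (is_mis & mtr_ok)
    if not qualifying.any() and (scen.case_carrier_freq > 0 or scen.control_carrier_freq > 0):
        # force an intolerant first missense (or the first site) so the
        # configured carrier rate has somewhere to live
        mtr_exome_pct[0] = 10.0
        mtr_ok = (mtr_exome_pct <= 25) | (mtr_gene_pct <= 50)
        qualifying = is_ptv | (is_mis & mtr_ok)
        if not qualifying.any():
            qualifying[0] = True

    # external reference: qualifying sites rare (or absent), synonymous free-range
    ext_present = rng.random(n) > np.where(qualifying, 0.3, 0.05)
    ext_af = np.where(
        qualifying,
        10 ** rng.uniform(-6, -4, n),
        10 ** rng.uniform(-6, -2, n),
    )
    ext_af = np.round(np.where(ext_present, ext_af, 0.0), 8)
    ext_ac_raw = np.where(ext_present, np.maximum(1, np.round(ext_af * 251_496)), 0).astype(int)
    ext_ac = ext_ac_raw.copy()
    damaging = rng.random(n) < np.where(is_mis, scen.damaging_fraction, 0.0)
    damaging |= is_ptv

    return pd.DataFrame({
        "variant_id": [f"{chrom}-{p}-{r}-{a}" for p, r, a in zip(pos, ref, alt)],
        "chrom": chrom,
        "pos": pos,
        "ref": ref,
        "alt": alt,
        "gene": scen.gene,
        "consequence": cons,
        "variant_class": np.where(is_indel, "indel", "SNV"),
        "qual": np.round(rng.uniform(50, 3000, n), 1),
        "fs": np.round(rng.uniform(0, 30, n), 2),
        "mq": np.round(rng.uniform(50, 60, n), 2),
        "rprs": np.round(np.clip(rng.normal(0, 0.5, n), -1.5, 1.5), 3),
        "mqrs": np.round(np.clip(rng.normal(0, 1.0, n), -3.0, 3.0), 3),
        "filter_status": "PASS",
        "ccds": True,
        "ext_present": ext_present,
        "ext_af": ext_af,
        "ext_ac": ext_ac,
        "ext_ac_raw": ext_ac_raw,
        "ext_cov10_frac": np.round(rng.uniform(0.8, 1.0, n), 4),
        "ext_rprs": np.round(rng.normal(0, 0.5, n), 3),
        "ext_mq": np.round(rng.uniform(45, 60, n), 2),
        "mtr": mtr,
        "mtr_exome_pct": mtr_exome_pct,
        "mtr_gene_pct": mtr_gene_pct,
        "predicted_damaging": damaging,
        "is_qualifying_truth": qualifying,
    })


def _call_metrics(n_calls: int, gt: np.ndarray, rng: np.random.Generator):
    """Depth/GQ/AD metrics that pass both QC profiles."""
    dp = np.clip(rng.poisson(40, n_calls), 12, None)
    gq = rng.integers(30, 100, n_calls)
    lo = np.ceil(0.30 * dp).astype(int)
    hi = np.floor(0.70 * dp).astype(int)
    alt = np.clip(rng.binomial(dp, 0.5), lo, hi)
    alt = np.where(gt == 2, dp, alt)
    return gq, dp, alt


def _simulate_gene_calls(
    scen: GeneScenario,
    gene_variants: pd.DataFrame,
    samples: pd.DataFrame,
    rng: np.random.Generator,
) -> list[pd.DataFrame]:
    """Carrier assignment for one gene: qualifying-class carriers by arm, plus
    arm-independent background carriers on non-qualifying sites."""
    out = []
    n = len(samples)
    is_case = (samples["arm"] == "case").to_numpy()
    sample_ids = samples["sample_id"].to_numpy()

    qual_ids = gene_variants.loc[gene_variants["is_qualifying_truth"], "variant_id"].to_numpy()
    freq = np.where(is_case, scen.case_carrier_freq, scen.control_carrier_freq)
    carrier = rng.random(n) < freq
    idx = np.flatnonzero(carrier)
    if idx.size and qual_ids.size:
        if scen.zygosity_mode == "compound_het" and qual_ids.size >= 2:
            k = qual_ids.size
            v1 = rng.integers(0, k, idx.size)
            v2 = (v1 + 1 + rng.integers(0, k - 1, idx.size)) % k  # distinct
            df = pd.DataFrame({
                "variant_id": np.concatenate([qual_ids[v1], qual_ids[v2]]),
                "sample_id": np.concatenate([sample_ids[idx], sample_ids[idx]]),
                "gt": 1,
            })
        else:
            gt = 2 if scen.zygosity_mode == "hom" else 1
            df = pd.DataFrame({
                "variant_id": qual_ids[rng.integers(0, qual_ids.size, idx.size)],
                "sample_id": sample_ids[idx],
                "gt": gt,
            })
        out.append(df)

    bg = scen.effective_background_freq
    for mask in (
        gene_variants["consequence"].eq("synonymous_variant"),
        gene_variants["consequence"].eq("missense_variant") & ~gene_variants["is_qualifying_truth"],
    ):
        vids = gene_variants.loc[mask, "variant_id"].to_numpy()
        if bg <= 0 or vids.size == 0:
            continue
        bidx = np.flatnonzero(rng.random(n) < bg)
        if bidx.size:
            out.append(pd.DataFrame({
                "variant_id": vids[rng.integers(0, vids.size, bidx.size)],
                "sample_id": sample_ids[bidx],
                "gt": 1,
            }))
    return out


def _apply_qc_failures(variants: pd.DataFrame, fraction: float,
                       rng: np.random.Generator) -> pd.DataFrame:
    variants = variants.copy()
    variants["qc_fail_filter"] = None
    k = int(round(fraction * len(variants)))
    if k == 0:
        return variants
    chosen = np.sort(rng.choice(len(variants), size=k, replace=False))
    for j, row in enumerate(chosen):
        filt = QC_FAIL_FILTERS[j % len(QC_FAIL_FILTERS)]
        i = variants.index[row]
        variants.loc[i, "qc_fail_filter"] = filt
        if filt == "qual":
            variants.loc[i, "qual"] = 15.0
        elif filt == "fs":
            # exceeds the SNV bound; keep the record an SNV so it fails
            variants.loc[i, ["variant_class", "ref", "alt"]] = ["SNV", "G", "T"]
            variants.loc[i, "fs"] = 250.0
        elif filt == "mq":
            variants.loc[i, "mq"] = 30.0
        elif filt == "rprs":
            variants.loc[i, "rprs"] = -3.0
        elif filt == "mqrs":
            variants.loc[i, "mqrs"] = -9.0
        elif filt == "filter_status":
            variants.loc[i, "filter_status"] = "LowQual"
        elif filt == "ext_cov10":
            variants.loc[i, "ext_cov10_frac"] = 0.05
    return variants


def simulate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort; output is a pure function of the
    configuration (including its seed)."""
    rng = np.random.default_rng(config.seed)
    samples = _simulate_samples(config, rng)

    variant_frames, call_frames = [], []
    for gi, scen in enumerate(config.genes):
        gv = _simulate_gene_variants(scen, gi, rng)
        variant_frames.append(gv)
        call_frames.extend(_simulate_gene_calls(scen, gv, samples, rng))

    if variant_frames:
        variants = pd.concat(variant_frames, ignore_index=True)
    else:
        variants = _simulate_gene_variants(
            GeneScenario("EMPTY", 0, 0, n_variants=1), 0, rng).iloc[0:0]
    variants = _apply_qc_failures(variants, config.qc_fail_fraction, rng)

    if call_frames:
        calls = pd.concat(call_frames, ignore_index=True)
        # one row per (variant, sample); duplicates from overlapping background
        # draws collapse to the higher genotype
        calls = (calls.groupby(["variant_id", "sample_id"], as_index=False)["gt"].max())
        calls = calls.sort_values(["variant_id", "sample_id"], ignore_index=True)
        gq, dp, alt = _call_metrics(len(calls), calls["gt"].to_numpy(), rng)
        calls["gq"] = gq
        calls["dp"] = dp
        calls["alt_reads"] = alt
    else:
        calls = pd.DataFrame(columns=["variant_id", "sample_id", "gt", "gq", "dp", "alt_reads"])

    kin_rows = []
    controls = samples.loc[samples["arm"] == "control", "sample_id"].to_numpy()
    for _ in range(config.n_related_pairs):
        a, b = rng.choice(controls.size, size=2, replace=False)
        kin_rows.append((controls[a], controls[b], round(rng.uniform(0.36, 0.45), 4)))
    kinship = pd.DataFrame(kin_rows, columns=["sample_a", "sample_b", "kinship"])

    return SyntheticCohort(samples=samples, variants=variants, calls=calls,
                           kinship=kinship, config=config)


def vsx2_like_scenario(seed: int = 0,
                       n_cases: int = 7276,
                       n_controls: int = 236_741) -> SyntheticConfig:
    """The headline gene-level scenario: qualifying-class carrier frequencies
    0.0074 in cases vs 0.0027 in controls at the full discovery cohort size."""
    return SyntheticConfig(
        n_cases=n_cases,
        n_controls=n_controls,
        genes=[GeneScenario("VSX2L", 0.0074, 0.0027, n_variants=21,
                            consequence_mix=(0.3, 0.5, 0.2), inheritance="AR")],
        seed=seed,
    )
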