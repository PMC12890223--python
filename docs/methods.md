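# Methods

`qvburden` implements a rare-variant case-control association framework of
the kind used for biobank-scale sequencing studies: a variant-level
exome-wide association scan (ExWAS) across the allele-frequency spectrum,
and a gene-level *collapsing* analysis in which rare "qualifying variants"
(QVs) are aggregated per gene and carrier proportions are compared between
cases and controls. Everything runs on synthetic cohorts generated by the
package itself, so no access-controlled data are required.

## Statistical model

All binary-trait association reduces to a 2x2 carrier-by-status table
(a = case carriers, b = case non-carriers, c = control carriers,
d = control non-carriers):

* **p-value** — two-sided Fisher exact test under the point-probability
  convention: with margins fixed, p is the sum of hypergeometric
  probabilities of all tables whose point probability does not exceed the
  observed table's. A table with a zero margin carries no information and
  returns p = 1 (logged).
* **Effect size** — the raw cross-product odds ratio ad/bc with a Woolf
  (log-scale normal) 95% CI, exp(ln OR ± z·sqrt(1/a + 1/b + 1/c + 1/d)).
  z defaults to 1.96: the two-decimal convention reproduces published Woolf
  bounds (e.g. 743.7 for the (10, 7266, 2, 236739) table) where the exact
  quantile 1.95996 rounds one printed digit away. When any cell is zero the
  Haldane-Anscombe correction (add 0.5 to every cell) is applied to both
  the estimate and the interval. A conditional-MLE exact CI
  (`conditional_exact_ci`, R's `fisher.test` convention) is also exposed as
  a cross-check; it is the convention that matches the published
  leave-one-variant-out interval, whereas the Woolf interval matches every
  other published bound.
* **Stratified meta-analysis** — the Cochran-Mantel-Haenszel 1-df
  chi-square without continuity correction (large strata), with the
  Mantel-Haenszel common odds ratio sum(a·d/n) / sum(b·c/n). Strata with no
  carriers anywhere contribute no information; an all-carrier-free set of
  strata returns p = 1 with an undefined common OR.
* **Quantitative traits** — OLS of the trait on carrier status or genotype
  dosage (0/1/2) with age and sex as covariates; a logistic model with
  covariates supports sensitivity analyses conditioning on a quantitative
  risk factor (e.g. refractive error). A binary carrier predictor with a
  zero cell in its carrier-by-status table has an infinite MLE; this raises
  a separation error directing the caller to the exact test.
* **Calibration** — genomic inflation lambda_GC = median chi-square(1 df)
  quantile of the observed p-values / 0.4549; an "n-of-1" permutation of
  case/control labels (case count preserved, seeded) re-runs the test
  battery once to produce an empirical null p-value distribution for QQ
  comparison.

p-values are floored at 1e-300 to avoid log-scale underflow.

## Qualifying-variant models

A QV model is a declarative predicate: consequence classes (PTV =
stop-gain, frameshift, essential splice, start/stop-loss; missense;
synonymous), internal and external MAF caps, a missense-tolerance-ratio
(MTR) sub-region rule (exome-wide percentile <= 25 OR intragenic percentile
<= 50, applied to missense only; PTVs are exempt; sites without MTR
annotation do not satisfy the rule), a predicted-deleteriousness rule
(consumed as a boolean annotation, never computed), an
external-reference-absence requirement (ultra-rare models), and a zygosity
coding. Ten models ship as defaults (`ptv`, `UR`, `URmtr`, `raredmg`,
`raredmgmtr`, `flexdmg`, `flexnonsynmtr`, `ptvraredmg`, `rec`, `syn`); the
`syn` synonymous model is the empirical negative control and is excluded
from enrichment aggregation. MAF caps default to 0.1% internal and
external; the qualifying condition requires both the in-cohort MAF
(computed on the combined case+control cohort after call QC) and the
external reference AF to sit at or below their caps. Thresholds that the
underlying study describes only in supplementary material (the ultra-rare
internal cap, per-model deleteriousness cutoffs) are package defaults,
clearly configurable, and not asserted to be the study's exact values.

Carrier coding: **dominant** — at least one het or hom-alt QV genotype;
**recessive** — at least one hom-alt QV genotype, or het genotypes at two
or more distinct QVs (putative compound heterozygote; phase is not
observed, so this is a deliberate over-call). Carrier counting is
idempotent under duplicated variant records and invariant to variant order.

The significance threshold for the genome-wide scan is p < 1e-8. The
leave-one-variant-out sensitivity re-run removes carriers of a named
variant from both arms — numerators *and* denominators — and recomputes the
gene test on the reduced cohort.

## Quality control

Two profiles, applied as call-level filters (failing calls become missing
genotypes, never excluded samples) plus site-level filters:

| filter | exwas | collapsing |
| --- | --- | --- |
| depth >= 10, GQ >= 20 | yes | yes |
| het alt-read fraction | >= 0.20 | in [0.25, 0.80] |
| hom-alt alt-read fraction | - | >= 0.80 |
| het allele-balance binomial p | >= 1e-6 | >= 1e-6 |
| QUAL >= 30; FS <= 60 (SNV) / 200 (indel); MQ >= 40; RPRS >= -2; MQRS >= -8; caller FILTER = PASS | yes | yes |
| cohort missingness <= 10% | yes | (call-level only) |
| CCDS membership | - | yes |
| external >= 10x coverage fraction | >= 0.30 | >= 0.25 |
| external AC >= 50% of raw AC (when present) | yes | - |
| external RPRS >= -2 and MQ >= 30 (when present) | - | yes |

Metrics with missing values pass the corresponding filter. A variant enters
the ExWAS only if at least six samples carry the minor allele after call QC
and no more than 20,000 calls were set missing by QC (both configurable).
An exact Hardy-Weinberg mid-p filter (> 1e-5) is available as an optional
flag for replication-style profiles and is off by default. Multiallelic
records are decomposed to biallelic records (AD re-attributed) at read
time; coordinates are 1-based VCF convention.

## Cohort construction

Phenotypes are unions of ICD-10-style code prefixes over dot-stripped,
upper-cased codes ("H33 and all sub-codes" = prefix `H33`; the default
retinal-detachment definition uses H33, with H33.0/H33.2 as subtype
definitions). Controls exclude anyone with a code under Chapter VII
(prefixes H00-H59), which structurally guarantees case/control
disjointness. Sample QC retains FREEMIX < 0.04, >= 10x coverage over >=
94.5% of CCDS, ancestry probability >= 0.90, and all of PC1-4 within 4 SD
of the mean, with PC moments computed per ancestry group on the
probability-passing subset (the probability gate precedes the PC gate).
Samples missing sex or diagnosis codes are dropped with a logged warning.

Kinship pruning (pairs above 0.3536) is a three-step greedy procedure:
resolve case-case pairs, drop controls related to remaining cases, resolve
control-control pairs; within a step the sample of highest remaining
relatedness degree is removed iteratively, ties broken toward the
lexicographically larger identifier. The true "largest unrelated subset" is
a maximum independent set (NP-hard); greedy max-degree removal is the
standard surrogate and the output is verified to contain no over-threshold
pair.

Sex rebalancing triggers when the two-sided exact p of the sex-by-status
table falls below 0.05; controls of the over-represented sex (generalised
from the study's female-control case) are removed by seeded uniform
sampling until the control male:female odds equal the case odds as nearly
as integers allow. Cases are never removed; single-sex case sets raise an
explicit error.

Mean spherical equivalent (MSE), in diopters: per-eye spherical power +
0.5 x cylindrical power, averaged over eyes with complete refractometry;
absent when neither eye is complete.

## Synthetic cohorts

The generator emulates exactly the statistical structure the analysis
consumes. Carrier status is assigned per sample (Bernoulli by arm at the
configured qualifying-carrier frequency), then each carrier is placed on a
uniformly chosen qualifying-class site of the gene — so the marginal
carrier frequency is the configured rate by construction. One variant per
carrier is the default; `compound_het` and `hom` modes produce recessive
structure. Non-qualifying classes (synonymous; tolerant or common
missense) receive arm-independent background carriers so negative-control
models have counts. MTR percentiles are uniform on [0, 100] (about 62.5%
of missense sites satisfy the intolerance rule); external AFs are
log-uniform, below the caps for qualifying classes and free-range
otherwise, with ~30% of qualifying sites absent from the external
reference. A configured fraction of variants receives metrics violating
exactly one named site filter, assigned round-robin, so QC tests can
assert per-filter behaviour. Sample metadata mirror the study's
demographics (median age ~60, 56% male cases, sex-matched controls,
ancestry weights ~0.90/0.04/0.04/0.02 over EUR/SAS/AFR/EAS, retinal
ICD codes with a ~22% serous fraction among cases).

Not emulated: linkage disequilibrium, phased haplotypes, read-level error,
relatedness structure beyond injected over-threshold pairs, and
population-specific allele-frequency differences (carrier rates are
identical across strata). Passing tests therefore demonstrate the
correctness and calibration of the *analysis machinery* under the assumed
sampling model, not robustness to confounding present in real cohorts.

## Validation study designs

* **Null calibration** — 4,000 genes at equal carrier frequency 0.04 in
  both arms, 2,500 cases / 7,500 controls, 100 sites per gene, compound-het
  carriers. Two constraints set these sizes. First, the Fisher exact test
  is conservative at small expected counts (its discreteness depresses
  lambda_GC well below 1); the frequency keeps *every* QV model — including
  those selecting small site subsets (external-absent,
  damaging-and-intolerant) — at expected carrier counts of order 100 per
  arm, beyond which the conservatism plateaus at a true lambda around
  0.94-0.96 (measured by direct simulation). Second, the per-model lambda
  is a sample median with standard error ~0.07 at 1,000 genes, scaling as
  1/sqrt(n_genes); 4,000 genes put the [0.85, 1.15] band at ~2.5 sigma
  from the plateau. One hundred sites per gene keep each site's allele
  frequency safely under the 0.1% cap. Expected behaviour: per-model
  lambda in [0.85, 1.15]; no synonymous-model p < 1e-8.
* **Parameter recovery** — 200 replicates of the headline gene scenario
  (carrier frequencies 0.0074 cases vs 0.0027 controls, 7,276 / 236,741
  samples, 21 sites); the generative odds ratio
  (0.0074/0.9926)/(0.0027/0.9973) = 2.754 should fall inside the Woolf 95%
  CI in ~95% of replicates (checked within 3 binomial SE).
* **Published-table reconstruction** — deterministic cohorts place exactly
  the published carrier counts (54/634 gene-level, 21/116 lead-variant with
  2/82 missing genotypes, 10/2 PTV) into cohorts of the published sizes;
  running the collapsing / ExWAS machinery end-to-end must reproduce the
  published p-values, odds ratios and intervals. Secondary carriers are
  spread over 20 sites so each site respects the internal MAF cap.

## Numerical and design notes

* Exact tests, CMH, regressions and FDR come from scipy/statsmodels; the
  test suite verifies the exact tests against independent exact-rational
  enumeration oracles (all tables with N <= 40), the CMH against its
  closed-form statistic, and the vectorized allele-balance path against
  the scalar path.
* The vectorized allele-balance p-value uses the symmetry of the p = 0.5
  binomial null: the point-probability two-sided p equals
  2·P(X <= min(k, n-k)) capped at 1.
* Minor-allele orientation: if the alternate allele frequency exceeds 0.5
  the tables are built over reference-allele carriers. "Seen in at least
  six individuals" is interpreted as >= 6 samples carrying the minor allele
  (not allele count >= 6); configurable.
* ExWAS tables are built over samples with a non-missing post-QC genotype
  (the published carrier denominators 7,274 / 236,659 are non-missing
  counts); collapsing carrier tables use the full cohort denominators.
* The enrichment background defaults to the set of genes tested in the
  collapsing run; panels are split biallelic -> AR, monoallelic -> AD
  (genes may carry both), with Benjamini-Hochberg q-values across panel
  tests and a configurable exclusion list for genes with established trait
  associations.
* All randomness flows from named seeds (simulation, rebalancing,
  permutation); reruns with identical configuration are byte-identical.
* The MSE-conditioned sensitivity model is logistic regression on carrier
  status + MSE (optionally age/sex); the underlying study does not name its
  method, so the covariate set is configuration, not assertion.

## Known limitations

Greedy kinship pruning is not guaranteed maximal; recessive carrier calls
over-count unphased cis double-hets; the CMH CI reported for pan-ancestry
results is the Woolf interval of the margin-summed table (descriptive, not
the exact stratified interval); enrichment p-values inherit the usual
caveats of overlapping panels tested against a shared background.
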