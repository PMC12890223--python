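import numpy as np
import pandas as pd
import pytest

from qvburden.cohort import CaseControlCohort, PhenotypeDefinition
from qvburden.synthetic import GeneScenario, SyntheticConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 300/700 cohort with one enriched gene, one null gene and QC-failing
    variants; small enough for per-test reuse."""
    cfg = SyntheticConfig(
        n_cases=300,
        n_controls=700,
        genes=[
            GeneScenario("RISK1", 0.05, 0.01, n_variants=40),
            GeneScenario("NULL1", 0.01, 0.01, n_variants=40),
        ],
        seed=42,
        qc_fail_fraction=0.2,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_case_control(small_cohort):
    s = small_cohort.samples
    return CaseControlCohort(
        case_ids=set(s.loc[s["arm"] == "case", "sample_id"]),
        control_ids=set(s.loc[s["arm"] == "control", "sample_id"]),
        phenotype=PhenotypeDefinition("rd", frozenset({"H33"})),
    )


def make_samples(rows):
    """Helper: sample table from compact dicts with generator defaults."""
    defaults = dict(
        arm="control", sex="female", age=60, ancestry="EUR",
        ancestry_prob=0.99, pc1=0.0, pc2=0.0, pc3=0.0, pc4=0.0,
        icd_codes="", sph_r=np.nan, cyl_r=np.nan, sph_l=np.nan, cyl_l=np.nan,
        freemix=0.01, ccds_cov10_fraction=0.99,
    )
    return pd.DataFrame([{**defaults, **r} for r in rows])
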