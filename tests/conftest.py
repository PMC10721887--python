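import numpy as np
import pandas as pd
import pytest

from penetrax.filtering import RareGenotypes
from penetrax.pipeline import RunConfig, run_pipeline
from penetrax.simulate import CohortSpec, SimConfig, simulate_cohort

# relaxed frequency ceilings used by small-n fixtures: the production
# ultra-rare ADPKD ceiling (1e-5) only admits planted carriers at
# biobank-scale n, so scaled-down fixtures scale the ceiling too
RELAXED_THRESHOLDS = {g: 5e-3 for g in ("PKD1", "PKD2", "COL4A3", "COL4A4", "COL4A5")}


def small_sim_config(seed=11, n1=4000, n2=3000, **overrides) -> SimConfig:
    kw = dict(
        cohorts=[
            CohortSpec("cohort1", n_participants=n1, age_range=(40, 69)),
            CohortSpec(
                "cohort2",
                n_participants=n2,
                ancestry_mixture={"EUR": 0.43, "AFR": 0.21, "EAS": 0.04,
                                  "SAS": 0.15, "AMR": 0.17},
                age_range=(18, 89),
                female_fraction=0.60,
            ),
        ],
        carrier_frequency={"adpkd": 0.02, "col4a": 0.02},
        maf_thresholds=dict(RELAXED_THRESHOLDS),
        baseline_case_rate=0.08,
        seed=seed,
    )
    kw.update(overrides)
    return SimConfig(**kw)


@pytest.fixture(scope="session")
def small_study():
    """One deterministic small two-cohort study shared across tests."""
    return simulate_cohort(small_sim_config())


@pytest.fixture(scope="session")
def small_pipeline(small_study):
    """Full pipeline result on the shared small study."""
    return run_pipeline(RunConfig(sim=small_study.config), study=small_study)


def toy_rare(gt, genes=None, chroms=None, sex=None, gq=None, dp=None):
    """Build a RareGenotypes from a plain genotype matrix."""
    gt = np.asarray(gt, dtype=np.int8)
    n, m = gt.shape
    genes = list(genes) if genes is not None else ["PKD1"] * m
    chroms = list(chroms) if chroms is not None else ["X" if g == "COL4A5" else "1"
                                                      for g in genes]
    variants = pd.DataFrame({
        "variant_id": [f"v{j}" for j in range(m)],
        "gene": genes,
        "chrom": chroms,
        "pos": np.arange(m) * 100 + 1,
        "ref": "A",
        "alt": "T",
    })
    return RareGenotypes(
        variants=variants,
        samples=np.array([f"s{i}" for i in range(n)]),
        gt=gt,
        gq=None if gq is None else np.asarray(gq, dtype=np.int16),
        dp=None if dp is None else np.asarray(dp, dtype=np.int16),
        sex=None if sex is None else np.asarray(sex),
    )


def base_annotation(**overrides) -> dict:
    """One fully-specified annotation row; override per test."""
    row = {
        "variant_id": "v0",
        "gene": "PKD1",
        "consequence": "missense",
        "revel": 0.1,
        "sift": "tolerated",
        "polyphen2_hdiv": "tolerated",
        "polyphen2_hvar": "tolerated",
        "lrt": "tolerated",
        "mutation_taster": "tolerated",
        "clinvar_assertion": "none",
        "clinvar_n_submitters": 0,
        "clinvar_conflict_flag": False,
        "varsome_assertion": "none",
        "af_gnomad_eur": 1e-6,
    }
    row.update(overrides)
    return row
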