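"""Shared fixtures: small simulated cohorts reused across test modules."""

import pandas as pd
import pytest

from urinprot.qc_filtering import ImputeParams, run_qc_pipeline
from urinprot.synthetic_cohort import SimConfig, simulate_human_cohorts


@pytest.fixture(scope="session")
def recovery_sim():
    """Single-cohort scenario with 20 planted dosage effects of 0.8 log2/dosage."""
    config = SimConfig(
        n_proteins=500,
        n_samples_per_cohort={"PPMI": 300},
        n_signature_proteins=20,
        effect_size_per_dosage=0.8,
        variant_table=[("G2019S", "LRRK2", 0.15)],
        seed=5,
    )
    matrix, meta, genotypes, truth = simulate_human_cohorts(config)
    return config, matrix, meta, genotypes, truth


@pytest.fixture(scope="session")
def recovery_clean(recovery_sim):
    """QC-processed version of the recovery scenario."""
    config, matrix, meta, genotypes, truth = recovery_sim
    clean, clean_meta, report = run_qc_pipeline(
        matrix, meta, impute_params=ImputeParams(seed=config.seed)
    )
    genotypes.dosages = genotypes.dosages.reindex(clean.sample_ids)
    return clean, clean_meta, genotypes, truth, report


@pytest.fixture(scope="session")
def small_multicohort():
    """Two-cohort dataset for split/classifier plumbing tests."""
    config = SimConfig(
        n_proteins=200,
        n_samples_per_cohort={"PPMI": 120, "LCC": 80},
        n_signature_proteins=15,
        variant_table=[("G2019S", "LRRK2", 0.3)],
        seed=11,
    )
    matrix, meta, genotypes, truth = simulate_human_cohorts(config)
    clean, clean_meta, _ = run_qc_pipeline(
        matrix, meta, impute_params=ImputeParams(seed=11)
    )
    labels = (genotypes.dosages.reindex(clean.sample_ids)["G2019S"] > 0).astype(int)
    return clean, clean_meta, pd.Series(labels, index=clean.sample_ids), truth
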