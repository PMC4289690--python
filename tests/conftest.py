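import numpy as np
import pandas as pd
import pytest

from crosspheno.datatypes import GenotypePanel, StudySummary
from crosspheno.simulate import CohortSpec, SimulationConfig, simulate_cohorts


def make_summary(study_id="S1", disease="AD", n=3, seed=0, **kwargs):
    """Small well-formed StudySummary for plumbing tests."""
    rng = np.random.default_rng(seed)
    table = pd.DataFrame({
        "SNP": [f"rs{i}" for i in range(1, n + 1)],
        "CHR": "1",
        "POS": np.arange(1, n + 1) * 1000,
        "EA": "A",
        "OA": "G",
        "EAF": rng.uniform(0.1, 0.9, n),
        "BETA": rng.normal(0, 0.2, n),
        "SE": rng.uniform(0.05, 0.2, n),
        "P": rng.uniform(1e-4, 1, n),
        "N_CASES": 500,
        "N_CONTROLS": 1000,
        "INFO": rng.uniform(0.5, 1, n),
    })
    return StudySummary(study_id=study_id, disease=disease, table=table,
                        **kwargs)


def hwe_panel(n_samples, eafs, seed=0, phenotype=None):
    """Independent Hardy-Weinberg genotypes, no LD."""
    rng = np.random.default_rng(seed)
    eafs = np.asarray(eafs, dtype=float)
    dosages = rng.binomial(2, eafs, size=(n_samples, len(eafs))).astype(float)
    variants = pd.DataFrame({
        "SNP": [f"v{i}" for i in range(len(eafs))],
        "CHR": "1",
        "POS": np.arange(1, len(eafs) + 1) * 1000,
        "EA": "A", "OA": "G",
    })
    return GenotypePanel(
        sample_ids=np.array([f"s{i}" for i in range(n_samples)]),
        phenotype=(np.full(n_samples, "control", dtype=object)
                   if phenotype is None else phenotype),
        dosages=dosages, variants=variants)


@pytest.fixture(scope="session")
def small_cohort_data():
    """One shared individual-level simulation reused across tests."""
    config = SimulationConfig(
        seed=11,
        n_variants={"AD_only": 6, "PSO_only": 6, "shared": 6,
                    "opposing": 6, "null": 16},
        ld_block_len=2,
    )
    panels, truth = simulate_cohorts(config)
    return config, panels, truth


@pytest.fixture(scope="session")
def tiny_cohorts():
    return [
        CohortSpec("AD_1", "AD", "general", 0.005, 150, 300),
        CohortSpec("AD_2", "AD", "childhood", 0.01, 150, 300),
        CohortSpec("PSO_1", "PSO", "general", 0.005, 150, 300),
        CohortSpec("PSO_2", "PSO", "general", 0.01, 150, 300),
    ]
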