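import numpy as np
import pandas as pd
import pytest

from epimediate import synthdata


@pytest.fixture(scope="session")
def default_cohort():
    """Study-sized cohort (n=262, 1000 probes) with planted mediation."""
    cfg = synthdata.SimConfig(seed=11)
    beta, pheno, truth = synthdata.simulate_cohort(cfg)
    return cfg, beta, pheno, truth


@pytest.fixture(scope="session")
def null_cohort():
    """Small cohort with no planted effects anywhere."""
    cfg = synthdata.SimConfig(
        n_samples=120,
        n_probes=300,
        n_cmrs=30,
        n_true_mediators=0,
        n_em_only=0,
        effect_direct=0.0,
        frac_outcome_t1=1.0,
        seed=7,
    )
    beta, pheno, truth = synthdata.simulate_cohort(cfg)
    return cfg, beta, pheno, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
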