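import numpy as np
import pytest

from miract import activity
from miract.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The standard cohort: 120 samples, 20 miRNAs, 60 targets each."""
    return generate_cohort(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_inference(default_cohort):
    c = default_cohort
    tumors = c.tumor_sample_ids
    acts, profiles = activity.infer_all_activities(
        c.mrna[tumors], c.mirna[tumors], c.targets
    )
    return acts, profiles


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Deterministic generation: no noise, every target functional."""
    cfg = SimulationConfig(
        seed=2,
        noise_sd_mrna=0.0,
        noise_sd_mirna=0.0,
        functional_fraction=1.0,
        mirna_coupling=1.0,
        simulate_subtypes=False,
        n_samples=100,
        n_normals=0,
        n_genes=1300,
        n_mirnas=10,
    )
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
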