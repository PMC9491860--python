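import numpy as np
import pytest

from dosagecomp.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_cohort():
    """Two tumor types x 60 samples, 300 genes, default noise."""
    cfg = SimulationConfig(
        n_genes=300, n_samples_per_type=60, n_tumor_types=2, n_pathways=20, seed=7
    )
    dataset, truth, segments = simulate_dataset(cfg)
    return cfg, dataset, truth, segments


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Single tumor type with all noise terms off: closed-form expectations hold."""
    cfg = SimulationConfig(
        n_genes=200,
        n_samples_per_type=80,
        n_tumor_types=1,
        n_pathways=10,
        sigma_fixed=0.0,
        dna_noise_sd=0.0,
        seed=13,
    )
    dataset, truth, segments = simulate_dataset(cfg)
    return cfg, dataset, truth, segments


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
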