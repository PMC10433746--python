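import pytest
from hypothesis import HealthCheck, settings

import triomics as tm

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_sim() -> tm.SimResult:
    """One default-condition synthetic bundle shared across tests."""
    return tm.generate_paired_omics(tm.SimConfig(seed=11))


@pytest.fixture(scope="session")
def zero_noise_sim() -> tm.SimResult:
    """Noise-free bundle: planted effects are exact, latent factor absent."""
    return tm.generate_paired_omics(tm.SimConfig(seed=5, noise_sd_log2=0.0))


@pytest.fixture(scope="session")
def small_config() -> tm.SimConfig:
    """Down-scaled configuration for Monte-Carlo loops."""
    return tm.SimConfig(n_genes=80, n_proteins=60, n_shared_ids=60,
                        n_de_genes=5, n_de_proteins=5, n_planted_pairs=10,
                        pathway_size=10, seed=0)
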