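import numpy as np
import pytest

from panelbench.simdata import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One small two-population cohort shared by read-only tests."""
    cfg = SimConfig(seed=42, n_sites=300, n_ancestral_haps=60,
                    panel_size=60, pop_sizes=(15, 15),
                    region_length=300_000, admixed_fraction=0.1)
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
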