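import numpy as np
import pytest

from cotwin import SimConfig, simulate_cohort
from cotwin.datasets import example_pair_counts, metadata_from_pair_counts


@pytest.fixture(scope="session")
def small_cohort():
    """A quick 30-pair cohort with spiked genus/metabolite effects."""
    cfg = SimConfig(n_mz_pairs=15, n_dz_pairs=15, n_genera=12,
                    n_metabolites=10, n_pathways=6, n_affected_genera=2,
                    n_affected_metabolites=2, seq_depth=5000, seed=11)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size (219-pair) cohort under default study conditions."""
    return simulate_cohort(SimConfig(seed=42))


@pytest.fixture(scope="session")
def reference_metadata():
    """Individual-level metadata of the 219-pair example cohort."""
    return metadata_from_pair_counts(example_pair_counts())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
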