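import numpy as np
import pandas as pd
import pytest

from repmeth.synthetic_data import SimConfig, simulate_beta_matrix, simulate_cohort


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig()


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(SimConfig(), seed=11)


@pytest.fixture(scope="session")
def small_matrix():
    """Desk-scale beta matrix: 300 loci x 40 subjects, default classes."""
    cfg = SimConfig(n_loci=300, n_array_subjects=40)
    return simulate_beta_matrix(cfg, seed=3)


def toy_beta_frame(values, loci=None, subjects=None) -> pd.DataFrame:
    values = np.asarray(values, dtype=float)
    loci = loci or [f"cg{i:03d}" for i in range(1, values.shape[0] + 1)]
    subjects = subjects or [f"S{j:03d}" for j in range(1, values.shape[1] + 1)]
    return pd.DataFrame(values, index=pd.Index(loci, name="locus_id"),
                        columns=subjects)
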