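import numpy as np
import pytest

import fcreeg as fc


@pytest.fixture(scope="session")
def small_cohort():
    """6 + 6 subjects under default study conditions (60 s at 128 Hz)."""
    cfg = fc.SynthConfig(n_sz=6, n_hc=6, seed=7)
    recs, manifest = fc.generate_cohort(cfg)
    return cfg, recs


@pytest.fixture(scope="session")
def beta_matrices(small_cohort):
    _, recs = small_cohort
    return fc.cohort_connectivity(recs, band="beta")


@pytest.fixture(scope="session")
def recovery_cohort():
    """12 + 12 subjects with the designed beta coupling deficit, plus the
    derived PLI matrices and FCR image dataset (shared across tests)."""
    cfg = fc.SynthConfig(n_sz=12, n_hc=12, seed=11)
    recs, _ = fc.generate_cohort(cfg)
    mats = fc.cohort_connectivity(recs, band="beta")
    ds = fc.build_dataset(mats, "beta")
    return cfg, mats, ds


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
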