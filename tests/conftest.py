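import numpy as np
import pytest

import vfprog as v
from vfprog import vae as vq


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_cohorts():
    """A small training/held-out cohort pair with default noise."""
    train_truth, train_noisy = v.generate_cohort(v.CohortConfig(n_eyes=64, seed=123))
    test_truth, test_noisy = v.generate_cohort(v.CohortConfig(n_eyes=24, seed=456))
    return train_truth, train_noisy, test_truth, test_noisy


@pytest.fixture(scope="session")
def small_vae(small_cohorts):
    """A lightly trained model for unit tests (not the evaluation-scale fit)."""
    _, train_noisy, _, _ = small_cohorts
    cfg = v.VAEConfig(seed=9, epochs=60)
    return vq.train_vae(vq.fields_from_cohort(train_noisy), cfg)
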