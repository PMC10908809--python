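import warnings

import numpy as np
import pytest

from virotrace.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted cohort shared by read-only tests."""
    cfg = CohortConfig(
        n_families=6,
        n_votus=8,
        n_bacteria=4,
        seq_length=3000,
        transmission_rate=0.5,
        coupling_rate=1.0,
        dropout=0.1,
        seed=42,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
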