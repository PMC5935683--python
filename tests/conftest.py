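import numpy as np
import pytest

import oligosnf as og


@pytest.fixture(scope="session")
def default_cohort():
    """One planted cohort at default parameters, shared across test modules."""
    return og.simulate_cohort(og.CohortParams(seed=7))


@pytest.fixture(scope="session")
def fused_default(default_cohort):
    c = default_cohort
    return og.fuse_expression([c.mrna, c.mirna])


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
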