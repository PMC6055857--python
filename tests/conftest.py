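import warnings

import numpy as np
import pytest

from hapimpute.simulate import standard_population


@pytest.fixture(scope="session")
def small_pop():
    """A small but structured cohort shared by fast unit tests."""
    return standard_population(seed=7, n_genotyped=120, n_snps=600)


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*animals with no masked slots.*")
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(0)
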