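import numpy as np
import pytest
from hypothesis import settings

from glycolocale import GeneratorParams, gen_cohort

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A 20-protein synthetic cohort with default study conditions."""
    return gen_cohort(GeneratorParams(n_proteins=20, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
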