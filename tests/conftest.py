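import numpy as np
import pytest

from ameskit import builtin_profiles, builtin_queries
from ameskit.synth import generate_set_with_metadata


@pytest.fixture(scope="session")
def profiles():
    return builtin_profiles()


@pytest.fixture(scope="session")
def queries():
    return builtin_queries()


@pytest.fixture(scope="session")
def literature_set(profiles):
    """Small literature-like synthetic set with grammar metadata."""
    return generate_set_with_metadata(profiles["literature_like"], 300, seed=101)


@pytest.fixture(scope="session")
def pharma_set(profiles):
    return generate_set_with_metadata(profiles["pharma_like"], 300, seed=102)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
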