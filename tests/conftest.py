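import warnings

import numpy as np
import pytest

from cellguild import references as refs
from cellguild import synth
from cellguild.taxonomy import default_taxonomy


@pytest.fixture(autouse=True)
def _quiet():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def reference():
    return refs.get_references()


@pytest.fixture(scope="session")
def tree():
    return default_taxonomy()


@pytest.fixture(scope="session")
def community():
    """One seeded six-genus community shared by the slower tests."""
    genomes, profiles = synth.simulate_default_community(seed=1)
    return genomes, profiles


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
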