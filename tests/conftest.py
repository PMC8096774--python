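import numpy as np
import pytest
from hypothesis import settings

from crnmut import (conservation_analysis, fixture_isomerization,
                    fixture_phospho_cycle)

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def fix1():
    return fixture_isomerization()


@pytest.fixture(scope="session")
def fix2():
    return fixture_phospho_cycle()


@pytest.fixture(scope="session")
def cs2(fix2):
    return conservation_analysis(fix2)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
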