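import numpy as np
import pytest

from patrace.chem import IsotopeAbundanceTable


@pytest.fixture(scope="session")
def nat_table():
    return IsotopeAbundanceTable.default()


@pytest.fixture(scope="session")
def principal_table():
    return IsotopeAbundanceTable.principal_only()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240529)
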