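import numpy as np
import pytest

from wolbsex import io


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def table2():
    """Packaged 20-family summary table."""
    return io.table2_families()


@pytest.fixture(scope="session")
def threegen():
    """Packaged three-generation pedigree."""
    return io.threegen_pedigree()
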