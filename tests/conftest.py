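import pytest

from tmodscan import synthetic_reference_set


@pytest.fixture(scope="session")
def refset():
    """The 22-gene synthetic mt-tRNA reference set used across tests."""
    return synthetic_reference_set()


@pytest.fixture(scope="session")
def mt_tk(refset):
    """The tRNA-Lys fixture: 70-nt gene, m1A58 landmark at mature index 54."""
    return refset["MT-TK"]
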