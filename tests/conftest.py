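import numpy as np
import pytest

from amplicall import ReferenceRegion
from amplicall.simulate import random_region


@pytest.fixture
def tiny_region():
    # GCAAAT: the A-homopolymer makes deletion placement ambiguous on purpose
    return ReferenceRegion("chrT", 1, 6, "GCAAAT")


@pytest.fixture(scope="session")
def region296():
    """A random amplicon the width of a typical MiSeq target window."""
    return random_region(296, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
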