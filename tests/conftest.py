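import numpy as np
import pytest
from hypothesis import settings

from cpdna import FixtureSpec, gen, pack

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def random_100kb():
    """i.i.d. uniform ACGT, 100 kb."""
    return pack(gen(FixtureSpec("random", 100_000, seed=11)))


@pytest.fixture(scope="session")
def tandem_100kb():
    """50 bp unit repeated 2000 times."""
    return pack(gen(FixtureSpec("tandem", 100_000, unit_len=50, copies=2000,
                                seed=13)))


@pytest.fixture(scope="session")
def mutated_100kb():
    """50 bp tandem array with 5% point substitutions."""
    return pack(gen(FixtureSpec("mutated", 100_000, unit_len=50,
                                sub_rate=0.05, seed=17)))


@pytest.fixture(scope="session")
def half_copy_20kb():
    """First half i.i.d. random, second half an exact copy of the first."""
    s = gen(FixtureSpec("random", 10_000, seed=7))
    return pack(s + s)
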