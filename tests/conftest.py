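import numpy as np
import pytest
from hypothesis import settings

from a2ipred import builtin_property_table, standardize, SiteWindow

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def raw_table():
    return builtin_property_table()


@pytest.fixture(scope="session")
def std_table(raw_table):
    return standardize(raw_table)


def random_window_residues(rng: np.random.Generator, length: int = 51) -> str:
    """Random residues with the central position forced to A."""
    chars = rng.choice(list("ACGU"), size=length)
    chars[length // 2] = "A"
    return "".join(chars)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def random_window(rng):
    res = random_window_residues(rng)
    return SiteWindow("rand", 26, res)
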