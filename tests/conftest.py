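import numpy as np
import pytest

from lanesw.scoring import load_builtin_scheme


@pytest.fixture(scope="session")
def bl62():
    return load_builtin_scheme("blosum62", 11, 1)


@pytest.fixture(scope="session")
def bl50():
    return load_builtin_scheme("blosum50", 13, 2)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def random_codes(rng, n, n_codes=20):
    """Random standard-residue codes (first 20 of the canonical order)."""
    return rng.integers(0, n_codes, size=n)
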