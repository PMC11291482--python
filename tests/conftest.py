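import numpy as np
import pytest

from reachrl import GridSpace


@pytest.fixture(scope="session")
def grid() -> GridSpace:
    """Default 8 x 8 x 4 grid with the corner-shell zone layout."""
    return GridSpace()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
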