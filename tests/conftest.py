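import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from centrolong.simulate import (
    default_vector,
    make_array,
    make_bacs,
    scaled_spec,
    scaled_tiling,
)


@pytest.fixture(scope="session")
def scaled_locus():
    """Desk-scale planted locus shared across tests (seed 1)."""
    return make_array(scaled_spec(seed=1))


@pytest.fixture(scope="session")
def vector():
    return default_vector()


@pytest.fixture(scope="session")
def bac_panel(scaled_locus, vector):
    """Three-clone tiling over the scaled locus, with truth order set."""
    locus, truth = scaled_locus
    bacs = make_bacs(locus, scaled_tiling(truth, 3, vector), truth, seed=5)
    return bacs
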