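import numpy as np
import pytest

from thzssm import SynthConfig, builtin_table1, generate_database
from thzssm.types import Spectrum


@pytest.fixture(scope="session")
def table1():
    return builtin_table1()


@pytest.fixture(scope="session")
def clean_db():
    """Noiseless, flat-baseline 8-analog synthetic database."""
    return generate_database()


@pytest.fixture(scope="session")
def grid():
    return SynthConfig().grid()


@pytest.fixture()
def flat_spectrum(grid):
    return Spectrum("flat", grid, np.zeros_like(grid))
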