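import numpy as np
import pandas as pd
import pytest

from stalkscreen import synthetic
from stalkscreen.spectra import SpectraSet


@pytest.fixture(scope="session")
def library():
    return synthetic.make_component_library(seed=1)


@pytest.fixture(scope="session")
def juice_design():
    return synthetic.factorial_design()


@pytest.fixture(scope="session")
def noiseless_juice(library, juice_design):
    return synthetic.simulate_juice_spectra(juice_design, library,
                                            noise_sd=0.0, seed=2)


@pytest.fixture
def small_set():
    """Tiny hand-made SpectraSet on a descending 4 cm^-1 grid."""
    grid = np.arange(1800.0, 799.0, -4.0)
    rng = np.random.default_rng(7)
    matrix = rng.normal(size=(5, grid.size)) * 0.01 + 0.5
    ref = pd.DataFrame({"target": np.linspace(1.0, 5.0, 5)})
    return SpectraSet(grid=grid, matrix=matrix,
                      sample_ids=[f"s{i}" for i in range(5)], reference=ref)
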