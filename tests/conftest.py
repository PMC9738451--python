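import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from regenatlas import SimulationConfig, simulate_counts
from regenatlas.design import TimepointDesign

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def design5() -> TimepointDesign:
    """The default study layout: control + 4 stages, replicates 3/2/2/3/2."""
    return TimepointDesign()


@pytest.fixture(scope="session")
def high_signal_sim(design5):
    """A strongly patterned simulation most stages can be tested against."""
    config = SimulationConfig(
        n_genes=400,
        design=design5,
        frac_patterned=0.3,
        fold_change=8.0,
        dispersion_range=(0.05, 0.05),
        seed=101,
    )
    matrix, truth = simulate_counts(config)
    return config, matrix, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
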