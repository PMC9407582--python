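import numpy as np
import pytest

from ripscan.synthetic_data import (
    DEFAULT_LIBRARY_SPEC,
    default_config,
    simulate_locus_panel,
    simulate_repeat_library,
)


@pytest.fixture(scope="session")
def library():
    """Four-family synthetic repeat consensus library (SINE/LTR/LINE)."""
    return simulate_repeat_library(1, DEFAULT_LIBRARY_SPEC)


@pytest.fixture(scope="session")
def default_panel(library):
    """The bundled five-locus study panel plus its truth set (seed 1)."""
    config = default_config(1)
    records, truth = simulate_locus_panel(config, library)
    return config, records, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20240701)
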