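import numpy as np
import pytest

from nanobuffer import TitrationMixture, chloroquine, ups_species


@pytest.fixture(scope="session")
def ups44_mixture() -> TitrationMixture:
    """40 mg of the pKa-4.4 nanobuffer model, bench titration protocol."""
    return TitrationMixture(species_loads=((ups_species(4.4), 40.0),))


@pytest.fixture(scope="session")
def cq_mixture() -> TitrationMixture:
    """40 mg chloroquine, bench titration protocol."""
    return TitrationMixture(species_loads=((chloroquine(), 40.0),))


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
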