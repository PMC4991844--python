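import numpy as np
import pytest

from anserdiet.io_core import RunConfig
from anserdiet.simulate import make_sample_sheet, simulate_reference


@pytest.fixture
def config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def small_library():
    """2 families x 2 genera x 2 species, clearly divergent."""
    library, _ = simulate_reference(
        n_families=2, genera_per_family=2, species_per_genus=2,
        seq_len=250, species_subs=8, genus_subs=14, family_subs=30, seed=11,
    )
    return library


@pytest.fixture(scope="session")
def two_sample_sheet():
    return make_sample_sheet(2, groups=["GWFG", "BG"], seed=5)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
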