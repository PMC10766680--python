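import numpy as np
import pytest

import firelarch as fl


@pytest.fixture(scope="session")
def species():
    return fl.default_species()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_landscape():
    """A 36 x 36 m synthetic landscape (4 coarse cells at 9 m), no water.

    Function-scoped: fine-grid state (litter, seed banks) is mutable.
    """
    return fl.generate_synthetic_landscape(
        n_coarse=4, coarse_res_m=9.0, water_fraction=0.0, seed=11)


@pytest.fixture()
def wet_landscape():
    """A landscape with water cells, fresh per test (mutable state)."""
    return fl.generate_synthetic_landscape(
        n_coarse=4, coarse_res_m=9.0, water_fraction=0.25, seed=12)


@pytest.fixture(scope="session")
def climate_100yr():
    return fl.generate_synthetic_climate(100, seed=42)
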