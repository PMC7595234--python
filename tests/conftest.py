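import warnings

import numpy as np
import pytest

from droughtsense import spei, synthetic


@pytest.fixture(scope="session")
def small_landscape():
    return synthetic.generate_landscape(
        synthetic.LandscapeConfig(n_rows=10, n_cols=10, subgrid_size=5, seed=11)
    )


@pytest.fixture(scope="session")
def small_climate(small_landscape):
    return synthetic.generate_climate(
        small_landscape.pixels["pixel_id"].to_numpy(),
        synthetic.ClimateConfig(start_year=1980, n_years=37),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_spei(small_climate):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return spei.compute_spei(small_climate, spei.SpeiConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
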