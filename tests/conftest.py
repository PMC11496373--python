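import numpy as np
import pandas as pd
import pytest

from climtop.gypsy import default_species_params
from climtop.synthetic import default_true_urf, make_urf_dataset


@pytest.fixture(scope="session")
def sw_params():
    return default_species_params("white_spruce")


@pytest.fixture(scope="session")
def pl_params():
    return default_species_params("lodgepole_pine")


@pytest.fixture(scope="session", params=["white_spruce", "lodgepole_pine"])
def species_params(request):
    """Both shipped species parameterisations."""
    return default_species_params(request.param)


@pytest.fixture(scope="session")
def true_urf():
    """Ground-truth single-variable response function (MAT.p x MAT.s)."""
    return default_true_urf()


@pytest.fixture(scope="session")
def noiseless_table(true_urf):
    """Exact fit table generated from the true response function."""
    table, truth = make_urf_dataset(true_urf, n_sites=20, n_populations=25,
                                    noise_sd_log=0.0, seed=11)
    return table
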