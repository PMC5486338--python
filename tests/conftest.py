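import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from staqr import (ChildDataset, CovariateRoles, SimConfig, generate_dataset,
                   make_lattice_graph, table1_fixture)
from staqr.synthetic import CATEGORICAL_VARS

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def lattice30():
    """5x6 rook lattice standing in for the 30-district map."""
    return make_lattice_graph(5, 6)


@pytest.fixture(scope="session")
def roles():
    return CovariateRoles(categorical=CATEGORICAL_VARS)


@pytest.fixture(scope="session")
def table1():
    return table1_fixture()


@pytest.fixture(scope="session")
def default_data():
    """Default-condition synthetic survey: n=3248, skew noise, seed 1."""
    return generate_dataset(SimConfig(n_children=3248, seed=1))


@pytest.fixture(scope="session")
def al_data():
    """AL-noise dataset for exact quantile-truth recovery checks."""
    return generate_dataset(
        SimConfig(n_children=4000, seed=11, noise="asymmetric-laplace"))


@pytest.fixture(scope="session")
def simple_dataset():
    """Outcome-only table for intercept models."""
    rng = np.random.default_rng(8)
    return ChildDataset(pd.DataFrame({"hb": rng.normal(3.0, 1.0, 5000)}),
                        district_col=None)
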