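import numpy as np
import pandas as pd
import pytest

from fieldomics.synthetic_field import SimulationConfig, make_field_layout


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_rows=6, n_cols=10, n_genes=60, n_metabolites=20,
                            n_traits=3, n_modules=3, module_size=8, seed=7)


@pytest.fixture(scope="session")
def small_layout(small_config):
    return make_field_layout(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_layout():
    """4 plants on a unit square; small enough for brute-force oracles."""
    return pd.DataFrame({
        "plant_id": ["a", "b", "c", "d"],
        "row": [0, 0, 1, 1], "col": [0, 1, 0, 1],
        "x": [0.0, 1.0, 0.0, 1.0], "y": [0.0, 0.0, 1.0, 1.0],
        "batch": [0, 0, 1, 1], "doh": [0, 1, 0, 1], "snp_group": [0, 0, 0, 1],
    })
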