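import numpy as np
import pytest

from snagfall.durability import DurabilityTable
from snagfall.model import (
    CovariateSpec,
    DurabilityModelParams,
    ModelParameters,
    SnagDataset,
    SpatialGrid,
)
from snagfall.simulate import parameter_recovery_config, simulate_survey

import pandas as pd


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def tiny_sim():
    """A small but fully structured synthetic survey (shared, read-only)."""
    cfg = parameter_recovery_config(seed=5, n_snags=600)
    return simulate_survey(cfg)


def make_tiny_model():
    """Hand-sized model state: 2 phys classes, 2x2 grid, 2 species."""
    spec = CovariateSpec(("AT",), centers={"AT": 10.0}, sds={"AT": 2.0})
    grid = SpatialGrid.rectangular(2, 2)
    durability = DurabilityModelParams(
        beta_dur=0.3,
        dur_bar=1.5,
        mu_family=np.array([0.2, -0.1]),
        sigma_family=0.5,
        mu_division=np.array([0.1, -0.2]),
        sigma_division=0.8,
        dur_imputed=np.array([1.0, 2.0]),
        family_of_species=np.array([0, 1]),
        division_of_family=np.array([0, 1]),
    )
    params = ModelParameters(
        beta0=1.2,
        rho=np.array([-0.25]),
        u=np.array([0.05, -0.05]),
        sigma_p=0.3,
        v=np.array([0.1, -0.1, 0.05, -0.05]),
        sigma_g=0.4,
        w=np.array([0.2, -0.2]),
        sigma_s=0.5,
        durability=durability,
    )
    records = pd.DataFrame(
        {
            "standing": [1, 0, 1, 0],
            "interval_years": [5.0, 4.5, 5.5, 5.0],
            "AT": [9.0, 11.0, 10.0, 12.0],
            "phys_class": [0, 1, 0, 1],
            "cell": [0, 1, 2, 3],
            "species": [0, 1, 1, 0],
            "decay_class": [1, 2, 1, 3],
        }
    )
    dataset = SnagDataset(
        records["standing"].to_numpy(),
        records["interval_years"].to_numpy(),
        records[["AT"]].to_numpy(),
        records["phys_class"].to_numpy(),
        records["cell"].to_numpy(),
        records["species"].to_numpy(),
        records["decay_class"].to_numpy(),
        spec,
    )
    observed_mask = np.array([True, False])
    return dataset, params, spec, grid, observed_mask


@pytest.fixture()
def tiny_model():
    return make_tiny_model()


@pytest.fixture()
def tiny_durability_table():
    return DurabilityTable(
        pd.DataFrame(
            {
                "species": ["sp_a", "sp_b"],
                "family": ["fam_a", "fam_b"],
                "division": ["angiosperm", "gymnosperm"],
                "durability": [1.0, np.nan],
                "n_sources": [1, 0],
            }
        )
    )
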