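import numpy as np
import pandas as pd
import pytest

from dlcirt.model_core import EncounterData, ItemBank, ModelSpec, ParameterSet
from dlcirt.simulator import recovery_scenario, simulate_dataset


@pytest.fixture(scope="session")
def small_sim():
    """One small dataset from the recovery scenario (200 persons)."""
    cfg = recovery_scenario(n_persons=200, seed=2)
    return cfg, simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_enc(small_sim):
    cfg, sim = small_sim
    return EncounterData.from_table(sim.encounters, cfg.spec, cfg.bank)


@pytest.fixture
def bank3():
    return ItemBank.uniform(3, n_options=4)


@pytest.fixture
def toy_table():
    """5 persons x 3 items with fixed responses and response times."""
    rng = np.random.default_rng(0)
    return pd.DataFrame({
        "person_id": np.repeat(np.arange(1, 6), 3),
        "item_id": np.tile([1, 2, 3], 5),
        "y": rng.integers(0, 2, 15),
        "rt_seconds": rng.uniform(5, 40, 15).round(3),
    })


@pytest.fixture
def toy_spec():
    return ModelSpec(family="dlc_tl", n_items=3, covariates=("log_rt",))


@pytest.fixture
def toy_params():
    return ParameterSet(beta={1: -0.5, 2: 0.2, 3: 0.8}, alpha0=-2.0,
                        gamma={"log_rt": 0.8}, sigma2_psi=0.8,
                        cov_psi_theta=0.3, var_theta=1.2)
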