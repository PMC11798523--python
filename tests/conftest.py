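import warnings

import numpy as np
import pandas as pd
import pytest

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")

from phenossm import (
    ModelSpec,
    ObservationTable,
    PhaseConfig,
    PredictorClimate,
    PriorConfig,
    SimulationConfig,
    VarianceParams,
    simulate_dataset,
)


@pytest.fixture
def small_config():
    """A short study: 40 years, FFL/LFB observed in the last 20."""
    return SimulationConfig(
        years=(1980, 2019),
        true_sigmas=VarianceParams(
            sigma_omega=0.1, sigma_tau=0.02, sigma_phi=2.0, sigma_upsilon=0.02
        ),
        phases={
            "FFL": PhaseConfig(mu0=125.3, beta0=-3.1, gamma0=-3.75, first_obs_year=2000),
            "LFB": PhaseConfig(mu0=130.5, beta0=-2.2, gamma0=None, first_obs_year=2000),
        },
        predictor_model={
            "ex1": PredictorClimate(2.0, 0.8, 0.28),
            "ex2": PredictorClimate(7.15, 1.2, 0.27),
            "ex3": PredictorClimate(13.0, 2.3, 0.25),
        },
        seed=11,
    )


@pytest.fixture
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture
def toy_spec():
    """A 10-year two-predictor model with a gap in the observations."""
    rng = np.random.default_rng(7)
    years = np.arange(2000, 2010)
    ex1 = rng.normal(2.0, 0.8, 10)
    ex2 = rng.normal(7.0, 1.2, 10)
    design = np.column_stack([np.ones(10), ex1, ex2])
    y = 125.0 - 3.0 * ex1 - 3.7 * ex2 + rng.normal(0, 2.0, 10)
    y[[2, 5, 6]] = np.nan
    return ModelSpec(
        phenophase="FFL",
        years=years,
        design=design,
        y=y,
        prior=PriorConfig(init_sd=50.0),
    )


def make_observations(rows):
    return ObservationTable(
        frame=pd.DataFrame(rows, columns=["year", "phenophase", "doy", "source"])
    )
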