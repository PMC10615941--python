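"""Shared fixtures: expensive simulated studies built once per session.

All fixtures use fixed seeds so the suite is deterministic; sizes are desk
scaled (hundreds of participants rather than the full designs' 1000) but
honour the minimum sizes the analyses require.
"""

import numpy as np
import pytest

from diffscore import (
    fit_model_family,
    fit_population,
    sample_lba_population,
    sample_uniform_population,
    simulate_population_trials,
)


@pytest.fixture(scope="session")
def sim1_study():
    """No-difference DDM study: 200 participants x 1000 trials/condition,
    with both ML and EZ refits of the same simulated data."""
    seed = 7
    pop = sample_uniform_population(200, seed=seed)
    trials = simulate_population_trials(pop, 1000, seed=seed)
    fit_ml = fit_population(trials, fitter="ml", seed=seed)
    fit_ez = fit_population(trials, fitter="ez", seed=seed)
    return {
        "seed": seed,
        "population": pop,
        "trials": trials,
        "fit_ml": fit_ml,
        "fit_ez": fit_ez,
    }


@pytest.fixture(scope="session")
def lba_study():
    """No-difference LBA study: 200 participants x 500 trials/condition."""
    seed = 9
    pop = sample_lba_population(200, seed=seed)
    trials = simulate_population_trials(pop, 500, seed=seed, model="lba")
    fitted = fit_population(trials, model="lba", seed=seed)
    return {"seed": seed, "population": pop, "trials": trials, "fitted": fitted}


@pytest.fixture(scope="session")
def competition_study():
    """8-model competition on no-difference data: 100 participants x 500
    trials/condition."""
    seed = 11
    pop = sample_uniform_population(100, seed=seed)
    trials = simulate_population_trials(pop, 500, seed=seed)
    table = fit_model_family(trials, seed=seed)
    return {"seed": seed, "population": pop, "trials": trials, "table": table}
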