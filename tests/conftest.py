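import numpy as np
import pandas as pd
import pytest

from tabhallu.population import (OutcomeSpec, PopulationSpec, VariableSpec,
                                 generate_population)


@pytest.fixture(scope="session")
def toy_spec():
    """Small mostly-categorical population with a logistic outcome."""
    core = (
        VariableSpec("age_band", "categorical", 4),
        VariableSpec("sex", "categorical", 2),
        VariableSpec("score", "numeric", 10),
    )
    adjuncts = (
        VariableSpec("dx", "categorical", 40, tail_shape=1.2),
        VariableSpec("flag1", "categorical", 2),
        VariableSpec("flag2", "categorical", 3),
        VariableSpec("lab", "numeric", 10),
        VariableSpec("region", "categorical", 6),
        VariableSpec("rx", "categorical", 12, tail_shape=1.2),
    )
    outcome = OutcomeSpec(outcome_name="outcome",
                          signal_vars=("age_band", "sex"),
                          coefficients={"age_band": 0.6, "sex": -0.9},
                          intercept=-0.3)
    return PopulationSpec(name="toy", n_records=8000, core_vars=core,
                          adjunct_pool=adjuncts, outcome=outcome,
                          missing_rate=0.02, seed=11)


@pytest.fixture(scope="session")
def toy_population(toy_spec):
    return generate_population(toy_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(123)


def random_matching_fixture(rng, n_syn, n_pop, n_cat=3, n_num=1,
                            cardinality=4, missing_rate=0.05):
    """Random synthetic/population table pair over a shared small alphabet,
    used to exercise the antijoin against the Hamming oracle."""
    def table(n):
        cols = {}
        for j in range(n_cat):
            vals = rng.choice([f"L{i}" for i in range(cardinality)], n).astype(object)
            mask = rng.random(n) < missing_rate
            vals[mask] = np.nan
            cols[f"c{j}"] = vals
        for j in range(n_num):
            x = rng.normal(size=n)
            x[rng.random(n) < missing_rate] = np.nan
            cols[f"x{j}"] = x
        return pd.DataFrame(cols)
    return table(n_syn), table(n_pop)
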