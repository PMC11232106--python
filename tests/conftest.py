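import numpy as np
import pandas as pd
import pytest

import linkshrink as ls

# The sim1 fit is the single expensive fixture; it is shared (session scope)
# by the recovery, selection and Shapley-coverage tests. Reduced draws:
# 4 chains x (500 warmup + 1000 kept).
SIM1_SEED = 1
REDUCED_MCMC = ls.MCMCConfig(chains=4, warmup=500, draws=1000, seed=SIM1_SEED)


@pytest.fixture(scope="session")
def sim1_dataset():
    cfg = ls.sim_config("sim1")
    return ls.generate_dataset(cfg, SIM1_SEED)


@pytest.fixture(scope="session")
def sim1_design(sim1_dataset):
    enc = ls.encode_covariates(sim1_dataset.table, sim1_dataset.schema)
    return ls.build_interactions(enc)


@pytest.fixture(scope="session")
def sim1_fit(sim1_dataset, sim1_design):
    return ls.fit(sim1_dataset.y, sim1_design, ls.PriorSpec(), REDUCED_MCMC)


@pytest.fixture()
def helius_table():
    cfg = ls.sim_config("helius_like", n=400)
    table = ls.simulate_covariates(cfg, 42)
    return table, ls.helius_like_schema()


def random_continuous_design(rng, n=50, p=4):
    """Small all-continuous encoded design with interactions, for unit tests."""
    table = pd.DataFrame(
        {f"x{j + 1}": rng.standard_normal(n) for j in range(p)}
    )
    schema = [ls.CovariateSchema(f"x{j + 1}", "continuous") for j in range(p)]
    enc = ls.encode_covariates(table, schema)
    return ls.build_interactions(enc)


def random_mixed_design(rng, n=60):
    """Mixed-type design: 2 continuous, 1 binary, 1 four-level categorical."""
    table = pd.DataFrame(
        {
            "a": rng.standard_normal(n),
            "b": rng.standard_normal(n),
            "c": rng.integers(0, 2, n),
            "d": rng.choice(list("wxyz"), n),
        }
    )
    schema = [
        ls.CovariateSchema("a", "continuous"),
        ls.CovariateSchema("b", "continuous"),
        ls.CovariateSchema("c", "binary"),
        ls.CovariateSchema("d", "categorical", ("w", "x", "y", "z")),
    ]
    enc = ls.encode_covariates(table, schema)
    return ls.build_interactions(enc)


def random_coefficients(rng, design, scale=1.0):
    return {
        "alpha": float(rng.normal(0, scale)),
        "beta_main": rng.normal(0, scale, design.p_enc),
        "beta_int": rng.normal(0, scale, design.q),
    }
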