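import numpy as np
import pandas as pd
import pytest

import bloodvar as bv


@pytest.fixture(scope="session")
def small_config() -> bv.SimulationConfig:
    """A compact study design: 300 genes, 6 donors x 3 degradation series."""
    return bv.config_from_fractions(
        n_genes=300,
        n_donors=6,
        n_series=3,
        fractions={"cell_mixture": 0.30, "gender": 0.09, "age": 0.08, "rin": 0.02},
        block_sizes={"gender": 40, "age": 40, "rin": 30, "bmi": 30},
        cell_block_sizes={
            "lymphocyte_pct": 40,
            "neutrophil_pct": 40,
            "monocyte_pct": 20,
        },
        seed=7,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    cov = bv.simulate_covariates(small_config)
    expr, truth = bv.simulate_expression(cov, small_config)
    return cov, expr, truth


@pytest.fixture()
def toy_covariates() -> bv.SampleCovariates:
    """Six samples, two donors, tie-free continuous covariates."""
    df = pd.DataFrame(
        {
            "donor": ["A", "A", "A", "B", "B", "B"],
            "gender": ["M", "M", "M", "F", "F", "F"],
            "age": [25.0, 25.0, 25.0, 31.0, 31.0, 31.0],
            "rin": [8.9, 7.7, 6.5, 9.1, 7.5, 6.2],
        },
        index=[f"s{i}" for i in range(6)],
    )
    return bv.SampleCovariates(df)


def random_expression(rng: np.random.Generator, m: int, n: int) -> pd.DataFrame:
    return pd.DataFrame(
        rng.normal(7.0, 1.0, (m, n)),
        index=[f"g{i}" for i in range(m)],
        columns=[f"s{j}" for j in range(n)],
    )
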