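"""Shared fixtures: small synthetic worlds reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mlsae import (
    GeographyFrame,
    TrueModel,
    generate_geography,
    generate_population_cells,
    simulate_survey,
)
from mlsae import coefficients as coefmod


@pytest.fixture(scope="session")
def small_geo() -> GeographyFrame:
    return generate_geography(10, 3, 4, 5, seed=11)


@pytest.fixture(scope="session")
def small_true(small_geo) -> TrueModel:
    return TrueModel.draw(small_geo, seed=12, sigma2_state=0.05)


@pytest.fixture(scope="session")
def small_survey(small_geo, small_true) -> pd.DataFrame:
    return simulate_survey(small_geo, small_true, n_per_state=250, seed=13)


@pytest.fixture(scope="session")
def small_cells(small_geo) -> pd.DataFrame:
    return generate_population_cells(small_geo, mean_children_per_bg=50.0, seed=14)


def make_tiny_instance(seed: int, n_groups: int = 4, n_obs: int = 40, sigma2: float = 0.15):
    """One random tiny one-covariate mixed-logit dataset for oracle checks.

    Balanced groups with a single binary covariate.  The family is kept in
    the Laplace accuracy regime — probabilities near 1/2 (high Bernoulli
    information) and ten observations per group — because the comparison
    being tested is approximation quality at a fixed instance, not robustness
    to arbitrarily sparse clusters.
    """
    rng = np.random.default_rng(seed)
    g = np.repeat(np.arange(n_groups), n_obs // n_groups)
    n = len(g)
    x = rng.integers(0, 2, size=n).astype(float)
    u = rng.normal(0.0, np.sqrt(sigma2), size=n_groups)
    beta0, beta1 = rng.uniform(-0.3, 0.3), rng.uniform(-0.5, 0.5)
    eta = beta0 + beta1 * x + u[g]
    y = rng.binomial(1, 1.0 / (1.0 + np.exp(-eta))).astype(float)
    X = np.column_stack([np.ones(n), x])
    return y, X, g
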