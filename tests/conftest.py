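import itertools

import numpy as np
import pandas as pd
import pytest

from easesim import Portfolio, PortfolioParams, generate_portfolio


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_portfolio():
    """Three hand-built parcels: (beta, value) = (10,1), (10,2), (10,3)."""
    return Portfolio(pd.DataFrame({
        "parcel_id": [1, 2, 3],
        "area_acres": [1.0, 1.0, 1.0],
        "assessed_value": [1.0, 2.0, 3.0],
        "beta_score": [10.0, 10.0, 10.0],
    }))


@pytest.fixture(scope="session")
def calibration_portfolio():
    """A 10k-parcel portfolio at default parameters (shared, read-only)."""
    return generate_portfolio(PortfolioParams(n_parcels=10_000, seed=7))


def random_small_portfolio(seed, n=None):
    """A random portfolio with at most 15 parcels for enumeration oracles."""
    r = np.random.default_rng(seed)
    if n is None:
        n = int(r.integers(2, 16))
    return Portfolio(pd.DataFrame({
        "parcel_id": np.arange(1, n + 1),
        "area_acres": r.uniform(0.1, 50.0, n),
        "assessed_value": r.uniform(1.0, 100.0, n),
        "beta_score": r.uniform(0.0, 10.0, n) + 0.01,
    }))


def exhaustive_min_cost(portfolio, target_fraction):
    """Brute-force minimum total value over all target-meeting subsets."""
    betas, values = portfolio.betas, portfolio.values
    target = target_fraction * betas.sum()
    n = len(betas)
    best = float("inf")
    for mask in itertools.product((0, 1), repeat=n):
        sel = np.array(mask, dtype=bool)
        if betas[sel].sum() >= target - 1e-9 * max(1.0, target):
            best = min(best, values[sel].sum())
    return best
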