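"""Shared fixtures: one small pool/dataset pair reused across tests.

Fixtures that equilibrate communities are session-scoped so the ODE work is
paid once; algorithm tests that don't need real dynamics use cheap synthetic
tables instead.
"""

import numpy as np
import pytest

from guildfinder import generate_dataset, generate_pool, linear_chain
from guildfinder.pool import GeneralizedResources


@pytest.fixture(scope="session")
def chain3():
    return linear_chain(3)


@pytest.fixture(scope="session")
def pool48(chain3):
    """Canonical pool: N = 3 truth groups of 16 species."""
    return generate_pool(48, chain3, seed=11)


@pytest.fixture(scope="session")
def small_dataset(pool48):
    """80 noisy samples from the canonical pool."""
    return generate_dataset(pool48, 80, noise=0.1, seed=12)


@pytest.fixture(scope="session")
def pool12():
    """Small pool (N = 3 groups of 4) for cheap end-to-end runs."""
    topo = linear_chain(3)
    return generate_pool(12, topo, GeneralizedResources(n_resources=8), seed=13)


@pytest.fixture(scope="session")
def easy_dataset(pool12):
    """150 low-noise samples from the small pool: an easy recovery task."""
    return generate_dataset(pool12, 150, subset_size=6, noise=0.05, seed=14)


@pytest.fixture()
def toy_table():
    """Synthetic abundance table with a planted 2-species functional group.

    No dynamics: y is the summed abundance of species {0, 1} plus small
    noise, so subset-selection objectives have a known sweet spot.
    """
    rng = np.random.default_rng(7)
    A = rng.gamma(2.0, 1.0, size=(40, 6))
    y = A[:, 0] + A[:, 1] + rng.normal(0, 0.05, size=40)
    return A, y
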