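import numpy as np
import pytest

import gemlr
from gemlr.model_core import (
    FeatureRoles,
    FeatureTable,
    GaussianComponent,
    MixtureGate,
)


@pytest.fixture(scope="session")
def het_data():
    """One heterogeneous synthetic dataset (two opposite-sign clusters)."""
    sc = gemlr.make_scenario("heterogeneous", n=300, seed=7)
    table, y, truth = gemlr.generate(sc)
    return sc, table, y, truth


@pytest.fixture(scope="session")
def het_model(het_data):
    """A GeM-LR fit (C=2, light penalty) on the heterogeneous dataset."""
    sc, table, y, _ = het_data
    cfg = gemlr.FitConfig(C=2, lambda1=0.05, seed=7)
    model = gemlr.fit(table, y, sc.default_roles(), cfg)
    return cfg, model


@pytest.fixture
def std_normal_gate():
    return MixtureGate([1.0], [GaussianComponent([0.0], [[1.0]])])


@pytest.fixture
def two_comp_gate():
    """Equal-prior 1-D pair at +/-1, unit variances."""
    return MixtureGate([0.5, 0.5], [GaussianComponent([-1.0], [[1.0]]),
                                    GaussianComponent([1.0], [[1.0]])])


def random_gate(rng, C=None, dim=None, max_C=4, max_dim=3):
    """A random, well-conditioned mixture gate for property tests."""
    C = C or rng.integers(1, max_C + 1)
    dim = dim or rng.integers(1, max_dim + 1)
    priors = rng.dirichlet(np.ones(C) * 2.0)
    comps = []
    for _ in range(C):
        mean = rng.normal(0, 2.0, size=dim)
        A = rng.normal(0, 1.0, size=(dim, dim))
        cov = A @ A.T + np.eye(dim) * (0.3 + rng.random())
        comps.append(GaussianComponent(mean, cov))
    return MixtureGate(priors, comps)


@pytest.fixture
def toy_table():
    return FeatureTable(np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]]),
                        ["a", "b", "c"], ["f1", "f2"])


@pytest.fixture
def roles_all(toy_table):
    return FeatureRoles([0, 1], [0, 1])
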