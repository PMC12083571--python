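import numpy as np
import pandas as pd
import pytest

from d3mi import Family, Federation, GLMMModel, SiteData


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_gaussian_federation(
    rng, n_sites=4, n_per_site=40, sigma_u=0.4, beta=(0.5, 1.0, -0.5), sigma_e=0.7
):
    """Small gaussian random-intercept federation with known parameters."""
    beta = np.asarray(beta, float)
    sites = []
    for i in range(n_sites):
        u = rng.normal(0.0, sigma_u)
        x1 = rng.normal(size=n_per_site)
        x2 = rng.normal(size=n_per_site)
        y = beta[0] + beta[1] * x1 + beta[2] * x2 + u + rng.normal(0, sigma_e, n_per_site)
        sites.append(SiteData(f"s{i}", {"y": y, "x1": x1, "x2": x2}))
    return Federation(sites)


def make_binomial_federation(
    rng, n_sites=5, n_per_site=60, sigma_u=0.5, beta=(-0.3, 0.8, -0.6)
):
    from scipy.special import expit

    beta = np.asarray(beta, float)
    sites = []
    for i in range(n_sites):
        u = rng.normal(0.0, sigma_u)
        x1 = rng.normal(size=n_per_site)
        x2 = rng.normal(size=n_per_site)
        p = expit(beta[0] + beta[1] * x1 + beta[2] * x2 + u)
        y = (rng.random(n_per_site) < p).astype(float)
        sites.append(SiteData(f"s{i}", {"y": y, "x1": x1, "x2": x2}))
    return Federation(sites)


GAUSS_MODEL = GLMMModel(outcome="y", covariates=("x1", "x2"), family=Family.gaussian)
BINOM_MODEL = GLMMModel(outcome="y", covariates=("x1", "x2"), family=Family.binomial)


@pytest.fixture
def gaussian_federation(rng):
    return make_gaussian_federation(rng)


@pytest.fixture
def binomial_federation(rng):
    return make_binomial_federation(rng)
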