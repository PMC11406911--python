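import numpy as np
import pytest

from taxanorm.simulate import SimConfig, make_template, simulate_counts
from taxanorm.zinb import TaxonParams


@pytest.fixture
def rng():
    return np.random.default_rng(20240916)


@pytest.fixture
def small_taxon():
    """A hand-sized taxon: counts and log depths for n=6 samples."""
    y = np.array([0.0, 3.0, 0.0, 12.0, 5.0, 1.0])
    x = np.array([9.2, 10.1, 9.7, 11.0, 10.4, 9.9])
    return y, x

@pytest.fixture
def sim_small():
    """A 20-taxon, 80-sample dataset from the generative model."""
    return simulate_counts(SimConfig(n_samples=80, n_taxa=20, seed=42))


def zinb_pmf_reference(y, mu, theta, pi):
    """Independent mixture pmf via math.gamma-free log-gamma arithmetic."""
    from math import exp, lgamma, log

    nb = exp(
        lgamma(y + theta) - lgamma(theta) - lgamma(y + 1)
        + y * (log(mu) - log(theta + mu)) + theta * (log(theta) - log(theta + mu))
    )
    return pi * (1.0 if y == 0 else 0.0) + (1.0 - pi) * nb
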