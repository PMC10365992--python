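import numpy as np
import pytest

from fitcode.domains import (Prior, StimulusDomain, make_diagonality_prior,
                             make_orientation_prior)


@pytest.fixture(scope="session")
def orientation_prior():
    return make_orientation_prior(1.85)


@pytest.fixture(scope="session")
def diagonality_prior():
    return make_diagonality_prior(1.85)


@pytest.fixture(scope="session")
def piecewise_prior():
    """Density 1.6 on [0, 0.5] and 0.4 on [0.5, 1] (integral 1)."""
    domain = StimulusDomain(0.0, 1.0, n_grid=2048)
    dens = np.where(domain.grid < 0.5, 1.6, 0.4)
    # make the trapezoid integral exact despite the step at 0.5
    dens[domain.grid == 0.5] = 1.0
    dens = dens / np.trapezoid(dens, domain.grid)
    return Prior(domain, dens)


@pytest.fixture(scope="session")
def uniform_prior():
    domain = StimulusDomain(0.0, 1.0, n_grid=512)
    return Prior(domain, np.ones(512))


@pytest.fixture(scope="session")
def skewed_prior():
    from fitcode.scenarios import make_skewed_prior
    return make_skewed_prior()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
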