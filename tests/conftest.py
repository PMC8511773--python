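import numpy as np
import pytest
from hypothesis import settings

from phasetip import climate, cycles, models, scan, tipping

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")

#: master seed for every stochastic fixture (digits of the study DOI)
SEED = 20210059


@pytest.fixture(scope="session")
def rma():
    return models.table1("rma")


@pytest.fixture(scope="session")
def may():
    return models.table1("may")


@pytest.fixture(scope="session")
def rma_cycle(rma):
    """Gamma(2.47) for the RMA model."""
    return cycles.find_limit_cycle(rma.with_r(2.47))


@pytest.fixture(scope="session")
def may_cycle(may):
    """Gamma(3.3) for the May model."""
    return cycles.find_limit_cycle(may.with_r(3.3))


@pytest.fixture(scope="session")
def rma_rh(rma):
    """Heteroclinic value r_h of the RMA cycle."""
    return scan.heteroclinic_rh(rma)


@pytest.fixture(scope="session")
def rma_ensemble(rma, rma_rh):
    """100 tipping events, RMA, forcing on [1.6, 2.5] (excludes r_h)."""
    spec = climate.ClimateSpec(r_low=1.6, r_high=2.5, rho=0.2,
                               horizon=5000.0)
    return tipping.monte_carlo(rma, spec, (3.0, 0.002), n_events=100,
                               seed=SEED, rh=rma_rh)


@pytest.fixture(scope="session")
def may_ensemble(may):
    """100 tipping events, May, forcing on [2, 3.3] (no dangerous
    bifurcation anywhere for the May cycle)."""
    spec = climate.ClimateSpec(r_low=2.0, r_high=3.3, rho=0.2,
                               horizon=5000.0)
    return tipping.monte_carlo(may, spec, (3.0, 0.002), n_events=100,
                               seed=SEED, rh=None)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(SEED)
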