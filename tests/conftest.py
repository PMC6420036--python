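import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from plasmidseg import ModelParameters, SegregationStrategy, multi_start_ess
from plasmidseg.lineage import simulate_lineages

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_params() -> ModelParameters:
    """Reference parameter set: z_hat=50, b=1.2/h, beta0=1/h, mu0=5/h."""
    return ModelParameters()


@pytest.fixture(scope="session")
def ess_default(default_params):
    """The optimised segregation strategy at the reference parameters.

    Shared across tests because the multi-start ascent is the most expensive
    deterministic computation in the suite.
    """
    return multi_start_ess(default_params, n_starts=3, seed=1, tol=1e-8)


@pytest.fixture(scope="session")
def sim_equal(default_params):
    """Long stochastic run under equal segregation (p = 0.5), used for the
    stationary-distribution and growth-rate comparisons."""
    strategy = SegregationStrategy.uniform(default_params.z_hat, 0.5)
    return simulate_lineages(
        default_params,
        strategy,
        t_max=22.0,
        max_cells=10_000,
        seed=1,
        initial=[25] * 50,
    )


@pytest.fixture(scope="session")
def step_strategy(default_params):
    """A copy-number-dependent step strategy: equal segregation below z=25,
    unequal (p=0.3) above."""
    p = np.full(default_params.z_hat, 0.5)
    p[24:] = 0.3
    return SegregationStrategy(p)


@pytest.fixture(scope="session")
def sim_step(default_params, step_strategy):
    """Stochastic run under the step strategy, used for end-to-end strategy
    recovery from division records."""
    return simulate_lineages(
        default_params,
        step_strategy,
        t_max=20.0,
        max_cells=6_000,
        seed=2,
        initial=[30] * 60,
    )
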