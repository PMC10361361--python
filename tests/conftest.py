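import numpy as np
import pytest

from seasonhmm import (
    EmissionParams,
    HMMParams,
    InitialStateParams,
    TransitionParams,
    build_basis,
    make_knots,
)


@pytest.fixture(scope="session")
def basis():
    return build_basis(make_knots(5, 1, 365))


@pytest.fixture(scope="session")
def deer_scenario(basis):
    from seasonhmm import preset_scenario

    return preset_scenario("deer_like", basis)


@pytest.fixture(scope="session")
def pronghorn_scenario(basis):
    from seasonhmm import preset_scenario

    return preset_scenario("pronghorn_like", basis)


def random_params(rng: np.random.Generator, K: int = 5, start_days=(1,)) -> HMMParams:
    """A random valid parameter set for property tests."""
    mu1 = rng.uniform(0.2, 2.0)
    em = EmissionParams(
        mu1_step=mu1,
        delta=rng.uniform(0.5, 8.0),
        sd_step=rng.uniform(0.2, 4.0, 2),
        mu_turn=rng.uniform(-np.pi, np.pi, 2),
        rho_turn=rng.uniform(0.0, 0.9, 2),
    )
    tr = TransitionParams(
        beta0=rng.normal(0, 1.5, 2),
        b=rng.normal(0, 0.5, (2, K)),
        sigma_b=rng.uniform(0.2, 2.0, 2),
    )
    phi = {}
    for d in start_days:
        p = rng.uniform(0.05, 0.95)
        phi[int(d)] = np.array([p, 1 - p])
    return HMMParams(em, tr, InitialStateParams(phi))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
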