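import numpy as np
import pytest

from monma import (
    MCMCConfig,
    ScenarioConfig,
    SimulationConfig,
    fit,
    make_fixture,
    simulate_network,
)


def quick_mcmc(seed: int = 0, iterations: int = 4000, chains: int = 2) -> MCMCConfig:
    """Short chains for smoke/contract tests (not for recovery checks)."""
    return MCMCConfig(
        iterations=iterations, burn_in=iterations // 4, thinning=5,
        chains=chains, seed=seed,
    )


@pytest.fixture(scope="session")
def two_arm_contrasts():
    return make_fixture("two_arm_minimal").to_contrasts()


@pytest.fixture(scope="session")
def three_arm_contrasts():
    return make_fixture("three_arm_minimal").to_contrasts()


@pytest.fixture(scope="session")
def mixed_missing_contrasts():
    return make_fixture("mixed_missing").to_contrasts()


@pytest.fixture(scope="session")
def small_network():
    """A 20-study, 4-treatment synthetic network used by several suites."""
    cfg = SimulationConfig(
        n_treatments=4, n_studies=20,
        beta={"R": [0.3, 0.5, 0.7], "D": [-0.3, -0.2, -0.1]},
        seed=11,
    )
    return simulate_network(cfg, seed=11)


@pytest.fixture(scope="session")
def small_fit(small_network):
    """One II.a posterior on the small network, shared across tests."""
    import warnings

    sc = ScenarioConfig("II.a", reference="T0", mcmc=quick_mcmc(seed=5, iterations=6000))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit(small_network.to_contrasts(), sc)


def random_three_arm_block(rng: np.random.Generator):
    """A random 4-dim three-arm contrast block from random binomial counts."""
    from monma import Study, Arm

    sid = "RND"
    arms = []
    for t in ("A", "B", "C"):
        n = int(rng.integers(20, 200))
        counts = {}
        for o in ("R", "D"):
            e = int(rng.integers(1, n))
            counts[o] = (e, n - e)
        arms.append(Arm(sid, t, counts))
    from monma import estimate_contrasts

    return estimate_contrasts(Study(sid, arms))
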