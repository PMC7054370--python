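import numpy as np
import pytest

from renalpanel.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-participant default-structure cohort shared across tests."""
    cfg = SimulationConfig(n_participants=300, seed=11)
    participants, panel, truth = generate_cohort(cfg)
    return cfg, participants, panel, truth


@pytest.fixture(scope="session")
def small_phenotypes(small_cohort):
    from renalpanel.phenotypes import derive_phenotypes

    _, participants, _, _ = small_cohort
    return derive_phenotypes(participants)


@pytest.fixture(scope="session")
def toy_linear_fit():
    """A quick horseshoe fit on a small constructed linear problem."""
    from renalpanel.horseshoe import ShrinkagePrior, fit_shrinkage

    rng = np.random.default_rng(5)
    n, p = 300, 5
    X_cov = rng.standard_normal((n, 2))
    X_bio = rng.standard_normal((n, p))
    beta = np.array([0.6, 0.0, 0.0, 0.0, 0.0])
    y = X_cov @ np.array([0.4, -0.3]) + X_bio @ beta + rng.standard_normal(n)
    prior = ShrinkagePrior(chains=2, draws=250, warmup=250)
    fit = fit_shrinkage(X_cov, X_bio, y, "linear", prior, seed=6)
    return fit, X_cov, X_bio, y, beta
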