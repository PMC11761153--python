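import numpy as np
import pytest

from locustdyn import derive_baseline_params


@pytest.fixture(scope="session")
def baseline():
    return derive_baseline_params()


@pytest.fixture(scope="session")
def extinction_params(baseline):
    """Autonomous scenario with offspring number below one."""
    return baseline.replace(phi=1.75)


@pytest.fixture(scope="session")
def persistence_params(baseline):
    """Autonomous scenario with offspring number above one."""
    return baseline.replace(phi=25.0, mu_h=0.25, mu_b=0.3)


def random_valid_params(rng: np.random.Generator):
    """A random parameter set within broad biological validity."""
    return derive_baseline_params().replace(
        phi=rng.uniform(0.5, 30.0),
        psi=rng.uniform(0.05, 0.95),
        eta=rng.uniform(0.2, 0.7),
        sigma=rng.uniform(0.01, 0.15),
        mu_e=rng.uniform(0.02, 0.7),
        theta=rng.uniform(0.05, 0.95),
        gamma_h=rng.uniform(0.01, 0.05),
        gamma_b=rng.uniform(0.01, 0.05),
        mu_h=rng.uniform(0.1, 0.9),
        mu_b=rng.uniform(0.1, 0.9),
        mu_s=rng.uniform(0.004, 0.02),
        mu_g=rng.uniform(0.004, 0.02),
        beta_1=rng.uniform(0.05, 0.4),
        beta_2=rng.uniform(0.05, 0.4),
    )
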