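import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from reefsph.particles import ParticleSystem, Phase


def random_cloud(n: int, rng: np.random.Generator, box: float = 1.0,
                 dx: float = 0.05, period_x=None) -> ParticleSystem:
    """Random particle configuration for oracle-equivalence fixtures."""
    x = rng.uniform(0.0, box, size=(n, 2))
    v = rng.normal(0.0, 0.1, size=(n, 2))
    rho = rng.uniform(950.0, 1050.0, size=n)
    m = np.full(n, 1000.0 * dx * dx)
    return ParticleSystem(
        x=x, v=v, rho=rho, p=np.zeros(n), m=m,
        phase=np.zeros(n, dtype=np.int8),
        streak=np.zeros(n, dtype=np.int32),
        dx=dx, bounds=(0.0, box, 0.0, box), period_x=period_x,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20211260)


# --- expensive shared runs (session scope: computed once, used by both the
# --- validation suite and the acceptance suite) ------------------------------

@pytest.fixture(scope="session")
def poiseuille_res10():
    from reefsph.validation import poiseuille_case
    return poiseuille_case(resolution=10)


@pytest.fixture(scope="session")
def poiseuille_res20():
    from reefsph.validation import poiseuille_case
    return poiseuille_case(resolution=20)


@pytest.fixture(scope="session")
def hydrostatic():
    from reefsph.validation import hydrostatic_case
    return hydrostatic_case()


@pytest.fixture(scope="session")
def scenario_runs():
    """Reduced-scale scenario across death intervals (25 growth events)."""
    from reefsph.validation import run_reduced_scenario
    return {k: run_reduced_scenario(death_interval=k)
            for k in (None, 5, 15, 30)}


@pytest.fixture(scope="session")
def extinction_run():
    """Reduced-scale scenario with a short energetic reserve (K=2)."""
    from reefsph.validation import run_reduced_scenario
    return run_reduced_scenario(death_interval=2, n_growth_steps=45)
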