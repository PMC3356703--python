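import numpy as np
import pytest
from hypothesis import settings

from mnpbpk.synth import make_toy_fixture, make_two_compartment_fixture

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def toy():
    return make_toy_fixture()


@pytest.fixture(scope="session")
def two_comp():
    return make_two_compartment_fixture()


@pytest.fixture(scope="session")
def rat():
    from mnpbpk.species import load_species_defaults
    return load_species_defaults("rat")


@pytest.fixture(scope="session")
def monkey():
    from mnpbpk.species import load_species_defaults
    return load_species_defaults("monkey")


@pytest.fixture(scope="session")
def human():
    from mnpbpk.species import load_species_defaults
    return load_species_defaults("human")


def rk4(rhs, y0, t0, t1, dt):
    """Fixed-step classical Runge–Kutta, independent oracle for the solver."""
    y = np.asarray(y0, dtype=float).copy()
    t = t0
    n = int(round((t1 - t0) / dt))
    for _ in range(n):
        k1 = rhs(t, y)
        k2 = rhs(t + dt / 2, y + dt / 2 * k1)
        k3 = rhs(t + dt / 2, y + dt / 2 * k2)
        k4 = rhs(t + dt, y + dt * k3)
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += dt
    return y
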