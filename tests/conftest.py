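import numpy as np
import pytest

import deermix as dm


@pytest.fixture(scope="session")
def grid():
    return dm.DistanceGrid.default()


@pytest.fixture(scope="session")
def times():
    return dm.default_times()


@pytest.fixture(scope="session")
def acq():
    return dm.AcquisitionModel(lambda_mod=0.3)


@pytest.fixture(scope="session")
def kernel(times, grid):
    return dm.build_kernel(times, grid)


@pytest.fixture(scope="session")
def undocked_clean(grid, acq, times):
    """Noiseless trace of the pure undocked (light-state) component."""
    return dm.simulate_trace(dm.gaussian_distribution(dm.UNDOCKED, grid), acq, times)


@pytest.fixture(scope="session")
def docked_clean(grid, acq, times):
    """Noiseless trace of the pure docked (dark-proxy) component."""
    return dm.simulate_trace(dm.gaussian_distribution(dm.DOCKED, grid), acq, times)


def brute_force_kernel(t, r, n_nodes=100_001):
    """Independent quadrature oracle for the powder-averaged dipolar kernel."""
    x = np.linspace(0.0, 1.0, n_nodes)
    phi = 2.0 * np.pi * dm.dipolar_frequency(r) * t
    return np.trapezoid(np.cos((3.0 * x**2 - 1.0) * phi), x)
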