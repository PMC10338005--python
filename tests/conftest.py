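import numpy as np
import pytest

from wavydrift.channel import ModelParams, make_grid
from wavydrift.baseflow import base_velocities
from wavydrift.meandrift import compute_mean_drift


@pytest.fixture(scope="session")
def params_wavy():
    """Reference wavy-channel mean-flow case: beta=0.4, alpha=4, one cell."""
    return ModelParams(alpha=4.0, beta=0.4, Ri=0.0, sigma=1.0, n=1)


@pytest.fixture(scope="session")
def base_wavy(params_wavy):
    grid = make_grid(params_wavy, Nx_cell=128, Neta=257)
    return base_velocities(params_wavy, grid)


@pytest.fixture(scope="session")
def drift_wavy(params_wavy):
    return compute_mean_drift(params_wavy, Nx_cell=128, Neta=257)


@pytest.fixture(scope="session")
def transport_params():
    """Transport base case: beta=0.2, alpha=4, sigma=Ri=1, three cells."""
    return ModelParams(alpha=4.0, beta=0.2, Ri=1.0, sigma=1.0, n=3)


def measured_order(errors, ratio=2.0):
    """Convergence orders from successive errors on a x`ratio` refinement."""
    errors = np.asarray(errors, dtype=float)
    return np.log(errors[:-1] / errors[1:]) / np.log(ratio)
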