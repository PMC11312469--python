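import numpy as np
import pytest

import steerid as s
from steerid.kernels import default_lag_grid


@pytest.fixture(scope="session")
def basis():
    return s.build_basis()


@pytest.fixture(scope="session")
def lag_grid():
    return default_lag_grid()


@pytest.fixture(scope="session")
def f_drift_params():
    """Second-order parameters of the drift-context reference fit
    (zeta, wn, amplitude G, delay)."""
    return s.SecondOrderParams.from_amplitude(
        zeta=0.31, omega_n=10.67, G=0.29, delay=0.17
    )


@pytest.fixture(scope="session")
def f_drift_kernel(f_drift_params, lag_grid):
    return s.second_order_kernel(f_drift_params, lag_grid)


@pytest.fixture(scope="session")
def true_basis_kernel(basis, f_drift_kernel):
    """A ground-truth kernel exactly inside the basis span (the least-squares
    projection of the second-order reference kernel onto the basis)."""
    w, *_ = np.linalg.lstsq(basis.B, f_drift_kernel.k, rcond=None)
    return s.kernel_from_weights(w, basis)


@pytest.fixture(scope="session")
def drift_cfg():
    return s.TaskConfig(context="drift")


@pytest.fixture(scope="session")
def step_cfg():
    return s.TaskConfig(context="step")


@pytest.fixture(scope="session")
def quiet_plant():
    return s.PlantConfig(noise_sd=0.0)


@pytest.fixture(scope="session")
def drift_trials_noiseless(drift_cfg, quiet_plant, true_basis_kernel):
    """30 noiseless drift trials simulated from the basis-span kernel."""
    return s.make_dataset(drift_cfg, quiet_plant, true_basis_kernel, 30, seed=301)


def single_step_target(amp: float, n: int = 1700, step_frame: int = 100,
                       dt: float = 1.0 / 85.0) -> s.TargetTrajectory:
    """A target with exactly one step, for controlled step-response tests."""
    t = dt * np.arange(n)
    T = np.zeros(n)
    T[step_frame:] = amp
    return s.TargetTrajectory(
        t=t, T_world=T, T_displayed=T.copy(),
        step_times=np.array([step_frame * dt]),
        step_amplitudes=np.array([amp]),
        context="step",
    )
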