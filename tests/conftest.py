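import numpy as np
import pytest

import tgtquant as tq
from tgtquant.calibration import CalibrationResult


@pytest.fixture(scope="session")
def calib800() -> CalibrationResult:
    """A known-good calibration matching the default generator I1."""
    return CalibrationResult(single_fluor_intensity=800.0, n_events=60,
                             dispersion=0.02)


@pytest.fixture(scope="session")
def default_sim():
    """One default rupture simulation shared by read-only tests."""
    params = tq.AcquisitionParams(seed=11)
    scenario = tq.SpreadingScenario(n_events=300)
    stack, truth = tq.simulate_rupture_stack(params, scenario)
    return params, scenario, stack, truth


@pytest.fixture(scope="session")
def clean_sim():
    """Noise-free, drift-free simulation for exactness checks."""
    params = tq.AcquisitionParams(seed=21, shot_noise=False, read_noise_sd=0.0)
    scenario = tq.SpreadingScenario(n_events=100)
    stack, truth = tq.simulate_rupture_stack(
        params, scenario, include_fiducials=False,
        drift_velocity=(0.0, 0.0), drift_jitter_sd=0.0)
    return params, scenario, stack, truth


def disk_mask(shape, center, radius):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2
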