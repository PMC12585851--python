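import numpy as np
import pytest

from stridecost.io import SignalChannel
from stridecost.preprocess import StrideSeries
from stridecost.synthetic import SyntheticGaitConfig, generate_gait_trial

NOISE_FREE = {"angle": 0.0, "moment": 0.0, "grf_force": 0.0, "other": 0.0}


def constant_torque_stride(
    value: float, duration: float = 1.0, rate: float = 100.0, joint: str = "hip_moment"
) -> StrideSeries:
    """A single-joint stride with constant torque; cost under the
    torque-squared model is value**2 exactly."""
    n = int(round(duration * rate)) + 1
    ch = SignalChannel(joint, np.full(n, float(value)))
    return StrideSeries(
        channels={joint: ch}, t_start=0.0, duration=(n - 1) / rate, sampling_rate=rate
    )


@pytest.fixture(scope="session")
def default_trial():
    """One synthetic trial at the default study conditions, with truth."""
    cfg = SyntheticGaitConfig(seed=42)
    return generate_gait_trial(cfg)


@pytest.fixture(scope="session")
def quiet_trial():
    """A fully deterministic trial: no amplitude/period/measurement noise."""
    cfg = SyntheticGaitConfig(
        seed=7, n_strides=10, sigma_amplitude=0.0, sigma_period=0.0, sigma_meas=dict(NOISE_FREE)
    )
    return generate_gait_trial(cfg)
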