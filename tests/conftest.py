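import numpy as np
import pytest

from manostat import ProductionProfile, ReactorConfig, simulate


@pytest.fixture(scope="session")
def default_config() -> ReactorConfig:
    return ReactorConfig(headspace_volume_mL=50.0)


@pytest.fixture(scope="session")
def noisefree_config() -> ReactorConfig:
    """Sensor model effectively disabled: tiny quantization, no noise."""
    return ReactorConfig(
        headspace_volume_mL=50.0,
        sensor_noise_sd_bar=0.0,
        sensor_resolution_bar=1e-9,
    )


@pytest.fixture(scope="session")
def five_day_run(default_config):
    """5-day reactor at a constant 8 mL STP/d with the default sensor model."""
    profile = ProductionProfile(rate_mL_STP_d=8.0)
    return simulate(default_config, profile, 5.0, seed=11)


@pytest.fixture
def sawtooth_trace():
    """Hand-built sawtooth: linear rise 1.05→1.2, instant drop, 4 cycles."""
    from manostat import PressureTrace

    rise = np.linspace(1.05, 1.2, 31)
    press = np.concatenate([rise] * 4 + [[1.05]])
    time_s = np.arange(len(press)) * 20.0
    return PressureTrace(time_s, press, "SAW")
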