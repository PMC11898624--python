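import pytest
from hypothesis import HealthCheck, settings

from stemresp import ChamberSpec, EnvState, SimulationConfig

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def chamber():
    return ChamberSpec(volume_cm3=100.0, area_m2=0.0028)


@pytest.fixture
def env():
    return EnvState(temp_C=20.0, pressure_kPa=101.325, rh_pct=70.0)


@pytest.fixture
def quiet_config():
    """Noise-free simulation with evaporation on."""
    return SimulationConfig(resp_flux=2.0, rq_true=1.0, evap_rate=0.5,
                            noise_sd_co2=0.0, noise_sd_o2=0.0, seed=11)
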