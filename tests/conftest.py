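import numpy as np
import pytest
from hypothesis import settings as hyp_settings

import dustintake as di

hyp_settings.register_profile("ci", derandomize=True, max_examples=50)
hyp_settings.load_profile("ci")


@pytest.fixture(scope="session")
def dust_scenario() -> di.ExposureScenario:
    """Chlorpyrifos via indoor dust, moment-matched from the packaged table."""
    return di.load_scenario("chlorpyrifos_dust")


@pytest.fixture(scope="session")
def soil_scenario() -> di.ExposureScenario:
    return di.load_scenario("chlorpyrifos_soil")


@pytest.fixture(scope="session")
def all_scenarios() -> list:
    return [di.load_scenario(name) for name in di.PACKAGED_SCENARIOS]


@pytest.fixture
def small_settings() -> di.SimulationSettings:
    """Fast settings for unit tests; study-scale runs live in the acceptance suite."""
    return di.SimulationSettings(iterations=20_000, replicates=4, seed=7)


@pytest.fixture
def point_mass_scenario() -> di.ExposureScenario:
    """Degenerate scenario: ir=10 mg/day, conc=1 ug/g, bw=10 kg, ADI 0.01."""
    return di.ExposureScenario(
        compound="custom",
        route="point",
        ir=di.LognormalSpec.point_mass(10.0, "mg/day"),
        conc=di.LognormalSpec.point_mass(1.0, "ug/g"),
        bw=di.LognormalSpec.point_mass(10.0, "kg"),
        adi=0.01,
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
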