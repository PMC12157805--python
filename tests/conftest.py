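import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from spabalance.calibration import CalibrationModel, LoadCellFit
from spabalance.raw_io import LightSchedule
from spabalance.simulator import SimulationConfig, simulate_raw


@pytest.fixture(scope="session")
def identity_model() -> CalibrationModel:
    """Signals already in grams: w = 1 * s + 0 per cell."""
    cell = LoadCellFit(a=1.0, b=0.0, r2=1.0, see_g=0.0, n_points=0)
    return CalibrationModel(cells=(cell, cell, cell))


@pytest.fixture(scope="session")
def tiny_schedule() -> LightSchedule:
    """2-h recording day: dark 00:00-00:59, light 01:00-01:59, gap after."""
    return LightSchedule(
        dark_windows=((0, 60),),
        light_windows=((60, 120),),
        gap_windows=((120, 1440),),
    )


@pytest.fixture(scope="session")
def tiny_sim(tiny_schedule):
    """A small (2-h) simulated recording with known ground truth."""
    config = SimulationConfig(
        schedule=tiny_schedule,
        start_clock=0,
        sigma_dark=24.0,
        sigma_light=8.0,
        seed=42,
    )
    return simulate_raw(config)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
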