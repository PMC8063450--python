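import numpy as np
import pytest

from movebench.habitat import HabitatParams, HabitatRaster, generate_habitat
from movebench.movement import MovementParams, TripConfig, observe_track, simulate_path


@pytest.fixture(scope="session")
def medium_raster() -> HabitatRaster:
    """Autocorrelated continuous landscape, small enough for fast tests."""
    return generate_habitat(HabitatParams(0.4, 0.2, "medium", "continuous"), 400, seed=11)


@pytest.fixture(scope="session")
def noise_raster() -> HabitatRaster:
    """Uncorrelated landscape (hab_auto = 0): raw iid U(0,1) values."""
    return generate_habitat(HabitatParams(0.0, 0.0, "medium", "continuous"), 200, seed=7)


@pytest.fixture(scope="session")
def sim_track(medium_raster):
    """One simulated trip at reduced scale shared by design/fit tests."""
    params = MovementParams(
        sigma_sd=0.8, sigma_omega=0.6, sigma_alpha=0.02,
        sigma_ran=1.0, sigma_ran2=0.3, error_spat=1.0,
    )
    trip = TripConfig(start=(200, 200), centre=(150, 260), n_steps=1500, n_obs=100)
    rng = np.random.default_rng(42)
    path = simulate_path(medium_raster, params, trip, rng)
    return observe_track(path, trip.n_obs, params.error_spat, rng)
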