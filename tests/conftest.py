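import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import killcurve as kc

settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


def make_series(rng, n=None, well_id="W01", construct="X", et_ratio=1.0,
                concentration=0.0, step=6.0):
    """Random positive well series on a grid anchored at 2 h."""
    n = n if n is not None else int(rng.integers(10, 49))
    t = 2.0 + step * np.arange(n)
    return kc.WellTimeSeries(
        well_id=well_id, construct=construct, et_ratio=et_ratio,
        concentration=concentration, t=t,
        e_live=rng.integers(50, 5000, n).astype(float),
        red_px=rng.uniform(10, 5e4, n),
        phase_px=rng.uniform(1e4, 5e5, n))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_config():
    """A reduced titration for fast simulation-backed tests."""
    doses = tuple(sorted([0.0] + [100e-6 / 3**k for k in range(9)]))
    return kc.SimulationConfig(concentrations=doses,
                               effector_to_target_ratios=(1.0,), rng_seed=7)


@pytest.fixture
def small_profile(small_config):
    plate = kc.build_platemap(["X"], (1.0,), small_config.concentrations, replicates=1)
    truth = kc.simulate_plate(small_config, plate)
    return kc.build_profiles(truth.wells)[0]
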