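import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import termwalk as tw

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def levy_track_1e6() -> tw.Trajectory:
    """Unbounded constant-speed Levy walk, mu=2.10, 1e6 grid samples.

    The reference superdiffusive track: move durations are power-law
    with exponent 2.10 above one sampling interval, no waiting bouts.
    """
    cfg = tw.SimConfig(
        model="levy_walk",
        mu=2.10,
        p_wait=0.0,
        speed=10.0,
        dt=0.5,
        n_samples=10**6,
        arena_diameter=None,
        boundary="none",
        x_min_step=0.5,
        seed=42,
    )
    return tw.simulate_walker(cfg)


@pytest.fixture(scope="session")
def brownian_track_1e5() -> tw.Trajectory:
    """Unbounded Gaussian walker, 1e5 samples — the normal-diffusion control."""
    cfg = tw.SimConfig(
        model="brownian",
        n_samples=10**5,
        arena_diameter=None,
        boundary="none",
        seed=5,
    )
    return tw.simulate_walker(cfg)


@pytest.fixture(scope="session")
def ballistic_track() -> tw.Trajectory:
    cfg = tw.SimConfig(
        model="ballistic",
        n_samples=2000,
        arena_diameter=None,
        boundary="none",
        seed=1,
    )
    return tw.simulate_walker(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture()
def small_levy_track() -> tw.Trajectory:
    """Confined Levy walk with waits, 5000 samples — cheap pipeline input."""
    cfg = tw.SimConfig(model="levy_walk", p_wait=0.3, n_samples=5000, seed=2)
    return tw.simulate_walker(cfg)
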