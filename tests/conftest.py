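import numpy as np
import pytest

from mwmaze import (
    PoolGeometry,
    StrategyParams,
    Trajectory,
    make_annuli,
    make_quadrants,
    simulate_trajectory,
)
from mwmaze.trajectory import DETECTED


def make_traj(points, frame_rate_hz=25.0, t0=0.0):
    """Fully valid trajectory from an (n, 2) array of metric points."""
    pts = np.asarray(points, float)
    n = len(pts)
    times = t0 + np.arange(n) / frame_rate_hz
    return Trajectory(
        times,
        pts,
        np.ones(n, bool),
        np.array([DETECTED] * n, object),
        frame_rate_hz=frame_rate_hz,
    )


@pytest.fixture(scope="session")
def geom():
    return PoolGeometry()


@pytest.fixture(scope="session")
def quadrants(geom):
    return make_quadrants(geom)


@pytest.fixture(scope="session")
def annuli(geom):
    return make_annuli(geom, 1.0)


@pytest.fixture(scope="session")
def random_walk_trials(geom):
    """200 seeded random-search swims (10 s cap), the shared substrate for
    oracle-equivalence and conservation checks."""
    params = StrategyParams(
        "random_search",
        speed_mean=0.18,
        heading_noise_sd_deg=35.0,
        platform_attraction=0.05,
        max_duration_s=10.0,
    )
    return [simulate_trajectory(params, geom, 1000 + k)[0] for k in range(200)]


@pytest.fixture(scope="session")
def uniform_disc_points(geom):
    rng = np.random.default_rng(99)
    r = geom.pool_radius_m * np.sqrt(rng.random(10_000))
    th = rng.uniform(0, 2 * np.pi, 10_000)
    return np.stack([r * np.cos(th), r * np.sin(th)], axis=1)
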