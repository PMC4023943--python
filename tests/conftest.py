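import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

import sourcesink as ss


def square(x0, y0, side=1.0):
    return Polygon(
        [(x0, y0), (x0 + side, y0), (x0 + side, y0 + side), (x0, y0 + side), (x0, y0)]
    )


@pytest.fixture
def two_squares():
    """Regions 1 and 2: unit squares side by side sharing the edge x=1."""
    return ss.RegionPartition([(1, square(0, 0)), (2, square(1, 0))])


@pytest.fixture
def grid8():
    """8-region partition: 3x3 grid over [0,3]^2 minus the (2,0) cell."""
    cfg = ss.SimConfig(region_grid=ss.RegionGridSpec(3, 3, ((2, 0),)))
    return ss.region_partition(cfg)


def make_traj(rows):
    """Build a TrajectoryTable from (year, j, site, depth, d, s, lon, lat) tuples."""
    df = pd.DataFrame(
        rows,
        columns=[
            "year", "source_id", "site_id", "depth_level",
            "release_index", "day_offset", "lon", "lat",
        ],
    )
    return ss.TrajectoryTable(df)


@pytest.fixture
def straight_track():
    """One propagule moving +0.1 lon per day for 11 days from the origin."""
    rows = [(2000, 1, 1, 1, 1, s, 0.1 * s, 0.0) for s in range(11)]
    return make_traj(rows)


def small_scenario(seed=3, sigma=0.0, K=4, years=10):
    """Well-posed 2-source scenario on the 8-region grid; truth aligned with
    the simulated occupancy so all parameters are identifiable."""
    cfg = ss.SimConfig(
        sources=[ss.SourceSpec((0.6, 0.6), 3), ss.SourceSpec((1.6, 1.4), 3)],
        n_depths=2,
        schedule=ss.ReleaseSchedule(window_length=20, step=2, tracking_end=(5, 15)),
        years=list(range(2000, 2000 + years)),
        sigma=sigma,
        seed=seed,
    )
    D = cfg.schedule.n_releases
    part = ss.region_partition(cfg)
    traj = ss.simulate_trajectories(cfg)
    G = ss.compute_exposure(traj, part, cfg.schedule)
    occ = G.G.sum(axis=(1, 3))
    theta = np.zeros((2, part.n_regions))
    for j in range(2):
        theta[j, np.argsort(occ[j])[-2:]] = [0.45, 0.55]
    cfg.true_theta = theta
    cfg.true_w = np.array([2.0, 1.0])
    cfg.true_f = np.vstack(
        [
            ss.spline_curve(D, K, [1.0, 2.0, 0.5, 0.2]),
            ss.spline_curve(D, K, [0.2, 0.5, 2.0, 1.0]),
        ]
    )
    Y = ss.simulate_abundance(G, cfg)
    basis = ss.build_basis(D, K)
    return cfg, part, traj, G, Y, basis


@pytest.fixture(scope="session")
def noiseless_fit_inputs():
    cfg, part, traj, G, Y, basis = small_scenario(sigma=0.0)
    return cfg, G, Y, basis


@pytest.fixture(scope="session")
def noisy_fit_inputs():
    cfg, part, traj, G, Y, basis = small_scenario(seed=7, sigma=0.05)
    return cfg, G, Y, basis
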