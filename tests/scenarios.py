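"""Shared synthetic scenarios for the acceptance suite.

Each builder returns everything a criterion needs; scenario shapes follow
the acceptance criteria (problem sizes, noise levels) while the velocity
fields are chosen so that distinct sources produce distinct, largely
disjoint region-occupancy signatures (identifiability by design).
"""

import numpy as np

import sourcesink as ss


def recovery_scenario(seed=3, sigma=0.0):
    """J=2, I=4, D=10, K=4, T=10 scenario; truth aligned with occupancy
    and release curves inside the fitting basis span."""
    cfg = ss.SimConfig(
        lon_bounds=(0.0, 2.0),
        lat_bounds=(0.0, 2.0),
        region_grid=ss.RegionGridSpec(2, 2, ()),
        sources=[ss.SourceSpec((0.5, 0.4), 3, 0.15), ss.SourceSpec((1.5, 0.4), 3, 0.15)],
        n_depths=2,
        schedule=ss.ReleaseSchedule(window_length=20, step=2, tracking_end=(6, 30)),
        years=list(range(2000, 2010)),
        drift=(0.002, 0.008),
        rot_amp=0.006,
        noise_sd=0.03,
        year_drift_range=(0.7, 1.3),
        sigma=sigma,
        seed=seed,
    )
    D = cfg.schedule.n_releases
    assert D == 10
    part = ss.region_partition(cfg)
    traj = ss.simulate_trajectories(cfg)
    G = ss.compute_exposure(traj, part, cfg.schedule)
    occ = G.G.sum(axis=(1, 3))
    theta = np.zeros((2, 4))
    for j in range(2):
        theta[j, np.argsort(occ[j])[-2:]] = [0.45, 0.55]
    cfg.true_theta = theta
    cfg.true_w = np.array([2.0, 1.0])
    cfg.true_f = np.vstack(
        [
            ss.spline_curve(D, 4, [1.0, 2.0, 0.5, 0.2]),
            ss.spline_curve(D, 4, [0.2, 0.5, 2.0, 1.0]),
        ]
    )
    Y = ss.simulate_abundance(G, cfg)
    basis = ss.build_basis(D, 4)
    return cfg, part, traj, G, Y, basis


def sparse_scenario(seed=42, years=None):
    """Post-1990-scale scenario: J=4, I=8, D=40, K=10, T=14; sparse truth on
    the top-2 occupied regions per source; curves in the K=10 basis span.
    Returns (cfg, G, basis, mask, true_theta); draw Y per replicate by
    setting cfg.sigma / cfg.seed and calling simulate_abundance."""
    if years is None:
        years = list(range(1991, 2005))
    cfg = ss.reference_design(years=years, seed=seed)
    cfg.sources = [
        ss.SourceSpec((0.5, 0.35), 4, 0.18),
        ss.SourceSpec((1.5, 0.35), 4, 0.18),
        ss.SourceSpec((2.5, 0.35), 4, 0.18),
        ss.SourceSpec((2.0, 1.75), 4, 0.18),
    ]
    cfg.n_depths = 1
    cfg.drift = (0.002, 0.007)
    cfg.rot_amp = 0.006
    cfg.noise_sd = 0.035
    cfg.year_drift_range = (0.7, 1.3)
    part = ss.region_partition(cfg)
    traj = ss.simulate_trajectories(cfg)
    G = ss.compute_exposure(traj, part, cfg.schedule)
    occ = G.G.sum(axis=(1, 3))
    mask = ss.structural_zero_mask(G)
    theta = np.zeros((4, 8))
    for j in range(4):
        theta[j, np.argsort(occ[j])[-2:]] = [0.45, 0.55]
    cfg.true_theta = theta
    coef = [
        [0, 0.5, 2, 1, 0.3, 0, 0, 0, 0, 0],
        [0, 0, 1, 2, 0.8, 0, 0, 0, 0, 0],
        [0, 0, 0, 1, 2, 1, 0, 0, 0, 0],
        [0, 0, 0, 0, 0.5, 2, 1.5, 0, 0, 0],
    ]
    cfg.true_f = np.vstack([ss.spline_curve(40, 10, c) for c in coef])
    basis = ss.build_basis(40, 10)
    return cfg, G, basis, mask, theta


#: strictly positive: the unpenalized fit serves as the pathwise warm start
#: (and pilot for the adaptive weights) but is not itself a tuning candidate
SPARSE_LAMBDA_GRID = np.array(
    [5e-4, 1e-3, 2e-3, 4e-3, 8e-3, 1.6e-2, 3.2e-2, 6.4e-2, 1.28e-1]
)


def tiny_scenario(seed=100, n_years=16):
    """Small J=2, I=4, D=5, K=3 scenario for the resampling-heavy criteria
    (permutation null, bootstrap coverage)."""
    cfg = ss.SimConfig(
        lon_bounds=(0.0, 2.0),
        lat_bounds=(0.0, 2.0),
        region_grid=ss.RegionGridSpec(2, 2, ()),
        sources=[ss.SourceSpec((0.5, 0.4), 3, 0.15), ss.SourceSpec((1.5, 0.4), 3, 0.15)],
        n_depths=1,
        schedule=ss.ReleaseSchedule(window_length=10, step=2, tracking_end=(5, 31)),
        years=list(range(1990, 1990 + n_years)),
        drift=(0.002, 0.009),
        rot_amp=0.006,
        noise_sd=0.03,
        year_drift_range=(0.7, 1.3),
        seed=seed,
    )
    D = cfg.schedule.n_releases
    part = ss.region_partition(cfg)
    traj = ss.simulate_trajectories(cfg)
    G = ss.compute_exposure(traj, part, cfg.schedule)
    occ = G.G.sum(axis=(1, 3))
    theta = np.zeros((2, 4))
    for j in range(2):
        theta[j, np.argsort(occ[j])[-2:]] = [0.45, 0.55]
    cfg.true_theta = theta
    cfg.true_w = np.array([1.5, 1.0])
    cfg.true_f = np.vstack(
        [ss.spline_curve(D, 3, [1.0, 2.0, 0.5]), ss.spline_curve(D, 3, [0.5, 2.0, 1.0])]
    )
    basis = ss.build_basis(D, 3)
    return cfg, G, basis


#: fast fit options for resampling-heavy criteria: few relaxation cycles,
#: quasi-Newton polish does the accurate final descent
FAST_OPTS = ss.FitOptions(n_restarts=1, max_iter=20, tol=1e-6,
                          polish_ftol=1e-11, polish_gtol=1e-8, polish_maxiter=60)
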