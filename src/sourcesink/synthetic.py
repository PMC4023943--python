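"""Synthetic drift scenarios with known ground truth.

Generates trajectory tables from a toy advection field (mean drift plus a
rotational component plus Gaussian jitter), a rectangular grid sink
partition, and abundance matrices drawn from the source-sink model with
known sparse parameters — so the full pipeline is testable end to end with
no external data.  A reference-design builder provides the full-size
release layout: 4 sources (100 + 50 + 50 + 50 sites), 3 depths, 40
every-other-day releases from March 15, and an 8-region sink partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .data_model import (
    AbundanceMatrix,
    ExposureTensor,
    RegionPartition,
    ReleaseSchedule,
    TrajectoryTable,
    TRAJECTORY_COLUMNS,
)


@dataclass(frozen=True)
class SourceSpec:
    center: tuple[float, float]   # (lon, lat)
    n_sites: int
    scatter: float = 0.05         # sd of site positions around the center


@dataclass(frozen=True)
class RegionGridSpec:
    rows: int
    cols: int
    excluded: tuple = ()          # (row, col) cells dropped from the partition


@dataclass
class SimConfig:
    """Complete specification of a synthetic scenario."""

    lon_bounds: tuple[float, float] = (0.0, 3.0)
    lat_bounds: tuple[float, float] = (0.0, 3.0)
    region_grid: RegionGridSpec = field(default_factory=lambda: RegionGridSpec(3, 3, ((2, 0),)))
    sources: list = field(default_factory=list)
    n_depths: int = 3
    schedule: ReleaseSchedule = field(default_factory=ReleaseSchedule)
    years: list = field(default_factory=lambda: list(range(2000, 2010)))
    drift: tuple[float, float] = (0.012, 0.012)   # mean displacement per day
    rot_amp: float = 0.004                        # rotational component amplitude
    rot_period: float = 60.0                      # days per rotation cycle
    noise_sd: float = 0.003                       # random-walk step sd
    year_drift_range: tuple[float, float] = (0.8, 1.2)  # per-year drift multiplier
    true_w: np.ndarray | None = None
    true_theta: np.ndarray | None = None
    true_f: np.ndarray | None = None
    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("noise sd sigma must be >= 0")
        if self.true_theta is not None:
            th = np.asarray(self.true_theta, dtype=float)
            if (th < 0).any() or not np.allclose(th.sum(axis=1), 1.0):
                raise ValueError("true theta rows must be non-negative and sum to 1")
        if self.true_f is not None:
            f = np.asarray(self.true_f, dtype=float)
            if (f < 0).any() or not np.allclose(f.sum(axis=1), 1.0):
                raise ValueError("true f rows must be non-negative and sum to 1")

    @property
    def n_sources(self) -> int:
        return len(self.sources)

    @property
    def n_regions(self) -> int:
        g = self.region_grid
        return g.rows * g.cols - len(g.excluded)


def region_partition(config: SimConfig) -> RegionPartition:
    """Rectangular grid partition of the domain, excluded cells dropped,
    region ids 1..I in row-major order."""
    g = config.region_grid
    lon0, lon1 = config.lon_bounds
    lat0, lat1 = config.lat_bounds
    dlon = (lon1 - lon0) / g.cols
    dlat = (lat1 - lat0) / g.rows
    regions = []
    rid = 0
    for r in range(g.rows):
        for c in range(g.cols):
            if (r, c) in set(map(tuple, g.excluded)):
                continue
            rid += 1
            x0, y0 = lon0 + c * dlon, lat0 + r * dlat
            poly = Polygon(
                [(x0, y0), (x0 + dlon, y0), (x0 + dlon, y0 + dlat), (x0, y0 + dlat), (x0, y0)]
            )
            regions.append((rid, poly))
    return RegionPartition(regions)


def source_sites(config: SimConfig) -> pd.DataFrame:
    """One row per release site: source_id, site_id, lon, lat.

    Site positions are scattered around each source's center; fixed by the
    scenario seed and shared across years.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for j, src in enumerate(config.sources, start=1):
        pos = rng.normal(loc=src.center, scale=src.scatter, size=(src.n_sites, 2))
        for s in range(src.n_sites):
            rows.append((j, s + 1, pos[s, 0], pos[s, 1]))
    return pd.DataFrame(rows, columns=["source_id", "site_id", "lon", "lat"])


def release_table(config: SimConfig, year: int) -> pd.DataFrame:
    """One row per released propagule in the given year (no positions).

    Enumerates the full release design: every site of every source, each
    depth level, each release event.
    """
    sites = source_sites(config)
    D = config.schedule.n_releases
    depths = np.arange(1, config.n_depths + 1)
    releases = np.arange(1, D + 1)
    out = sites.loc[:, ["source_id", "site_id"]].merge(
        pd.DataFrame({"depth_level": depths}), how="cross"
    ).merge(pd.DataFrame({"release_index": releases}), how="cross")
    out.insert(0, "year", year)
    return out


def simulate_trajectories(config: SimConfig) -> TrajectoryTable:
    """Forward-Euler drift tracks for every propagule in the design.

    Daily step = year-scaled mean drift + rotational term (a function of
    absolute day within the season, shared across propagules) + Gaussian
    jitter; one propagule per (year, site, depth, release); deterministic
    given the config seed.
    """
    rng = np.random.default_rng(config.seed + 1)
    sites = source_sites(config)
    sched = config.schedule
    D = sched.n_releases
    offsets = sched.release_offsets()
    year_mult = {
        y: rng.uniform(*config.year_drift_range) for y in config.years
    }
    drift = np.asarray(config.drift)
    frames = []
    for year in config.years:
        mult = year_mult[year]
        for d in range(1, D + 1):
            n_days = sched.tracking_days(d, year)
            day_abs = offsets[d - 1] + np.arange(n_days)  # absolute day in season
            phase = 2 * np.pi * day_abs / config.rot_period
            rot = config.rot_amp * np.stack([np.cos(phase), np.sin(phase)], axis=1)
            step_common = mult * drift[None, :] + rot  # (n_days, 2)
            n_prop = len(sites) * config.n_depths
            noise = rng.normal(0.0, config.noise_sd, size=(n_prop, n_days, 2))
            # depth acts as a mild speed modifier so depths are genuine replicates
            depth_mult = 1.0 + 0.05 * (np.arange(config.n_depths) - (config.n_depths - 1) / 2)
            starts = np.repeat(sites[["lon", "lat"]].to_numpy(), config.n_depths, axis=0)
            dm = np.tile(depth_mult, len(sites))[:, None, None]
            steps = dm * step_common[None, :, :] + noise
            steps[:, 0, :] = 0.0  # day 0 is the release position itself
            pos = starts[:, None, :] + np.cumsum(steps, axis=1)

            src = np.repeat(sites["source_id"].to_numpy(), config.n_depths)
            sid = np.repeat(sites["site_id"].to_numpy(), config.n_depths)
            dep = np.tile(np.arange(1, config.n_depths + 1), len(sites))
            frames.append(
                pd.DataFrame(
                    {
                        "year": year,
                        "source_id": np.repeat(src, n_days),
                        "site_id": np.repeat(sid, n_days),
                        "depth_level": np.repeat(dep, n_days),
                        "release_index": d,
                        "day_offset": np.tile(np.arange(n_days), n_prop),
                        "lon": pos[:, :, 0].ravel(),
                        "lat": pos[:, :, 1].ravel(),
                    }
                )
            )
    df = pd.concat(frames, ignore_index=True)[list(TRAJECTORY_COLUMNS)]
    return TrajectoryTable(df)


def model_mean(G: ExposureTensor, w, theta, f) -> np.ndarray:
    """Noiseless response sum_j w[j] theta[j, i] sum_d f[j, d] G[j, d, i, t]."""
    return np.einsum("j,ji,jd,jdit->it", np.asarray(w, float),
                     np.asarray(theta, float), np.asarray(f, float), G.G)


def simulate_abundance(G: ExposureTensor, config: SimConfig) -> AbundanceMatrix:
    """Draw Y from the model with the config's true parameters and i.i.d.
    Normal(0, sigma^2) noise; all cells observed."""
    if config.true_w is None or config.true_theta is None or config.true_f is None:
        raise ValueError("config must carry true_w, true_theta, true_f")
    J, D, I, T = G.G.shape
    th = np.asarray(config.true_theta, float)
    f = np.asarray(config.true_f, float)
    if th.shape != (J, I) or f.shape != (J, D):
        raise ValueError(
            f"true parameter dims (theta {th.shape}, f {f.shape}) do not match G {G.G.shape}"
        )
    mean = model_mean(G, config.true_w, th, f)
    rng = np.random.default_rng(config.seed + 2)
    y = mean + rng.normal(0.0, config.sigma, size=mean.shape)
    return AbundanceMatrix(y=y, n_obs=np.ones(mean.shape, dtype=int), years=list(G.years))


def beta_shaped_curve(D: int, a: float = 3.0, b: float = 5.0) -> np.ndarray:
    """Smooth unimodal probability mass on 1..D (discretized beta density)."""
    x = (np.arange(1, D + 1) - 0.5) / D
    dens = x ** (a - 1) * (1 - x) ** (b - 1)
    return dens / dens.sum()


def spline_curve(D: int, K: int, coeffs: np.ndarray) -> np.ndarray:
    """Probability mass in the span of the fitting basis (exact-recovery
    scenarios): normalize Phi @ coeffs."""
    from .basis import build_basis

    f = build_basis(D, K).curve(np.asarray(coeffs, float))
    if (f < 0).any() or f.sum() <= 0:
        raise ValueError("coefficients must give a non-negative, non-null curve")
    return f / f.sum()


def reference_design(years: list[int] | None = None, seed: int = 0) -> SimConfig:
    """The full-size reference scenario: 4 sources with site counts (100, 50, 50,
    50), 3 release depths, every-other-day releases over the 80-day window
    from March 15 (40 events), an 8-region partition (3x3 grid minus the
    northernmost inshore cell), years 1982-2004."""
    if years is None:
        years = list(range(1982, 2005))
    sources = [
        SourceSpec(center=(2.4, 0.35), n_sites=100, scatter=0.12),  # peninsula-like, SE
        SourceSpec(center=(2.75, 0.9), n_sites=50, scatter=0.08),   # inner bay
        SourceSpec(center=(1.25, 1.6), n_sites=50, scatter=0.08),   # mid-shelf islands
        SourceSpec(center=(1.1, 2.45), n_sites=50, scatter=0.08),   # northern island
    ]
    J, I, D = 4, 8, 40
    theta = np.zeros((J, I))
    theta[0, [2, 5]] = [0.55, 0.45]
    theta[1, [0, 3]] = [0.8, 0.2]
    theta[2, [3, 6]] = [0.5, 0.5]
    theta[3, [4, 7]] = [0.6, 0.4]
    f = np.vstack(
        [
            beta_shaped_curve(D, 2.5, 5.0),
            beta_shaped_curve(D, 3.0, 4.0),
            beta_shaped_curve(D, 4.0, 3.0),
            beta_shaped_curve(D, 5.0, 2.5),
        ]
    )
    return SimConfig(
        region_grid=RegionGridSpec(3, 3, ((2, 0),)),
        sources=sources,
        n_depths=3,
        schedule=ReleaseSchedule(),
        years=years,
        true_w=np.array([2.0, 0.6, 1.5, 1.2]),
        true_theta=theta,
        true_f=f,
        sigma=0.1,
        seed=seed,
    )
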