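"""Region-occupancy covariates from drift trajectories.

Turns a :class:`~sourcesink.data_model.TrajectoryTable` into the exposure
tensor G[j, d, i, t] (mean fraction of tracked days spent in each sink
region), and provides the two trajectory/covariate transformations used by
the sensitivity experiments: forward shifting of positions and random
+/-frac perturbation of G.
"""

from __future__ import annotations

import logging

import numpy as np
import shapely
from shapely.geometry import Point

from .data_model import (
    ExposureTensor,
    PROPAGULE_KEY,
    RegionPartition,
    ReleaseSchedule,
    TrajectoryTable,
)

logger = logging.getLogger(__name__)


def assign_region(lon: float, lat: float, partition: RegionPartition) -> int | None:
    """Region id of the first polygon (lowest id) covering the point.

    Boundary inclusive; returns None when no polygon contains the point.
    Ties on shared edges resolve to the lowest region_id.
    """
    pt = Point(lon, lat)
    for rid, poly in partition.regions:
        if poly.covers(pt):
            return rid
    return None


def _region_matrix(lons: np.ndarray, lats: np.ndarray, partition: RegionPartition) -> np.ndarray:
    """Vectorized assign_region: (n,) array of region ids, 0 = outside.

    Lowest-id-wins on boundaries, matching :func:`assign_region`.
    """
    pts = shapely.points(lons, lats)
    out = np.zeros(len(pts), dtype=np.int32)
    for rid, poly in sorted(partition.regions, key=lambda r: -r[0]):
        inside = shapely.covers(poly, pts)
        out[inside] = rid
    return out


def compute_exposure(
    traj: TrajectoryTable,
    partition: RegionPartition,
    schedule: ReleaseSchedule,
) -> ExposureTensor:
    """Mean fraction-of-time occupancy per (source, release, region, year).

    For each propagule the occupancy fraction in region i is the count of
    recorded daily positions falling in i — from day_offset 0 through the
    offset of the tracking end date — divided by the number of recorded
    positions in that span.  G[j, d, i, t] averages these fractions over
    all propagules sharing (j, d, t), i.e. over sites and depth levels.
    Cells with no propagules are zero and listed in the coverage report.
    """
    df = traj.df
    if df.empty:
        raise ValueError("trajectory table is empty")
    years = traj.years
    year_pos = {y: t for t, y in enumerate(years)}
    J = int(df["source_id"].max())
    D = schedule.n_releases
    I = partition.n_regions
    T = len(years)

    regions = _region_matrix(df["lon"].to_numpy(), df["lat"].to_numpy(), partition)

    # per-row span limit: keep offsets within the tracked window
    tracking_days = np.array(
        [
            [schedule.tracking_days(d, y) for d in range(1, D + 1)]
            for y in years
        ]
    )  # (T, D)
    t_idx = df["year"].map(year_pos).to_numpy()
    d_idx = df["release_index"].to_numpy() - 1
    keep = df["day_offset"].to_numpy() < tracking_days[t_idx, d_idx]

    j_idx = df["source_id"].to_numpy() - 1

    # propagule grouping over kept rows
    key = df[list(PROPAGULE_KEY)].to_numpy()
    newgrp = np.ones(len(df), dtype=bool)
    if len(df) > 1:
        newgrp[1:] = (key[1:] != key[:-1]).any(axis=1)
    grp = np.cumsum(newgrp) - 1
    n_grp = grp[-1] + 1

    days_total = np.bincount(grp[keep], minlength=n_grp).astype(float)
    # per-propagule per-region day counts -> fractions
    frac = np.zeros((n_grp, I))
    in_region = keep & (regions > 0)
    np.add.at(frac, (grp[in_region], regions[in_region] - 1), 1.0)
    valid = days_total > 0
    n_excluded = int((~valid).sum())
    if n_excluded:
        logger.warning(
            "compute_exposure: %d propagule(s) with zero tracked days excluded", n_excluded
        )
    frac[valid] /= days_total[valid, None]

    # (j, d, t) of each propagule = values at its first row
    starts = np.flatnonzero(newgrp)
    pj = j_idx[starts]
    pd_ = d_idx[starts]
    pt = t_idx[starts]

    counts = np.zeros((J, D, T))
    np.add.at(counts, (pj[valid], pd_[valid], pt[valid]), 1.0)
    G = np.zeros((J, D, I, T))
    for i in range(I):
        np.add.at(G, (pj[valid], pd_[valid], i, pt[valid]), frac[valid, i])
    nz = counts > 0
    for i in range(I):
        G[:, :, i, :][nz] /= counts[nz]

    empty = [
        {"source_id": int(j + 1), "release_index": int(d + 1), "year": int(years[t])}
        for j, d, t in zip(*np.nonzero(~nz))
    ]
    coverage = {
        "n_propagules": int(valid.sum()),
        "n_excluded_zero_days": n_excluded,
        "n_empty_cells": len(empty),
        "empty_cells": empty,
    }
    return ExposureTensor(G=G, years=years, coverage=coverage)


def shift_trajectories(traj: TrajectoryTable, a: float) -> TrajectoryTable:
    """Shift propagule positions toward their future counterparts.

    The position at day offset s becomes the original position at scaled
    offset (1+a)*s — copied directly when that is an integer, otherwise
    linearly interpolated between the two bracketing integer offsets.
    Scaled offsets past the end of the recorded track truncate to the last
    recorded position.  The output keeps the original day_offset grid.
    """
    if a < 0:
        raise ValueError(f"shift rate must be non-negative, got {a}")
    if a > 0.5:
        raise ValueError(f"shift rate must be <= 0.5, got {a}")
    if a == 0:
        return TrajectoryTable(traj.df.copy())

    df = traj.df
    key = df[list(PROPAGULE_KEY)].to_numpy()
    newgrp = np.ones(len(df), dtype=bool)
    if len(df) > 1:
        newgrp[1:] = (key[1:] != key[:-1]).any(axis=1)
    grp = np.cumsum(newgrp) - 1
    starts = np.flatnonzero(newgrp)
    lengths = np.diff(np.append(starts, len(df)))

    s = df["day_offset"].to_numpy().astype(float)
    scaled = (1.0 + a) * s
    last = (lengths - 1).astype(float)[grp]  # max offset per propagule
    scaled = np.minimum(scaled, last)
    lo = np.floor(scaled).astype(np.int64)
    hi = np.minimum(lo + 1, last.astype(np.int64))
    wt = scaled - lo

    base = starts[grp]
    lon = df["lon"].to_numpy()
    lat = df["lat"].to_numpy()
    new_lon = (1 - wt) * lon[base + lo] + wt * lon[base + hi]
    new_lat = (1 - wt) * lat[base + lo] + wt * lat[base + hi]

    out = df.copy()
    out["lon"] = new_lon
    out["lat"] = new_lat
    return TrajectoryTable(out)


def perturb_exposure(G: ExposureTensor, frac: float = 0.05, seed: int = 0) -> ExposureTensor:
    """Multiply each entry by (1 + frac) or (1 - frac) with probability 1/2.

    Zeros are invariant; the multiplicative scheme cannot produce negative
    values.  Entries equal to 1 may marginally exceed 1 and are clipped
    back to 1 so the tensor invariants still hold.
    """
    if not 0 <= frac < 1:
        raise ValueError(f"frac must be in [0, 1), got {frac}")
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=G.G.shape)
    newG = np.clip(G.G * (1.0 + frac * signs), 0.0, 1.0)
    # renormalize any (j,d,t) whose region-sum was pushed above 1
    sums = newG.sum(axis=2, keepdims=True)
    over = sums > 1.0
    if over.any():
        newG = np.where(over, newG / sums, newG)
    return ExposureTensor(G=newG, years=list(G.years), coverage=dict(G.coverage))
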