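"""Core typed containers and file I/O for trajectories, regions, and abundance.

The containers here are deliberately thin wrappers around numpy/pandas
structures: a :class:`TrajectoryTable` holds per-propagule daily positions,
a :class:`RegionPartition` holds the sink polygons, and an
:class:`AbundanceMatrix` holds the region-by-year response on the
log(CPUE+1) scale.  Validation happens at construction time so downstream
code can assume the invariants.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, shape, mapping

logger = logging.getLogger(__name__)

TRAJECTORY_COLUMNS = (
    "year",
    "source_id",
    "site_id",
    "depth_level",
    "release_index",
    "day_offset",
    "lon",
    "lat",
)

#: columns identifying a single propagule (one drifting particle)
PROPAGULE_KEY = ("year", "source_id", "site_id", "depth_level", "release_index")


class FormatError(ValueError):
    """Input file does not conform to the documented schema."""


class ValidationError(ValueError):
    """Input parses but violates a structural invariant."""


# ---------------------------------------------------------------------------
# Release schedule
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReleaseSchedule:
    """Calendar layout of the propagule release design.

    Releases occur every ``step`` days at offsets {0, step, 2*step, ...}
    strictly inside an ``window_length``-day window opening on
    ``window_start`` (month, day).  Tracking of each propagule continues
    through ``tracking_end`` (month, day) of the same year.
    """

    window_start: tuple[int, int] = (3, 15)  # (month, day)
    window_length: int = 80
    step: int = 2
    tracking_end: tuple[int, int] = (9, 30)

    @property
    def n_releases(self) -> int:
        """Number of release events D per site-depth-year."""
        return len(self.release_offsets())

    def release_offsets(self) -> np.ndarray:
        """Day offsets of release events from window_start (0-based)."""
        return np.arange(0, self.window_length, self.step)

    def release_date(self, release_index: int, year: int) -> _dt.date:
        """Calendar date of release event ``release_index`` (1-based)."""
        if not 1 <= release_index <= self.n_releases:
            raise ValueError(f"release_index {release_index} outside 1..{self.n_releases}")
        start = _dt.date(year, *self.window_start)
        return start + _dt.timedelta(days=int(self.release_offsets()[release_index - 1]))

    def tracking_end_date(self, year: int) -> _dt.date:
        return _dt.date(year, *self.tracking_end)

    def tracking_days(self, release_index: int, year: int) -> int:
        """Number of tracked days (inclusive of release day) for an event."""
        n = (self.tracking_end_date(year) - self.release_date(release_index, year)).days + 1
        if n <= 0:
            raise ValidationError(
                f"tracking_end precedes release {release_index} in year {year}"
            )
        return n

    def __post_init__(self) -> None:
        if self.step < 1 or self.window_length < 1:
            raise ValueError("step and window_length must be positive")
        # tracking must extend beyond the last release of any year
        probe_year = 2000
        last = self.release_date(self.n_releases, probe_year)
        if self.tracking_end_date(probe_year) <= last:
            raise ValidationError("tracking_end must be later than the last release date")


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------


@dataclass
class TrajectoryTable:
    """Per-propagule daily positions.

    ``df`` has the eight columns in :data:`TRAJECTORY_COLUMNS`; rows are
    sorted by propagule key then ``day_offset``, day offsets within each
    propagule form a contiguous run 0..S, and the full key is unique.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in TRAJECTORY_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"trajectory table missing column(s): {', '.join(missing)}")
        df = self.df.loc[:, list(TRAJECTORY_COLUMNS)].copy()
        for c in TRAJECTORY_COLUMNS[:6]:
            df[c] = df[c].astype(np.int64)
        df = df.sort_values(list(PROPAGULE_KEY) + ["day_offset"], kind="mergesort")
        df = df.reset_index(drop=True)
        self._validate_contiguity(df)
        self.df = df

    @staticmethod
    def _validate_contiguity(df: pd.DataFrame) -> None:
        key = df[list(PROPAGULE_KEY)].to_numpy()
        newgrp = np.ones(len(df), dtype=bool)
        if len(df) > 1:
            newgrp[1:] = (key[1:] != key[:-1]).any(axis=1)
        grp_id = np.cumsum(newgrp) - 1
        starts = np.flatnonzero(newgrp)
        offs = df["day_offset"].to_numpy()
        expected = np.arange(len(df)) - starts[grp_id]
        bad = offs != expected
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValidationError(
                "non-contiguous day_offsets for propagule key "
                f"{tuple(key[i])}: expected {expected[i]}, found {offs[i]}"
            )

    @property
    def n_propagules(self) -> int:
        return len(self.df.drop_duplicates(list(PROPAGULE_KEY)))

    @property
    def years(self) -> list[int]:
        return sorted(self.df["year"].unique().tolist())

    @property
    def source_ids(self) -> list[int]:
        return sorted(self.df["source_id"].unique().tolist())

    def write(self, path) -> None:
        self.df.to_csv(path, index=False)


def read_trajectories(path) -> TrajectoryTable:
    """Read a trajectory CSV; validates schema, sorts, checks contiguity."""
    df = pd.read_csv(path)
    return TrajectoryTable(df)


def write_trajectories(traj: TrajectoryTable, path) -> None:
    traj.write(path)


# ---------------------------------------------------------------------------
# Regions
# ---------------------------------------------------------------------------


@dataclass
class RegionPartition:
    """Ordered sink regions; ids 1..I consecutive, polygons simple."""

    regions: list[tuple[int, Polygon]]

    def __post_init__(self) -> None:
        ids = [rid for rid, _ in self.regions]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate region_id(s): {dup}")
        if sorted(ids) != list(range(1, len(ids) + 1)):
            raise ValidationError(f"region_ids must be consecutive 1..I, got {sorted(ids)}")
        for rid, poly in self.regions:
            if not isinstance(poly, Polygon):
                raise ValidationError(f"region {rid} geometry is not a polygon")
            if not poly.is_valid:
                raise ValidationError(f"region {rid} polygon is not simple/valid")
        self.regions = sorted(self.regions, key=lambda r: r[0])
        for (ra, pa), (rb, pb) in zip(self.regions, self.regions[1:]):
            inter = pa.intersection(pb)
            if inter.area > 1e-12:
                logger.warning("regions %d and %d overlap (area %.3g)", ra, rb, inter.area)

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def polygons(self) -> list[Polygon]:
        return [p for _, p in self.regions]

    def write(self, path) -> None:
        features = [
            {
                "type": "Feature",
                "properties": {"region_id": rid},
                "geometry": mapping(poly),
            }
            for rid, poly in self.regions
        ]
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_regions(path) -> RegionPartition:
    """Read a GeoJSON FeatureCollection of polygons with region_id props."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise FormatError("regions file must be a GeoJSON FeatureCollection")
    regions = []
    for feat in gj["features"]:
        props = feat.get("properties") or {}
        if "region_id" not in props:
            raise FormatError("polygon feature missing region_id property")
        geom = shape(feat["geometry"])
        if not isinstance(geom, Polygon):
            raise ValidationError(
                f"region {props['region_id']}: geometry type "
                f"{feat['geometry'].get('type')} is not Polygon"
            )
        regions.append((int(props["region_id"]), geom))
    return RegionPartition(regions)


def write_regions(partition: RegionPartition, path) -> None:
    partition.write(path)


# ---------------------------------------------------------------------------
# Abundance
# ---------------------------------------------------------------------------


@dataclass
class AbundanceMatrix:
    """Region-by-year response on the log(CPUE+1) scale.

    ``y`` is (I, T); ``n_obs`` counts contributing stations per cell;
    ``mask`` is True exactly where a cell has no stations (excluded from
    all fitting sums).  ``transformed`` guards against double transforms.
    """

    y: np.ndarray
    n_obs: np.ndarray
    years: list[int]
    mask: np.ndarray = field(default=None)
    transformed: bool = True

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.n_obs = np.asarray(self.n_obs, dtype=int)
        if self.mask is None:
            self.mask = self.n_obs == 0
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.y.shape != self.n_obs.shape or self.y.shape != self.mask.shape:
            raise ValidationError("y, n_obs, mask shape mismatch")
        if self.y.shape[1] != len(self.years):
            raise ValidationError("year labels do not match y columns")
        if not np.isfinite(self.y[~self.mask]).all():
            raise ValidationError("non-finite abundance in observed cells")

    @property
    def n_regions(self) -> int:
        return self.y.shape[0]

    @property
    def n_years(self) -> int:
        return self.y.shape[1]

    @property
    def observed(self) -> np.ndarray:
        """Boolean (I, T): True where the cell enters the fit."""
        return ~self.mask

    def write(self, path) -> None:
        out = pd.DataFrame(
            np.where(self.mask, np.nan, self.y),
            index=pd.Index(range(1, self.n_regions + 1), name="region_id"),
            columns=self.years,
        )
        out.to_csv(path)


def read_abundance(path) -> AbundanceMatrix:
    """Read a pre-aggregated region-by-year abundance CSV (masked cells empty)."""
    df = pd.read_csv(path, index_col=0)
    y = df.to_numpy(dtype=float)
    mask = ~np.isfinite(y)
    n_obs = (~mask).astype(int)
    years = [int(c) for c in df.columns]
    return AbundanceMatrix(y=np.where(mask, 0.0, y), n_obs=n_obs, years=years, mask=mask)


def read_stations(path) -> pd.DataFrame:
    """Read station records (year, lon, lat, cpue)."""
    df = pd.read_csv(path)
    required = ["year", "lon", "lat", "cpue"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"station table missing column(s): {', '.join(missing)}")
    return df.loc[:, required]


def aggregate_abundance(
    stations: pd.DataFrame,
    partition: RegionPartition,
    years: list[int] | None = None,
) -> AbundanceMatrix:
    """Aggregate station CPUE into a region-by-year matrix.

    Each station's CPUE is transformed to log(cpue + 1) and the cell value
    is the arithmetic mean of transformed values over stations falling in
    the region-year.  Stations outside all regions are excluded (count
    logged).  Cells with no stations are masked.
    """
    from .exposure import assign_region  # local import to avoid a cycle

    if (stations["cpue"] < 0).any():
        bad = stations.loc[stations["cpue"] < 0].iloc[0]
        raise ValidationError(f"negative cpue at year {int(bad['year'])}: {bad['cpue']}")
    if years is None:
        years = sorted(stations["year"].unique().tolist())
    year_pos = {y: t for t, y in enumerate(years)}
    I, T = partition.n_regions, len(years)
    total = np.zeros((I, T))
    n_obs = np.zeros((I, T), dtype=int)
    n_outside = 0
    for row in stations.itertuples(index=False):
        rid = assign_region(row.lon, row.lat, partition)
        if rid is None:
            n_outside += 1
            continue
        t = year_pos.get(int(row.year))
        if t is None:
            continue
        total[rid - 1, t] += np.log1p(row.cpue)
        n_obs[rid - 1, t] += 1
    if n_outside:
        logger.info("aggregate_abundance: %d station(s) outside all regions excluded", n_outside)
    with np.errstate(invalid="ignore"):
        y = np.where(n_obs > 0, total / np.maximum(n_obs, 1), 0.0)
    return AbundanceMatrix(y=y, n_obs=n_obs, years=years)


# ---------------------------------------------------------------------------
# Exposure tensor
# ---------------------------------------------------------------------------


@dataclass
class ExposureTensor:
    """Covariates G[j, d, i, t]: mean fraction of tracked time a propagule
    from source j, release event d, year t spent inside region i."""

    G: np.ndarray  # (J, D, I, T)
    years: list[int]
    coverage: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=float)
        if self.G.ndim != 4:
            raise ValidationError(f"G must be 4-dimensional, got shape {self.G.shape}")
        if self.G.shape[3] != len(self.years):
            raise ValidationError("year labels do not match G's last axis")
        if (self.G < 0).any() or (self.G > 1).any():
            raise ValidationError("G entries must lie in [0, 1]")
        sums = self.G.sum(axis=2)
        if (sums > 1 + 1e-9).any():
            raise ValidationError("sum of G over regions exceeds 1 for some (j, d, t)")

    @property
    def dims(self) -> tuple[int, int, int, int]:
        return self.G.shape

    def write(self, path) -> None:
        """Serialize in long format (j, d, i, t, g), 1-based indices."""
        J, D, I, T = self.G.shape
        j, d, i, t = np.meshgrid(
            np.arange(1, J + 1),
            np.arange(1, D + 1),
            np.arange(1, I + 1),
            np.arange(T),
            indexing="ij",
        )
        out = pd.DataFrame(
            {
                "source_id": j.ravel(),
                "release_index": d.ravel(),
                "region_id": i.ravel(),
                "year": np.asarray(self.years)[t.ravel()],
                "g": self.G.ravel(),
            }
        )
        out.to_csv(path, index=False)


def read_exposure(path) -> ExposureTensor:
    """Read the long-format exposure CSV written by :meth:`ExposureTensor.write`."""
    df = pd.read_csv(path)
    years = sorted(df["year"].unique().tolist())
    J = int(df["source_id"].max())
    D = int(df["release_index"].max())
    I = int(df["region_id"].max())
    T = len(years)
    year_pos = {y: t for t, y in enumerate(years)}
    G = np.zeros((J, D, I, T))
    G[
        df["source_id"] - 1,
        df["release_index"] - 1,
        df["region_id"] - 1,
        df["year"].map(year_pos),
    ] = df["g"]
    return ExposureTensor(G=G, years=years)
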