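"""Occurrence cleaning, thinning, zone balancing, and background sampling.

Presence records arrive as tables with columns
``lon, lat, year, uncertainty_km, source, zone``.  Cleaning applies the
standard record-quality rules (valid coordinates, recency, positional
uncertainty), thinning enforces a minimum pairwise distance so that no two
points extract the same raster pixel, area-weighted balancing caps the
per-zone point density, and background (pseudo-absence) points are sampled
at a fixed presence:background ratio outside a buffer around the presences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from zonesdm.grids import EnvStack, ZoneSet

EARTH_RADIUS_KM = 6371.0

REQUIRED_COLUMNS = ["lon", "lat", "year", "uncertainty_km", "source", "zone"]

RULE_COORDS = "coordinates"
RULE_YEAR = "year"
RULE_UNCERTAINTY = "uncertainty"


@dataclass
class OccurrenceSet:
    """Presence records plus the distance metric their coordinates use.

    ``metric`` is ``"planar"`` (coordinates in km, Euclidean distances) or
    ``"spherical"`` (lon/lat degrees, haversine distances).
    """

    records: pd.DataFrame
    metric: str = "spherical"

    def __post_init__(self) -> None:
        if self.metric not in {"planar", "spherical"}:
            raise ValueError("metric must be 'planar' or 'spherical'")
        df = pd.DataFrame(self.records).copy()
        for col in REQUIRED_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan if col not in {"source", "zone"} else ""
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def xy(self) -> np.ndarray:
        return self.records[["lon", "lat"]].to_numpy(dtype=float)


@dataclass
class BackgroundSet:
    """Pseudo-absence points sampled outside the presence buffer."""

    points: np.ndarray
    seed: int
    buffer_km: float
    ratio: int = 10

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class CleaningLog:
    """Per-rule rejection counts and the per-record reasons."""

    counts: dict[str, int] = field(default_factory=dict)
    reasons: pd.DataFrame | None = None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rule": list(self.counts), "n_rejected": list(self.counts.values())}
        )


def pairwise_distance_km(a: np.ndarray, b: np.ndarray, metric: str) -> np.ndarray:
    """All-pairs distances in km under the declared metric."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if metric == "planar":
        return cdist(a, b)
    lon1, lat1 = np.radians(a[:, 0])[:, None], np.radians(a[:, 1])[:, None]
    lon2, lat2 = np.radians(b[:, 0])[None, :], np.radians(b[:, 1])[None, :]
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


def _coords_valid(lon: pd.Series, lat: pd.Series, metric: str) -> pd.Series:
    lon = pd.to_numeric(lon, errors="coerce")
    lat = pd.to_numeric(lat, errors="coerce")
    ok = np.isfinite(lon) & np.isfinite(lat)
    if metric == "spherical":
        ok &= (lon.abs() <= 180) & (lat.abs() <= 90)
    return ok


def clean_occurrences(
    records: pd.DataFrame | OccurrenceSet,
    min_year: int = 2000,
    max_uncertainty_km: float = 50.0,
    metric: str = "spherical",
) -> tuple[OccurrenceSet, CleaningLog]:
    """Apply the record-quality rules and return survivors plus a log.

    Rules, applied in order (a record is logged under the first rule it
    fails): (1) missing or out-of-bounds coordinates; (2) year missing or
    before ``min_year`` — an unknown collection year cannot certify
    recency, so it fails the recency rule; (3) reported positional
    uncertainty above ``max_uncertainty_km`` (a missing uncertainty is
    kept: only a *reported* excess rejects).
    """
    if isinstance(records, OccurrenceSet):
        metric = records.metric
        df = records.records.copy()
    else:
        df = OccurrenceSet(pd.DataFrame(records), metric=metric).records

    coords_ok = _coords_valid(df["lon"], df["lat"], metric)
    year = pd.to_numeric(df["year"], errors="coerce")
    year_ok = year.notna() & (year >= min_year)
    unc = pd.to_numeric(df["uncertainty_km"], errors="coerce")
    unc_ok = unc.isna() | (unc <= max_uncertainty_km)

    reason = np.where(
        ~coords_ok, RULE_COORDS, np.where(~year_ok, RULE_YEAR, np.where(~unc_ok, RULE_UNCERTAINTY, ""))
    )
    keep = reason == ""
    log = CleaningLog(
        counts={
            RULE_COORDS: int((reason == RULE_COORDS).sum()),
            RULE_YEAR: int((reason == RULE_YEAR).sum()),
            RULE_UNCERTAINTY: int((reason == RULE_UNCERTAINTY).sum()),
        },
        reasons=pd.DataFrame({"index": df.index, "rule": reason})[reason != ""],
    )
    survivors = df[keep].reset_index(drop=True)
    if len(survivors) == 0 and len(df) > 0:
        warnings.warn("cleaning removed every record", stacklevel=2)
    return OccurrenceSet(records=survivors, metric=metric), log


def thin_by_distance(occ: OccurrenceSet, radius_km: float = 5.0) -> OccurrenceSet:
    """Greedy distance thinning in stable input order.

    A record is kept iff it lies at least ``radius_km`` from every record
    already kept, so all pairwise kept distances are >= ``radius_km``.
    """
    df = occ.records
    if len(df) <= 1:
        return OccurrenceSet(records=df.copy(), metric=occ.metric)
    xy = occ.xy
    kept: list[int] = []
    for i in range(len(df)):
        if not kept:
            kept.append(i)
            continue
        d = pairwise_distance_km(xy[i : i + 1], xy[kept], occ.metric)[0]
        if np.all(d >= radius_km):
            kept.append(i)
    return OccurrenceSet(records=df.iloc[kept].reset_index(drop=True), metric=occ.metric)


def assign_zone(occ: OccurrenceSet, zones: ZoneSet) -> OccurrenceSet:
    """Label each record with the zone containing it ("other" if none).

    Boundary points go to the lexicographically first matching zone.
    """
    df = occ.records.copy()
    if len(df):
        df["zone"] = zones.assign_points(df["lon"].to_numpy(float), df["lat"].to_numpy(float))
    return OccurrenceSet(records=df, metric=occ.metric)


def area_weighted_balance(occ: OccurrenceSet, zones: ZoneSet, seed: int = 0) -> OccurrenceSet:
    """Cap per-zone point density at the median zone density.

    Zones whose density (points per km² of zone area) exceeds the median
    are randomly subsampled (seeded) down to ``ceil(median_density *
    zone_area)``; zones at or below the median, and records outside every
    zone, are untouched.  Guards against some zones dominating the model
    purely because they were sampled more heavily.
    """
    df = occ.records
    zone_records = {
        zid: df.index[df["zone"] == zid].to_numpy() for zid in zones.zone_ids if (df["zone"] == zid).any()
    }
    if len(zone_records) < 2:
        warnings.warn("fewer than 2 populated zones; balancing is an identity", stacklevel=2)
        return OccurrenceSet(records=df.copy(), metric=occ.metric)

    densities = {zid: len(idx) / zones.area_km2(zid) for zid, idx in zone_records.items()}
    cap = float(np.median(list(densities.values())))

    rng = np.random.default_rng(seed)
    keep = np.ones(len(df), dtype=bool)
    for zid in sorted(zone_records):
        idx = zone_records[zid]
        target = int(np.ceil(cap * zones.area_km2(zid)))
        if len(idx) > target:
            kept = rng.choice(idx, size=target, replace=False)
            drop = np.setdiff1d(idx, kept)
            keep[drop] = False
    return OccurrenceSet(records=df[keep].reset_index(drop=True), metric=occ.metric)


def sample_background(
    presences: OccurrenceSet,
    stack: EnvStack,
    ratio: int = 10,
    buffer_km: float = 10.0,
    seed: int = 0,
) -> BackgroundSet:
    """Sample pseudo-absence cell centres outside the presence buffer.

    Draws exactly ``ratio * len(presences)`` distinct masked cell centres,
    uniformly at random (seeded), each at least ``buffer_km`` from every
    presence.  One point per cell, so no two background points extract the
    same pixel.
    """
    n_needed = ratio * len(presences)
    xg, yg = stack.cell_centers()
    centers = np.column_stack([xg[stack.mask], yg[stack.mask]])
    if len(presences):
        d = pairwise_distance_km(centers, presences.xy, presences.metric)
        eligible = centers[d.min(axis=1) >= buffer_km]
    else:
        eligible = centers
    if len(eligible) < n_needed:
        raise ValueError(
            f"only {len(eligible)} eligible background cells for {n_needed} "
            f"requested (deficit {n_needed - len(eligible)})"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(eligible), size=n_needed, replace=False)
    return BackgroundSet(points=eligible[chosen], seed=seed, buffer_km=buffer_km, ratio=ratio)
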