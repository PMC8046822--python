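"""Gridded environmental stacks, zone polygons, and suitability maps.

All grids in a run share one planar row/column geometry with square cells of
side ``cell_km`` (kilometres); cell centres are at ``(col + 0.5, row + 0.5)
* cell_km`` with the origin at the top-left corner and y increasing
downward in row index but reported as a planar "lat"-like coordinate.
Rasters are exchanged as ESRI ASCII grids (one file per layer plus a JSON
manifest), zone polygons as GeoJSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon, mapping, shape

#: Bioclimatic layer names follow the WorldClim convention: Bio1-Bio11 are
#: temperature-derived, Bio12-Bio19 precipitation-derived.
CLIMATE_LAYERS: tuple[str, ...] = tuple(f"Bio{i}" for i in range(1, 20))
TOPO_LAYERS: tuple[str, ...] = ("elevation", "slope", "aspect")
SOIL_LAYERS: tuple[str, ...] = ("pH", "CEC", "BD", "OC")
#: Precipitation-type layers are floored at zero after any additive shift.
PRECIPITATION_LAYERS: tuple[str, ...] = tuple(f"Bio{i}" for i in range(12, 20))

DEFAULT_LAYERS: tuple[str, ...] = CLIMATE_LAYERS + TOPO_LAYERS + SOIL_LAYERS


def layer_group(name: str) -> str:
    """Classify a layer as climate, topography, or soil."""
    if name in CLIMATE_LAYERS:
        return "climate"
    if name in TOPO_LAYERS:
        return "topography"
    if name in SOIL_LAYERS:
        return "soil"
    raise KeyError(f"unknown layer {name!r}")


@dataclass
class EnvStack:
    """Named environmental layers on a common planar grid.

    Parameters
    ----------
    layer_names
        Ordered, unique layer names.
    values
        ``(rows, cols, n_layers)`` float array. Values outside ``mask`` may
        be anything; inside the mask they must be finite.
    cell_km
        Side of a square cell in kilometres.
    mask
        ``(rows, cols)`` boolean; True marks cells inside the study domain.
    """

    layer_names: list[str]
    values: np.ndarray
    cell_km: float
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be (rows, cols, n_layers)")
        if len(self.layer_names) != self.values.shape[2]:
            raise ValueError("layer_names length must match values depth")
        if len(set(self.layer_names)) != len(self.layer_names):
            raise ValueError("layer names must be unique")
        if self.cell_km <= 0:
            raise ValueError("cell_km must be positive")
        if self.mask is None:
            self.mask = np.ones(self.values.shape[:2], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape[:2]:
            raise ValueError("mask shape must match grid")
        inside = self.values[self.mask]
        if inside.size and not np.all(np.isfinite(inside)):
            raise ValueError("non-finite values inside mask")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[:2]

    @property
    def cell_area_km2(self) -> float:
        return self.cell_km**2

    def index(self, name: str) -> int:
        try:
            return self.layer_names.index(name)
        except ValueError:
            raise KeyError(f"layer {name!r} not in stack") from None

    def layer(self, name: str) -> np.ndarray:
        return self.values[:, :, self.index(name)]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Planar x/y (km) of every cell centre, each shaped like the grid."""
        rows, cols = self.shape
        x = (np.arange(cols) + 0.5) * self.cell_km
        y = (np.arange(rows) + 0.5) * self.cell_km
        return np.meshgrid(x, y)

    def xy_to_rowcol(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        row = np.floor(np.asarray(y) / self.cell_km).astype(int)
        col = np.floor(np.asarray(x) / self.cell_km).astype(int)
        return row, col

    def standardize_stats(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-layer mean and standard deviation over masked cells."""
        flat = self.values[self.mask]
        mean = flat.mean(axis=0)
        sd = flat.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        return mean, sd

    def extract(self, x: np.ndarray, y: np.ndarray, layers: Sequence[str] | None = None) -> np.ndarray:
        """Sample layer values at planar points (nearest cell)."""
        row, col = self.xy_to_rowcol(x, y)
        rows, cols = self.shape
        if np.any((row < 0) | (row >= rows) | (col < 0) | (col >= cols)):
            raise ValueError("point outside grid extent")
        names = list(layers) if layers is not None else self.layer_names
        idx = [self.index(n) for n in names]
        return self.values[row, col][:, idx]

    def copy(self) -> "EnvStack":
        return replace(self, values=self.values.copy(), mask=self.mask.copy(),
                       layer_names=list(self.layer_names))


@dataclass
class ZoneSet:
    """Non-overlapping zone polygons inside a study domain."""

    zones: list[tuple[str, Polygon]]
    domain: Polygon

    def __post_init__(self) -> None:
        ids = [z for z, _ in self.zones]
        if len(set(ids)) != len(ids):
            raise ValueError("zone ids must be unique")

    @property
    def zone_ids(self) -> list[str]:
        return [z for z, _ in self.zones]

    def polygon(self, zone_id: str) -> Polygon:
        for zid, poly in self.zones:
            if zid == zone_id:
                return poly
        raise KeyError(f"no zone {zone_id!r}")

    def area_km2(self, zone_id: str) -> float:
        # planar polygons drawn in km coordinates
        return float(self.polygon(zone_id).area)

    def zone_mask(self, stack: EnvStack, zone_id: str) -> np.ndarray:
        """Boolean grid of cells whose centre falls in the zone."""
        xg, yg = stack.cell_centers()
        poly = self.polygon(zone_id)
        inside = shapely.contains_xy(poly, xg.ravel(), yg.ravel())
        return inside.reshape(stack.shape)

    def assign_points(self, x: np.ndarray, y: np.ndarray) -> list[str]:
        """Zone id per point; boundary points go to the lexicographically
        first covering zone; points outside every zone get ``"other"``."""
        labels = ["other"] * len(np.atleast_1d(x))
        order = sorted(range(len(self.zones)), key=lambda i: self.zones[i][0])
        xa, ya = np.atleast_1d(x), np.atleast_1d(y)
        undecided = np.ones(len(xa), dtype=bool)
        for i in order:
            zid, poly = self.zones[i]
            hit = shapely.intersects_xy(poly, xa, ya) & undecided
            for j in np.flatnonzero(hit):
                labels[j] = zid
            undecided &= ~hit
        return labels


@dataclass
class SuitabilityMap:
    """Continuous (and optionally binary) suitability on the stack grid."""

    continuous: np.ndarray
    cell_km: float
    mask: np.ndarray
    binary: np.ndarray | None = None
    threshold: float | None = None
    scope: str = "combined"
    scenario: str | None = None

    @property
    def cell_area_km2(self) -> float:
        return self.cell_km**2

    def with_threshold(self, threshold: float) -> "SuitabilityMap":
        binary = np.zeros(self.continuous.shape, dtype=bool)
        binary[self.mask] = self.continuous[self.mask] >= threshold
        return SuitabilityMap(
            continuous=self.continuous,
            cell_km=self.cell_km,
            mask=self.mask,
            binary=binary,
            threshold=threshold,
            scope=self.scope,
            scenario=self.scenario,
        )


# ---------------------------------------------------------------------------
# I/O: ESRI ASCII grids + JSON manifest for stacks, GeoJSON for zones.

def write_ascii_grid(path: Path | str, grid: np.ndarray, cell_km: float,
                     nodata: float = -9999.0) -> None:
    grid = np.asarray(grid, dtype=float)
    out = np.where(np.isfinite(grid), grid, nodata)
    header = (
        f"ncols {grid.shape[1]}\n"
        f"nrows {grid.shape[0]}\n"
        "xllcorner 0.0\n"
        "yllcorner 0.0\n"
        f"cellsize {cell_km}\n"
        f"NODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.8g")


def read_ascii_grid(path: Path | str) -> tuple[np.ndarray, float, float]:
    """Return (grid with NaN at nodata, cell size, nodata value)."""
    meta: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            meta[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    grid = np.loadtxt(lines[n_header:], dtype=float, ndmin=2)
    nodata = meta.get("nodata_value", -9999.0)
    grid = np.where(grid == nodata, np.nan, grid)
    return grid, meta["cellsize"], nodata


def write_stack(stack: EnvStack, directory: Path | str) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in stack.layer_names:
        layer = stack.layer(name).copy()
        layer[~stack.mask] = np.nan
        write_ascii_grid(directory / f"{name}.asc", layer, stack.cell_km)
    write_ascii_grid(directory / "mask.asc", stack.mask.astype(float), stack.cell_km)
    manifest = {
        "layer_names": stack.layer_names,
        "cell_km": stack.cell_km,
        "rows": stack.shape[0],
        "cols": stack.shape[1],
    }
    (directory / "stack.json").write_text(json.dumps(manifest, indent=2))
    return directory


def read_stack(directory: Path | str) -> EnvStack:
    directory = Path(directory)
    manifest = json.loads((directory / "stack.json").read_text())
    mask_grid, cell_km, _ = read_ascii_grid(directory / "mask.asc")
    mask = mask_grid > 0.5
    layers = []
    for name in manifest["layer_names"]:
        grid, _, _ = read_ascii_grid(directory / f"{name}.asc")
        grid = np.where(mask, grid, 0.0)
        layers.append(grid)
    values = np.stack(layers, axis=2)
    return EnvStack(layer_names=list(manifest["layer_names"]), values=values,
                    cell_km=float(manifest["cell_km"]), mask=mask)


def write_zones(zones: ZoneSet, path: Path | str) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"zone_id": zid},
            "geometry": mapping(poly),
        }
        for zid, poly in zones.zones
    ]
    features.append(
        {
            "type": "Feature",
            "properties": {"zone_id": "__domain__"},
            "geometry": mapping(zones.domain),
        }
    )
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))


def read_zones(path: Path | str) -> ZoneSet:
    data = json.loads(Path(path).read_text())
    zones: list[tuple[str, Polygon]] = []
    domain: Polygon | None = None
    for feat in data["features"]:
        zid = feat["properties"]["zone_id"]
        geom = shape(feat["geometry"])
        if zid == "__domain__":
            domain = geom
        else:
            zones.append((zid, geom))
    if domain is None:
        domain = shapely.union_all([p for _, p in zones]).convex_hull
    return ZoneSet(zones=zones, domain=domain)


def write_map(smap: SuitabilityMap, directory: Path | str, stem: str) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cont = smap.continuous.copy()
    cont[~smap.mask] = np.nan
    write_ascii_grid(directory / f"{stem}_continuous.asc", cont, smap.cell_km)
    if smap.binary is not None:
        binary = smap.binary.astype(float)
        binary[~smap.mask] = np.nan
        write_ascii_grid(directory / f"{stem}_binary.asc", binary, smap.cell_km)
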