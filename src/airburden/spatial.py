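"""County-to-grid apportionment by area overlap.

County-level demographics and baseline rates live on administrative
polygons; exposure lives on the model grid. The bridge is the sparse
area-overlap weight matrix: for each county, the fraction of its area
falling in each grid cell. County counts are pushed onto the grid with
these fractions, county rates are attached unchanged to every overlapping
(county, cell) pair, and gridded results are summed back up to county,
state and national totals.

Areas are computed in lon/lat degrees with a cos(latitude) correction at
each intersection's centroid — adequate at county scale, and the
fine-rasterization oracle in the test suite quantifies the error.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, box, mapping, shape
from shapely.strtree import STRtree

from .containers import PopulationGrid
from .grids import EARTH_RADIUS_KM, GridDefinition
from .rates import RateTable

KM_PER_DEGREE = 2 * np.pi * EARTH_RADIUS_KM / 360.0


@dataclass
class County:
    county_id: str
    state_id: str
    polygon: Polygon

    def area_km2(self) -> float:
        return _polygon_area_km2(self.polygon)


def _polygon_area_km2(poly: Polygon) -> float:
    lat = poly.centroid.y
    return poly.area * KM_PER_DEGREE**2 * np.cos(np.deg2rad(lat))


@dataclass
class CountyMap:
    """A set of simple county polygons, each belonging to one state."""

    counties: list[County]

    def __post_init__(self) -> None:
        ids = [c.county_id for c in self.counties]
        if len(set(ids)) != len(ids):
            raise ValueError("county ids must be unique")
        for c in self.counties:
            if not c.polygon.is_valid:
                raise ValueError(f"county {c.county_id} has an invalid polygon")

    def __len__(self) -> int:
        return len(self.counties)

    @property
    def state_of(self) -> dict[str, str]:
        return {c.county_id: c.state_id for c in self.counties}

    def total_area_km2(self) -> float:
        return sum(c.area_km2() for c in self.counties)

    def to_geojson(self, path) -> None:
        features = [
            {
                "type": "Feature",
                "properties": {"county_id": c.county_id, "state_id": c.state_id},
                "geometry": mapping(c.polygon),
            }
            for c in self.counties
        ]
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)

    @classmethod
    def from_geojson(cls, path) -> "CountyMap":
        with open(path) as fh:
            gj = json.load(fh)
        counties = [
            County(
                county_id=f["properties"]["county_id"],
                state_id=f["properties"]["state_id"],
                polygon=shape(f["geometry"]),
            )
            for f in gj["features"]
        ]
        return cls(counties)


@dataclass
class OverlapWeights:
    """Sparse (county, cell) area-overlap fractions.

    ``fraction`` is the share of the county's in-domain area in the cell
    (sums to 1 per county); ``cell_share`` is the county's share of the
    county-covered area within the cell (sums to 1 per covered cell) and
    is used to split gridded population among counties sharing a cell.
    """

    table: pd.DataFrame  # columns: county_id, state_id, row, col, area_km2, fraction, cell_share
    grid: GridDefinition
    uncovered: list[str]  # counties with no overlap with the grid domain

    def for_county(self, county_id: str) -> pd.DataFrame:
        return self.table[self.table["county_id"] == county_id]

    def to_csv(self, path) -> None:
        out = self.table[["county_id", "row", "col", "fraction"]]
        out.to_csv(path, index=False)


def intersect_counties(grid: GridDefinition, counties: CountyMap) -> OverlapWeights:
    """Compute sparse area-overlap weights between counties and grid cells.

    Counties partially outside the grid are renormalized over their
    in-domain portion; counties entirely outside are recorded with zero
    coverage and a warning.
    """
    cells = []
    idx = []
    for i in range(grid.nlat):
        for j in range(grid.nlon):
            cells.append(
                box(grid.lon_edges[j], grid.lat_edges[i], grid.lon_edges[j + 1], grid.lat_edges[i + 1])
            )
            idx.append((i, j))
    tree = STRtree(cells)

    rows: list[dict] = []
    uncovered: list[str] = []
    for county in counties.counties:
        hits = tree.query(county.polygon)
        areas = []
        for k in hits:
            inter = county.polygon.intersection(cells[int(k)])
            if inter.is_empty or inter.area == 0:
                continue
            areas.append((idx[int(k)], _polygon_area_km2(inter)))
        total = sum(a for _, a in areas)
        if total == 0:
            warnings.warn(f"county {county.county_id} lies entirely outside the grid")
            uncovered.append(county.county_id)
            continue
        for (i, j), a in areas:
            rows.append(
                {
                    "county_id": county.county_id,
                    "state_id": county.state_id,
                    "row": i,
                    "col": j,
                    "area_km2": a,
                    "fraction": a / total,
                }
            )
    if not rows:
        raise ValueError("no county overlaps the grid domain")
    table = pd.DataFrame(rows)
    cell_total = table.groupby(["row", "col"])["area_km2"].transform("sum")
    table["cell_share"] = table["area_km2"] / cell_total
    return OverlapWeights(table=table, grid=grid, uncovered=uncovered)


def apportion_population(
    pop_by_county: pd.DataFrame,
    weights: OverlapWeights,
    age_bins: list[tuple[float, float]],
    subgroups: list[str],
    births_by_county: pd.DataFrame | None = None,
) -> PopulationGrid:
    """Push county person counts onto the grid by area-overlap fractions.

    ``pop_by_county`` needs columns (county_id, subgroup, age_lo, age_hi,
    count); ``births_by_county`` (county_id, subgroup, births). National
    totals are conserved exactly (the weights are a partition per county).
    """
    known = set(weights.table["county_id"]) | set(weights.uncovered)
    unknown = set(pop_by_county["county_id"]) - known
    if unknown:
        raise ValueError(f"county ids not present in the overlap weights: {sorted(unknown)}")

    grid = weights.grid
    bin_index = {tuple(b): k for k, b in enumerate(age_bins)}
    sub_index = {s: k for k, s in enumerate(subgroups)}
    counts = np.zeros((len(subgroups), len(age_bins)) + grid.shape)
    births = np.zeros((len(subgroups),) + grid.shape)

    w = weights.table.set_index("county_id")
    for (county, subgroup, lo, hi), chunk in pop_by_county.groupby(
        ["county_id", "subgroup", "age_lo", "age_hi"]
    ):
        if county in weights.uncovered:
            continue
        b = bin_index[(lo, hi)]
        s = sub_index[subgroup]
        total = chunk["count"].sum()
        cw = w.loc[[county]]
        counts[s, b, cw["row"].to_numpy(), cw["col"].to_numpy()] += (
            total * cw["fraction"].to_numpy()
        )
    if births_by_county is not None:
        for (county, subgroup), chunk in births_by_county.groupby(["county_id", "subgroup"]):
            if county in weights.uncovered:
                continue
            s = sub_index[subgroup]
            cw = w.loc[[county]]
            births[s, cw["row"].to_numpy(), cw["col"].to_numpy()] += (
                chunk["births"].sum() * cw["fraction"].to_numpy()
            )
    return PopulationGrid(grid=grid, age_bins=age_bins, subgroups=subgroups, counts=counts, births=births)


def attach_rates(
    rates: RateTable,
    weights: OverlapWeights,
    cause: str,
    subgroup: str = "total",
    age_group: str = "all",
) -> pd.DataFrame:
    """Attach each county's baseline rate to its (county, cell) overlap pairs.

    Rates must be fully gap-filled first. Each pair carries its county's
    rate unchanged — downstream burden math operates on these pairs, never
    on a blended per-cell rate, so two counties sharing a cell keep their
    distinct rates.
    """
    sel = rates.select(level="county", cause=cause, subgroup=subgroup, age_group=age_group)
    if sel["suppressed"].any():
        raise ValueError("rate table still contains suppressed entries; run gap filling first")
    rate_of = sel.set_index("region_id")["rate"]
    pairs = weights.table.copy()
    missing = set(pairs["county_id"]) - set(rate_of.index)
    if missing:
        raise ValueError(f"no {cause!r} rate for counties {sorted(missing)[:5]}")
    pairs["rate"] = pairs["county_id"].map(rate_of)
    pairs["cause"] = cause
    pairs["subgroup"] = subgroup
    return pairs


def aggregate(pairs: pd.DataFrame, level: str, value_cols: list[str] | None = None) -> pd.DataFrame:
    """Sum per-(county, cell) values up to county, state, or national level."""
    if value_cols is None:
        value_cols = [c for c in ("central", "lower", "upper") if c in pairs.columns]
    if level == "county":
        out = pairs.groupby(["state_id", "county_id"], as_index=False)[value_cols].sum()
    elif level == "state":
        out = pairs.groupby("state_id", as_index=False)[value_cols].sum()
    elif level == "national":
        out = pairs[value_cols].sum().to_frame().T
        out.insert(0, "region", "US")
    else:
        raise ValueError(f"unknown aggregation level {level!r}")
    return out
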