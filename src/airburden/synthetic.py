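"""Seeded synthetic inputs with the statistical structure the analysis assumes.

Real inputs to this kind of assessment — chemical-transport model
concentration fields, gridded demographics, county shapefiles, baseline
rate tables with small-count suppression, and monitor networks — are
large and access-restricted. This module generates seeded stand-ins with
the same structure so every downstream stage is testable end to end:

* concentration scenarios as background + per-stage Gaussian-plume
  hotspots + noise, with the zero-out sensitivity fields and the true
  per-stage contributions stored alongside for oracle checks;
* populations allocated by multinomial draw over a smooth density
  surface, with per-subgroup density tilts so exposure disparities exist
  by construction;
* axis-aligned rectangular counties jittered off the cell edges so
  area-overlap weighting is genuinely fractional;
* Poisson event counts driving the sub-threshold suppression mechanism
  of county rate tables;
* per-site daily observation series with configurable missingness.

Every generator is a pure function of its arguments and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import box

from .containers import POLLUTANT_UNITS, ConcentrationField, PopulationGrid, ScenarioSet
from .evaluation import ObservationSet
from .grids import GridDefinition
from .rates import COLUMNS as RATE_COLUMNS
from .rates import RateTable
from .spatial import County, CountyMap

#: Default lifecycle stages, mirroring a fuel-lifecycle zero-out design.
DEFAULT_STAGES = ("upstream_midstream", "downstream", "end_use")

#: Roughly realistic ambient background levels per pollutant (units as in
#: POLLUTANT_UNITS). The ozone background sits above its 32.4 ppb risk
#: threshold and PM2.5/NO2 above theirs, so burdens are non-degenerate.
DEFAULT_BACKGROUND = {
    "PM2.5": 6.0,
    "NO2": 4.0,
    "MDA8_O3": 40.0,
    "formaldehyde": 1.5,
    "acetaldehyde": 1.0,
    "benzene": 0.3,
}

DEFAULT_AGE_BINS: list[tuple[float, float]] = [(0.0, 1.0), (1.0, 5.0)] + [
    (float(a), float(a + 5)) for a in range(5, 85, 5)
] + [(85.0, 100.0)]

#: Census-style subgroup shares of the national population ("total" first;
#: the shares leave a ~3% multiracial remainder unassigned to any subgroup).
DEFAULT_SUBGROUP_SHARES = {
    "hispanic": 0.18,
    "asian": 0.06,
    "black": 0.12,
    "native_american": 0.013,
    "white": 0.60,
}

#: Approximate US age-bin population weights (uniform-ish with decline at
#: old age); normalized at use.
_AGE_WEIGHTS = np.array(
    [1.2, 4.8] + [6.3, 6.5, 6.6, 6.6, 6.8, 6.9, 6.5, 6.3, 6.4, 6.6, 6.4, 5.8, 4.9, 3.8, 2.8, 1.9, 2.0]
)


@dataclass(frozen=True)
class SyntheticScenarioSpec:
    """Knobs of the scenario generator.

    ``hotspots_per_stage`` maps stage name to hotspot count (an int applies
    to every stage); amplitudes are drawn uniformly from
    ``amplitude_range`` (concentration units) and scaled per pollutant by
    the ratio of its background to the PM2.5 background, so each
    pollutant's enhancements are commensurate with its ambient level.
    """

    hotspots_per_stage: int | dict[str, int] = 3
    amplitude_range: tuple[float, float] = (0.5, 4.0)
    plume_length_scale: float = 2.0  # in cells
    background: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BACKGROUND))
    noise_scale: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.amplitude_range
        if lo < 0 or hi < lo:
            raise ValueError("amplitude range must be non-negative and ordered")
        if any(v < 0 for v in self.background.values()):
            raise ValueError("background levels must be non-negative")
        if self.noise_scale < 0:
            raise ValueError("noise scale must be non-negative")
        if self.plume_length_scale <= 0:
            raise ValueError("plume length scale must be positive")

    def n_hotspots(self, stage: str) -> int:
        if isinstance(self.hotspots_per_stage, dict):
            return self.hotspots_per_stage[stage]
        return self.hotspots_per_stage


def generate_grid(
    nlat: int,
    nlon: int,
    origin: tuple[float, float] = (25.0, -110.0),
    resolution: tuple[float, float] = (0.25, 0.3125),
) -> GridDefinition:
    """A regular grid like a nested regional simulation's (default 0.25 x 0.3125 deg)."""
    return GridDefinition.regular(nlat, nlon, origin, resolution)


def _plume(grid: GridDefinition, i0: float, j0: float, amp: float, scale: float) -> np.ndarray:
    ii, jj = np.mgrid[0 : grid.nlat, 0 : grid.nlon]
    d2 = (ii - i0) ** 2 + (jj - j0) ** 2
    return amp * np.exp(-d2 / (2.0 * scale**2))


def generate_scenarios(
    grid: GridDefinition,
    spec: SyntheticScenarioSpec,
    pollutants: list[str] | None = None,
    stages: list[str] | None = None,
) -> ScenarioSet:
    """Baseline plus zero-out sensitivity fields with known true contributions.

    baseline = max(0, background + noise) + sum of stage contributions;
    each stage's sensitivity field removes exactly that stage's
    contribution, so ``baseline - sensitivity == contribution`` holds to
    the last bit (the zero floor is applied before the non-negative
    contributions are added).
    """
    pollutants = list(pollutants or POLLUTANT_UNITS)
    stages = list(stages or DEFAULT_STAGES)
    if not stages:
        raise ValueError("stages must be non-empty")
    unknown = set(pollutants) - set(POLLUTANT_UNITS)
    if unknown:
        raise ValueError(f"unknown pollutants {sorted(unknown)}")

    rng = np.random.default_rng(spec.seed)
    ref = spec.background.get("PM2.5", 1.0) or 1.0
    contributions: dict[str, dict[str, np.ndarray]] = {}
    for stage in stages:
        per_pollutant = {p: np.zeros(grid.shape) for p in pollutants}
        for _ in range(spec.n_hotspots(stage)):
            i0 = rng.uniform(0, grid.nlat)
            j0 = rng.uniform(0, grid.nlon)
            for p in pollutants:
                rel = (spec.background.get(p, ref) or ref) / ref
                amp = rng.uniform(*spec.amplitude_range) * rel
                per_pollutant[p] += _plume(grid, i0, j0, amp, spec.plume_length_scale)
        contributions[stage] = per_pollutant

    def make_field(pollutant: str, values: np.ndarray) -> ConcentrationField:
        metric = "peak_season_mda8" if pollutant == "MDA8_O3" else "annual_mean"
        return ConcentrationField(pollutant, values, grid, metric=metric)

    baseline: dict[str, ConcentrationField] = {}
    floor_fields: dict[str, np.ndarray] = {}
    for p in pollutants:
        noise = rng.normal(0.0, spec.noise_scale, grid.shape) if spec.noise_scale else 0.0
        floor_fields[p] = np.maximum(0.0, spec.background.get(p, 0.0) + noise)
        total = floor_fields[p] + sum(contributions[s][p] for s in stages)
        baseline[p] = make_field(p, total)

    sensitivities = {
        stage: {
            p: make_field(p, baseline[p].values - contributions[stage][p]) for p in pollutants
        }
        for stage in stages
    }
    # store the truth as the realized baseline - sensitivity difference so the
    # zero-out bookkeeping identity holds to the last bit (the analytic plume
    # differs from it only by one float rounding)
    stored = {
        stage: {
            p: baseline[p].values - sensitivities[stage][p].values for p in pollutants
        }
        for stage in stages
    }
    return ScenarioSet(
        grid=grid, baseline=baseline, sensitivities=sensitivities, contributions=stored
    )


def _density_surface(grid: GridDefinition, rng: np.random.Generator, n_blobs: int = 4) -> np.ndarray:
    dens = np.full(grid.shape, 0.05)
    for _ in range(n_blobs):
        i0 = rng.uniform(0, grid.nlat)
        j0 = rng.uniform(0, grid.nlon)
        scale = rng.uniform(1.0, max(2.0, 0.25 * max(grid.shape)))
        dens += _plume(grid, i0, j0, rng.uniform(0.5, 2.0), scale)
    return dens / dens.sum()


def generate_population(
    grid: GridDefinition,
    age_bins: list[tuple[float, float]] | None = None,
    subgroups: list[str] | None = None,
    total: float = 1_000_000,
    subgroup_shares: dict[str, float] | None = None,
    fertility_rate: float = 0.06,
    seed: int = 0,
) -> PopulationGrid:
    """Multinomially allocated cell x age x subgroup counts plus births.

    Each subgroup gets its own smooth density surface (a tilted version of
    the shared base surface), so subgroups are spatially segregated to a
    realistic degree and exposure disparities are non-trivial. Births are
    a women-of-childbearing-age proxy: half the 15-50 population times a
    configurable annual fertility rate.
    """
    if total < 0:
        raise ValueError("total population must be non-negative")
    age_bins = list(age_bins or DEFAULT_AGE_BINS)
    shares = dict(subgroup_shares or DEFAULT_SUBGROUP_SHARES)
    if subgroups is None:
        subgroups = ["total", *shares]
    if subgroups[0] != "total":
        subgroups = ["total", *subgroups]
    named = [s for s in subgroups if s != "total"]
    if sum(shares.get(s, 0.0) for s in named) > 1.0 + 1e-9:
        raise ValueError("subgroup shares exceed 1")

    rng = np.random.default_rng(seed)
    base_density = _density_surface(grid, rng)
    age_w = _AGE_WEIGHTS[: len(age_bins)].astype(float)
    age_w /= age_w.sum()

    counts = np.zeros((len(subgroups), len(age_bins)) + grid.shape)
    ncell = grid.nlat * grid.nlon
    remainder_share = 1.0 - sum(shares.get(s, 0.0) for s in named)
    layers = [(s, shares.get(s, 0.0)) for s in named] + [("_multiracial", remainder_share)]
    for name, share in layers:
        n = int(round(total * share))
        if n == 0:
            continue
        tilt = _density_surface(grid, rng)
        dens = base_density * (0.4 + 0.6 * tilt / tilt.max())
        dens = (dens / dens.sum()).ravel()
        cell_draw = rng.multinomial(n, dens)  # conserves n exactly
        for c in np.nonzero(cell_draw)[0]:
            per_age = rng.multinomial(cell_draw[c], age_w)
            i, j = divmod(c, grid.nlon)
            if name != "_multiracial":
                counts[subgroups.index(name), :, i, j] += per_age
            counts[0, :, i, j] += per_age  # total includes the remainder

    # births: 0.5 * persons aged 15-50 * fertility rate, per subgroup
    births = np.zeros((len(subgroups),) + grid.shape)
    for k in range(len(subgroups)):
        women = np.zeros(grid.shape)
        for b, (lo, hi) in enumerate(age_bins):
            overlap = max(0.0, min(hi, 50.0) - max(lo, 15.0))
            if overlap > 0:
                women += counts[k, b] * (overlap / (hi - lo)) * 0.5
        births[k] = women * fertility_rate
    return PopulationGrid(
        grid=grid, age_bins=age_bins, subgroups=list(subgroups), counts=counts, births=births
    )


def generate_counties(
    grid: GridDefinition,
    n_lat_cuts: int,
    n_lon_cuts: int,
    seed: int = 0,
) -> CountyMap:
    """Rectangular counties tiling the domain, jittered off the cell edges.

    Interior cut positions get a random jitter of up to half a cell so
    county boundaries deliberately misalign with cell edges and the
    area-overlap weights are genuinely fractional. Each row of counties
    belongs to one synthetic state.
    """
    if n_lat_cuts < 1 or n_lon_cuts < 1:
        raise ValueError("county cuts must be at least 1x1")
    rng = np.random.default_rng(seed)

    def cuts(edges: np.ndarray, n: int) -> np.ndarray:
        pos = np.linspace(edges[0], edges[-1], n + 1)
        if n > 1:
            half_cell = 0.5 * float(np.min(np.diff(edges)))
            jitter_room = 0.45 * float(np.min(np.diff(pos)))
            jit = rng.uniform(-1, 1, n - 1) * min(half_cell, jitter_room)
            pos[1:-1] += jit
        return pos

    lat_cuts = cuts(grid.lat_edges, n_lat_cuts)
    lon_cuts = cuts(grid.lon_edges, n_lon_cuts)
    counties = []
    for a in range(n_lat_cuts):
        for b in range(n_lon_cuts):
            poly = box(lon_cuts[b], lat_cuts[a], lon_cuts[b + 1], lat_cuts[a + 1])
            counties.append(
                County(county_id=f"C{a:02d}{b:02d}", state_id=f"S{a:02d}", polygon=poly)
            )
    return CountyMap(counties)


#: Baseline rates per 100,000 per year, loosely calibrated to US vital
#: statistics: non-accidental mortality ~700, COPD mortality ~40, preterm
#: births ~10,000 per 100k births, pediatric asthma onset ~190 per 100k.
DEFAULT_CAUSE_RATES = {
    "non_accidental_mortality": 700.0,
    "copd_mortality": 40.0,
    "preterm_birth": 10_000.0,
    "asthma_incidence": 190.0,
}

#: Mild subgroup rate multipliers (realistic direction, modest size).
DEFAULT_SUBGROUP_RATE_FACTORS = {
    "total": 1.0,
    "hispanic": 0.8,
    "asian": 0.7,
    "black": 1.2,
    "native_american": 1.25,
    "white": 1.0,
}


def generate_rate_table(
    counties: CountyMap,
    causes: list[str] | None = None,
    subgroups: list[str] | None = None,
    suppression_threshold: int = 10,
    seed: int = 0,
    county_population: dict[str, float] | None = None,
    cause_rates: dict[str, float] | None = None,
    age_groups: tuple[str, ...] = ("all", "age_standardized"),
) -> RateTable:
    """County/state/national baseline rates with small-count suppression.

    A county x cause x subgroup entry draws its annual event count as
    Poisson(rate x subgroup population); entries with fewer events than
    ``suppression_threshold`` are flagged suppressed with no rate, the
    mechanism public mortality databases use. State and national rates
    (population-weighted means of the county truths) are always present.
    """
    if suppression_threshold < 0:
        raise ValueError("suppression threshold must be non-negative")
    cause_rates = dict(cause_rates or DEFAULT_CAUSE_RATES)
    if causes is None:
        causes = list(cause_rates)
    if not causes:
        raise ValueError("cause list must be non-empty")
    causes = list(causes)
    subgroups = list(subgroups or DEFAULT_SUBGROUP_RATE_FACTORS)
    if "total" not in subgroups:
        subgroups = ["total", *subgroups]

    rng = np.random.default_rng(seed)
    if county_population is None:
        county_population = {
            c.county_id: float(np.round(rng.lognormal(10.0, 1.0)))  # median ~22k persons
            for c in counties.counties
        }
    shares = {
        s: DEFAULT_SUBGROUP_SHARES.get(s, 0.05) if s != "total" else 1.0 for s in subgroups
    }
    state_of = counties.state_of

    rows: list[dict] = []
    for cause in causes:
        base = cause_rates.get(cause, 100.0)
        for age_group in age_groups:
            # age standardization shifts rates modestly; one shared factor
            ag_factor = 1.0 if age_group == "all" else 0.92
            acc: dict[tuple[str, str], list[tuple[float, float]]] = {}
            for county in counties.counties:
                pop = county_population[county.county_id]
                county_factor = rng.lognormal(0.0, 0.15)
                for sub in subgroups:
                    rate = base * ag_factor * DEFAULT_SUBGROUP_RATE_FACTORS.get(sub, 1.0)
                    rate *= county_factor
                    sub_pop = pop * shares[sub]
                    events = rng.poisson(rate / 1e5 * sub_pop)
                    suppressed = events < suppression_threshold
                    rows.append(
                        {
                            "level": "county",
                            "region_id": county.county_id,
                            "state_id": state_of[county.county_id],
                            "cause": cause,
                            "age_group": age_group,
                            "subgroup": sub,
                            "rate": np.nan if suppressed else rate,
                            "suppressed": suppressed,
                            "provenance": "county",
                        }
                    )
                    acc.setdefault((state_of[county.county_id], sub), []).append((rate, sub_pop))
                    acc.setdefault(("US", sub), []).append((rate, sub_pop))
            for (region, sub), pairs in sorted(acc.items()):
                w = np.array([p for _, p in pairs])
                r = np.array([r for r, _ in pairs])
                mean_rate = float((r * w).sum() / w.sum()) if w.sum() > 0 else float(r.mean())
                level = "national" if region == "US" else "state"
                rows.append(
                    {
                        "level": level,
                        "region_id": region,
                        "state_id": "US" if region == "US" else region,
                        "cause": cause,
                        "age_group": age_group,
                        "subgroup": sub,
                        "rate": mean_rate,
                        "suppressed": False,
                        "provenance": level,
                    }
                )
    return RateTable(pd.DataFrame(rows, columns=RATE_COLUMNS))


def generate_observation_series(
    conc: ConcentrationField,
    n_sites: int,
    missingness: float = 0.0,
    noise: float = 0.0,
    seed: int = 0,
    year: int = 2017,
    months: list[int] | None = None,
) -> ObservationSet:
    """Per-site daily series whose truth is the model value at the site cell.

    Records are dropped independently with probability ``missingness``;
    per-month completeness is recorded so the coverage filter can be
    exercised against a known truth.
    """
    if not (0 <= missingness < 1):
        raise ValueError("missingness must be in [0, 1)")
    grid = conc.grid
    ncell = grid.nlat * grid.nlon
    if n_sites > ncell:
        raise ValueError("more sites requested than grid cells")
    months = list(months or range(1, 13))
    rng = np.random.default_rng(seed)
    flat = rng.choice(ncell, size=n_sites, replace=False)

    records = []
    completeness = []
    dates = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
    dates = dates[dates.month.isin(months)]
    for s, cell in enumerate(np.sort(flat)):
        i, j = divmod(int(cell), grid.nlon)
        truth = conc.values[i, j]
        present = rng.random(len(dates)) >= missingness
        vals = np.full(len(dates), truth)
        if noise:
            vals = vals + rng.normal(0.0, noise, len(dates))
        for month in months:
            in_month = dates.month == month
            n_days = int(in_month.sum())
            completeness.append(
                {
                    "site_id": f"site{s:03d}",
                    "month": month,
                    "fraction": float(present[in_month].sum()) / n_days,
                }
            )
        for d, keep, v in zip(dates, present, vals):
            if keep:
                records.append(
                    {"site_id": f"site{s:03d}", "row": i, "col": j, "date": d, "value": float(v)}
                )
    rec = pd.DataFrame(records, columns=["site_id", "row", "col", "date", "value"])
    comp = pd.DataFrame(completeness, columns=["site_id", "month", "fraction"])
    return ObservationSet(records=rec, completeness=comp)


# ---------------------------------------------------------------------------
# Writers/readers (NetCDF for fields, CSV for populations)


def scenarios_to_netcdf(scen: ScenarioSet, path) -> None:
    """Write a scenario set to one NetCDF file (CF-style lat/lon coords)."""
    import xarray as xr

    coords = {
        "lat": ("lat", scen.grid.lat_centers, {"units": "degrees_north"}),
        "lon": ("lon", scen.grid.lon_centers, {"units": "degrees_east"}),
        "lat_edges": ("lat_edge", scen.grid.lat_edges),
        "lon_edges": ("lon_edge", scen.grid.lon_edges),
    }
    data = {}
    for p, f in scen.baseline.items():
        data[f"baseline__{p}"] = (("lat", "lon"), f.values, {"units": f.units})
    for stage, fields in scen.sensitivities.items():
        for p, f in fields.items():
            data[f"sensitivity__{stage}__{p}"] = (("lat", "lon"), f.values, {"units": f.units})
    for stage, fields in scen.contributions.items():
        for p, v in fields.items():
            data[f"contribution__{stage}__{p}"] = (("lat", "lon"), v)
    xr.Dataset(data, coords=coords).to_netcdf(path, engine="scipy")


def scenarios_from_netcdf(path) -> ScenarioSet:
    import xarray as xr

    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    grid = GridDefinition(ds["lat_edges"].values, ds["lon_edges"].values)

    def make_field(p: str, vals: np.ndarray) -> ConcentrationField:
        metric = "peak_season_mda8" if p == "MDA8_O3" else "annual_mean"
        return ConcentrationField(p, vals, grid, metric=metric)

    baseline: dict[str, ConcentrationField] = {}
    sens: dict[str, dict[str, ConcentrationField]] = {}
    contrib: dict[str, dict[str, np.ndarray]] = {}
    for name in ds.data_vars:
        parts = str(name).split("__")
        if parts[0] == "baseline":
            baseline[parts[1]] = make_field(parts[1], ds[name].values)
        elif parts[0] == "sensitivity":
            sens.setdefault(parts[1], {})[parts[2]] = make_field(parts[2], ds[name].values)
        elif parts[0] == "contribution":
            contrib.setdefault(parts[1], {})[parts[2]] = ds[name].values
    return ScenarioSet(grid=grid, baseline=baseline, sensitivities=sens, contributions=contrib)


def population_to_csv(pop: PopulationGrid, path) -> None:
    """Long-format CSV (kind, subgroup, age_lo, age_hi, row, col, value).

    Integer person counts round-trip bit-exactly through
    :func:`population_from_csv`.
    """
    rows = []
    for k, sub in enumerate(pop.subgroups):
        for b, (lo, hi) in enumerate(pop.age_bins):
            ii, jj = np.nonzero(pop.counts[k, b])
            for i, j in zip(ii, jj):
                rows.append(("count", sub, lo, hi, int(i), int(j), repr(float(pop.counts[k, b, i, j]))))
        ii, jj = np.nonzero(pop.births[k])
        for i, j in zip(ii, jj):
            rows.append(("births", sub, np.nan, np.nan, int(i), int(j), repr(float(pop.births[k, i, j]))))
    df = pd.DataFrame(rows, columns=["kind", "subgroup", "age_lo", "age_hi", "row", "col", "value"])
    df.to_csv(path, index=False)


def population_from_csv(path, grid: GridDefinition) -> PopulationGrid:
    df = pd.read_csv(path, float_precision="round_trip")
    counts_df = df[df["kind"] == "count"]
    age_bins = sorted(
        {(lo, hi) for lo, hi in zip(counts_df["age_lo"], counts_df["age_hi"])}
    )
    subgroups = list(pd.unique(df["subgroup"]))  # writer order, "total" first
    counts = np.zeros((len(subgroups), len(age_bins)) + grid.shape)
    births = np.zeros((len(subgroups),) + grid.shape)
    bin_index = {b: k for k, b in enumerate(age_bins)}
    sub_index = {s: k for k, s in enumerate(subgroups)}
    for rec in df.itertuples(index=False):
        k = sub_index[rec.subgroup]
        v = float(rec.value)
        if rec.kind == "count":
            counts[k, bin_index[(rec.age_lo, rec.age_hi)], rec.row, rec.col] = v
        else:
            births[k, rec.row, rec.col] = v
    return PopulationGrid(
        grid=grid,
        age_bins=[(float(lo), float(hi)) for lo, hi in age_bins],
        subgroups=subgroups,
        counts=counts,
        births=births,
    )
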