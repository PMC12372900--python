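"""End-to-end pipeline: synthetic inputs -> burdens -> disparities -> report.

``run_pipeline`` sequences the whole assessment under one seed: generate
(or load) a scenario set, counties, population and rate tables; gap-fill
the rates; compute per-endpoint burdens for the baseline and every
zero-out sensitivity scenario; attribute burdens to lifecycle stages by
differencing with quadrature uncertainty intervals; derive exposure and
burden-rate disparities per racial-ethnic subgroup; probe gap-filling
bias; and write CSV tables plus a JSON manifest. Outputs are
deterministic: the same config and seed give byte-identical text files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .burden import (
    BurdenResult,
    attribute_stage,
    apply_bias_offset,
    cancer_burden,
    scenario_burden,
)
from .containers import HAPS, ConcentrationField, ScenarioSet
from .disparity import (
    SUBGROUPS,
    gap_fill,
    gap_fill_sensitivity,
    population_weighted_exposure,
    relative_disparity,
    subgroup_burden_rate,
)
from .registry import load_registry
from .spatial import attach_rates, intersect_counties
from .synthetic import (
    DEFAULT_STAGES,
    SyntheticScenarioSpec,
    generate_counties,
    generate_grid,
    generate_population,
    generate_rate_table,
    generate_scenarios,
    population_to_csv,
    scenarios_to_netcdf,
)

_CSV_KW = dict(index=False, float_format="%.10g")


@dataclass
class RunConfig:
    """Everything a pipeline run depends on, loadable from YAML."""

    seed: int = 0
    nlat: int = 24
    nlon: int = 30
    origin: tuple[float, float] = (25.0, -110.0)
    resolution: tuple[float, float] = (0.25, 0.3125)
    stages: tuple[str, ...] = DEFAULT_STAGES
    hotspots_per_stage: int = 3
    amplitude_range: tuple[float, float] = (0.5, 4.0)
    plume_length_scale: float = 2.0
    noise_scale: float = 0.2
    population_total: int = 2_000_000
    county_lat_cuts: int = 5
    county_lon_cuts: int = 6
    suppression_threshold: int = 10
    registry_path: str | None = None
    pm25_bias_offset: float = 0.0
    gap_fill_perturbations: tuple[float, ...] = (0.2, 0.3)
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        for key in ("origin", "resolution", "stages", "amplitude_range", "gap_fill_perturbations"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class PipelineResult:
    burden_table: pd.DataFrame       # state, endpoint, pollutant, stage, central, lower, upper, population_base
    national_table: pd.DataFrame     # endpoint, pollutant, stage, central, lower, upper
    shares: pd.DataFrame             # pollutant share of multi-pollutant mortality
    disparity_table: pd.DataFrame    # subgroup, stage, metric, absolute, relative
    gap_fill_log: pd.DataFrame
    sensitivity_reports: dict[float, pd.DataFrame]
    manifest: dict


def summarize_shares(totals: dict[str, float]) -> pd.DataFrame:
    """Each pollutant's share of the multi-pollutant mortality total.

    Shares of the unrounded values sum to 100%; the reported column is
    rounded to integer percent.
    """
    if any(v < 0 for v in totals.values()):
        raise ValueError("burdens must be non-negative")
    total = sum(totals.values())
    if total == 0:
        raise ValueError("total burden is zero; shares undefined")
    rows = [
        {
            "pollutant": p,
            "burden": v,
            "share_percent_raw": 100.0 * v / total,
            "share_percent": int(round(100.0 * v / total)),
        }
        for p, v in totals.items()
    ]
    return pd.DataFrame(rows)


def _field_for(scen: ScenarioSet, pollutant: str, scenario: str, offset: float) -> ConcentrationField:
    f = scen.baseline[pollutant] if scenario == "baseline" else scen.sensitivities[scenario][pollutant]
    if offset and pollutant == "PM2.5":
        f = apply_bias_offset(f, offset)
    return f


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full assessment for one configuration; see module docstring."""
    seed = int(config.seed)
    grid = generate_grid(config.nlat, config.nlon, config.origin, config.resolution)
    spec = SyntheticScenarioSpec(
        hotspots_per_stage=config.hotspots_per_stage,
        amplitude_range=config.amplitude_range,
        plume_length_scale=config.plume_length_scale,
        noise_scale=config.noise_scale,
        seed=seed,
    )
    scen = generate_scenarios(grid, spec, stages=list(config.stages))
    counties = generate_counties(grid, config.county_lat_cuts, config.county_lon_cuts, seed=seed + 1)
    weights = intersect_counties(grid, counties)
    pop = generate_population(grid, total=config.population_total, seed=seed + 2)
    raw_rates = generate_rate_table(
        counties, suppression_threshold=config.suppression_threshold, seed=seed + 3
    )
    rates, gap_log = gap_fill(raw_rates)
    registry = load_registry(config.registry_path)

    state_rows: list[dict] = []
    national_rows: list[dict] = []
    pollutant_mortality: dict[str, float] = {}

    def record(result: BurdenResult, endpoint: str, stage: str) -> None:
        for r in result.state.itertuples(index=False):
            state_rows.append(
                {
                    "state": r.state_id,
                    "endpoint": endpoint,
                    "pollutant": result.pollutant,
                    "stage": stage,
                    "central": r.central,
                    "lower": r.lower,
                    "upper": r.upper,
                    "population_base": result.population_base,
                }
            )
        national_rows.append(
            {
                "endpoint": endpoint,
                "pollutant": result.pollutant,
                "stage": stage,
                "central": result.national.central,
                "lower": result.national.lower,
                "upper": result.national.upper,
            }
        )

    for name, ep in registry.endpoints.items():
        rate_pairs = attach_rates(rates, weights, cause=ep.cause, subgroup="total", age_group="all")
        common = dict(
            pop=pop,
            rate_pairs=rate_pairs,
            model=ep.model,
            endpoint=name,
            population_base=ep.population_base,
        )
        base = scenario_burden(
            _field_for(scen, ep.pollutant, "baseline", config.pm25_bias_offset),
            label="baseline",
            **common,
        )
        record(base, name, "all_sources")
        stage_total = 0.0
        for stage in config.stages:
            sens = scenario_burden(
                _field_for(scen, ep.pollutant, stage, config.pm25_bias_offset),
                label=stage,
                **common,
            )
            attributed = attribute_stage(base, sens, stage)
            record(attributed, name, stage)
            stage_total += attributed.national.central
        if "mortality" in name:
            pollutant_mortality[ep.pollutant] = (
                pollutant_mortality.get(ep.pollutant, 0.0) + stage_total
            )

    # HAP cancers: unit-risk burden, lifetime then annualized
    hap_baseline = [scen.baseline[p] for p in HAPS if p in scen.baseline]
    if hap_baseline:
        cancer_base = cancer_burden(
            hap_baseline, pop, registry.unit_risks, weights.table,
            lifespan_years=registry.lifespan_years, label="baseline",
        )
        record(cancer_base, "hap_cancer_lifetime", "all_sources")
        for stage in config.stages:
            sens_fields = [scen.sensitivities[stage][p] for p in HAPS if p in scen.baseline]
            cancer_sens = cancer_burden(
                sens_fields, pop, registry.unit_risks, weights.table,
                lifespan_years=registry.lifespan_years, label=stage,
            )
            attributed = attribute_stage(cancer_base, cancer_sens, stage)
            record(attributed, "hap_cancer_lifetime", stage)
            national_rows.append(
                {
                    "endpoint": "hap_cancer_annual",
                    "pollutant": attributed.pollutant,
                    "stage": stage,
                    "central": attributed.national.central / registry.lifespan_years,
                    "lower": attributed.national.lower / registry.lifespan_years,
                    "upper": attributed.national.upper / registry.lifespan_years,
                }
            )

    # A degenerate (no-contribution) scenario set yields zero burdens: shares
    # and relative disparities are undefined there, so they are left empty.
    has_signal = sum(pollutant_mortality.values()) > 0
    shares = (
        summarize_shares(pollutant_mortality)
        if has_signal
        else pd.DataFrame(columns=["pollutant", "burden", "share_percent_raw", "share_percent"])
    )

    # Disparities: exposure to each stage's contribution, and per-person
    # attributable burden rates for the rate-based endpoints.
    disparity_rows: list[dict] = []
    for stage in config.stages if has_signal else []:
        for pollutant in scen.pollutants:
            contribution = scen.contribution(stage, pollutant)
            national = population_weighted_exposure(contribution, pop, "total")
            absolute = {
                s: population_weighted_exposure(contribution, pop, s) for s in SUBGROUPS
            }
            rel = relative_disparity(absolute, national)
            for r in rel.itertuples(index=False):
                disparity_rows.append(
                    {
                        "subgroup": r.subgroup,
                        "stage": stage,
                        "metric": f"exposure_{pollutant}",
                        "absolute": r.absolute,
                        "relative": r.relative,
                    }
                )
        for name, ep in registry.endpoints.items():
            # asthma incidence data are not stratified by subgroup; use
            # total-population rates there (disparity mirrors exposure)
            rate_sub = "total" if ep.cause == "asthma_incidence" else None
            kw = dict(
                baseline_field=_field_for(scen, ep.pollutant, "baseline", config.pm25_bias_offset),
                sensitivity_field=_field_for(scen, ep.pollutant, stage, config.pm25_bias_offset),
                pop=pop,
                rates=rates,
                weights=weights,
                model=ep.model,
                endpoint=name,
                cause=ep.cause,
                population_base=ep.population_base,
            )
            national = subgroup_burden_rate(subgroup="total", rate_subgroup="total", **kw)
            absolute = {
                s: subgroup_burden_rate(subgroup=s, rate_subgroup=rate_sub, **kw)
                for s in SUBGROUPS
            }
            rel = relative_disparity(absolute, national)
            for r in rel.itertuples(index=False):
                disparity_rows.append(
                    {
                        "subgroup": r.subgroup,
                        "stage": stage,
                        "metric": f"burden_rate_{name}",
                        "absolute": r.absolute,
                        "relative": r.relative,
                    }
                )
    disparity_table = pd.DataFrame(
        disparity_rows, columns=["subgroup", "stage", "metric", "absolute", "relative"]
    )

    # Gap-fill bias probe on the PM2.5-mortality disparity of the first stage
    probe_stage = config.stages[0]
    probe = registry.endpoints.get("pm25_mortality") or next(iter(registry.endpoints.values()))

    def recompute(rt) -> dict[str, float]:
        kw = dict(
            baseline_field=_field_for(scen, probe.pollutant, "baseline", config.pm25_bias_offset),
            sensitivity_field=_field_for(scen, probe.pollutant, probe_stage, config.pm25_bias_offset),
            pop=pop,
            rates=rt,
            weights=weights,
            model=probe.model,
            endpoint=probe.endpoint,
            cause=probe.cause,
            population_base=probe.population_base,
        )
        national = subgroup_burden_rate(subgroup="total", rate_subgroup="total", **kw)
        return {s: subgroup_burden_rate(subgroup=s, **kw) / national for s in SUBGROUPS}

    sensitivity_reports = {
        p: gap_fill_sensitivity(rates, p, recompute).report
        for p in (config.gap_fill_perturbations if has_signal else ())
    }

    burden_table = pd.DataFrame(state_rows).sort_values(
        ["endpoint", "stage", "state"], kind="stable"
    ).reset_index(drop=True)
    national_table = pd.DataFrame(national_rows).sort_values(
        ["endpoint", "stage"], kind="stable"
    ).reset_index(drop=True)

    manifest = {
        "package_version": __version__,
        "seed": seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
            if k != "outdir"  # the run is identified by its inputs, not its destination
        },
        "n_counties": len(counties),
        "n_counties_uncovered": len(weights.uncovered),
        "n_gap_fill_events": int(len(gap_log)),
        "gap_fill_sources": gap_log["source"].value_counts().to_dict() if len(gap_log) else {},
        "stages": list(config.stages),
        "endpoints": sorted(registry.endpoints),
    }

    result = PipelineResult(
        burden_table=burden_table,
        national_table=national_table,
        shares=shares,
        disparity_table=disparity_table,
        gap_fill_log=gap_log,
        sensitivity_reports=sensitivity_reports,
        manifest=manifest,
    )
    if config.outdir:
        _write_outputs(result, scen, counties, pop, rates, Path(config.outdir))
    return result


def _write_outputs(result: PipelineResult, scen, counties, pop, rates, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.burden_table.to_csv(outdir / "burden_states.csv", **_CSV_KW)
    result.national_table.to_csv(outdir / "burden_national.csv", **_CSV_KW)
    result.shares.to_csv(outdir / "mortality_shares.csv", **_CSV_KW)
    result.disparity_table.to_csv(outdir / "disparity.csv", **_CSV_KW)
    result.gap_fill_log.to_csv(outdir / "gap_fill_log.csv", **_CSV_KW)
    for p, report in result.sensitivity_reports.items():
        report.to_csv(outdir / f"gap_fill_sensitivity_{int(round(p * 100))}.csv", **_CSV_KW)
    scenarios_to_netcdf(scen, outdir / "scenarios.nc")
    counties.to_geojson(outdir / "counties.geojson")
    population_to_csv(pop, outdir / "population.csv")
    rates.to_csv(outdir / "rates.csv")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
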