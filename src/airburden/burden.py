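"""Attributable health burdens, stage attribution, and uncertainty.

For each endpoint, the burden in a (county, cell) overlap pair is

    burden = AF(RR(C_cell)) * rate_county * population_pair

with the attributable fraction AF = (RR - 1)/RR, the county's baseline
rate (per 100,000 per year), and the pair's share of the cell's selected
population. Burdens are computed for a baseline scenario and for each
zero-out sensitivity scenario; a lifecycle stage's burden is the
difference of the two, with an uncertainty interval obtained by combining
the two scenarios' relative errors in quadrature at the reporting level.

Cancers from hazardous air pollutants use lifetime unit risks instead of
rates: lifetime incidences = sum over pollutants and cells of
C * UR * population, annualized by dividing by a statistical lifespan
(76.4 years by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import HAPS, ConcentrationField, PopulationGrid
from .risk import UnitRisk, attributable_fraction, relative_risk

#: US-average statistical lifespan (years) used to annualize lifetime cancers.
DEFAULT_LIFESPAN_YEARS = 76.4

#: Denominator of baseline rates (incidences per 100,000 per year).
RATE_DENOMINATOR = 1e5


def round_to_nearest(x: float, nearest: float) -> float:
    """Round to the nearest multiple of ``nearest`` (e.g. 100)."""
    if nearest <= 0:
        raise ValueError("rounding granularity must be positive")
    return float(nearest * np.round(x / nearest))


def report_round(x: float) -> float:
    """House reporting convention: nearest 100 at/above 10,000, else nearest 10."""
    return round_to_nearest(x, 100.0 if abs(x) >= 10_000 else 10.0)


@dataclass(frozen=True)
class ValueWithUI:
    """A central estimate with its uncertainty interval."""

    central: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (self.lower <= self.central <= self.upper):
            raise ValueError("require lower <= central <= upper")

    def rel_half_width(self, side: str) -> float:
        """Relative half-width on one side ('lower' or 'upper').

        Zero for a degenerate zero-central, zero-width value.
        """
        hw = {"lower": self.central - self.lower, "upper": self.upper - self.central}[side]
        if self.central == 0:
            if hw == 0:
                return 0.0
            raise ValueError(
                "relative error undefined for a zero central value; "
                "report absolute half-widths instead"
            )
        return hw / self.central

    def rounded(self, nearest: float) -> "ValueWithUI":
        return ValueWithUI(
            round_to_nearest(self.central, nearest),
            round_to_nearest(self.lower, nearest),
            round_to_nearest(self.upper, nearest),
        )

    def scaled(self, k: float) -> "ValueWithUI":
        return ValueWithUI(self.central * k, self.lower * k, self.upper * k)


def quadrature_ui(a: ValueWithUI, b: ValueWithUI) -> ValueWithUI:
    """Uncertainty interval of the difference a - b by quadrature.

    Per side, the relative half-widths of ``a`` and ``b`` are combined as
    sqrt(rel_a^2 + rel_b^2) and applied to the central difference. The
    two sides are treated separately, so asymmetric intervals stay
    asymmetric. Raw (unrounded) values are returned; apply
    :meth:`ValueWithUI.rounded` for reporting.
    """
    if b.central < 0 or a.central < b.central:
        raise ValueError("require a.central >= b.central >= 0 (burdens reported as positive)")
    d = a.central - b.central
    if d == 0:
        return ValueWithUI(0.0, 0.0, 0.0)
    rel = {
        side: math.hypot(a.rel_half_width(side), b.rel_half_width(side))
        for side in ("lower", "upper")
    }
    return ValueWithUI(d, d * (1.0 - rel["lower"]), d * (1.0 + rel["upper"]))


def combined_relative_error(a: ValueWithUI, b: ValueWithUI) -> float:
    """Symmetric combined relative error of a - b (fraction, not percent).

    Each input's relative uncertainty is its average half-width divided by
    its central value; the two are added in quadrature. This is the single
    number quoted alongside an asymmetric interval.
    """
    def sym_rel(v: ValueWithUI) -> float:
        if v.central == 0:
            return 0.0
        return 0.5 * ((v.upper - v.lower)) / v.central

    return math.hypot(sym_rel(a), sym_rel(b))


@dataclass
class BurdenResult:
    """Attributable incidences resolved by (county, cell), state, nation.

    ``pairs`` carries columns (county_id, state_id, row, col, central,
    lower, upper); ``state`` the per-state sums; ``national`` the national
    total with its uncertainty interval. Cancer results additionally carry
    the lifetime total and the lifespan used to annualize it (the
    pairs/state/national values are annual occurrences).
    """

    endpoint: str
    pollutant: str
    label: str  # scenario or stage name
    pairs: pd.DataFrame
    state: pd.DataFrame
    national: ValueWithUI
    population_base: str = "population"
    lifetime: ValueWithUI | None = None
    lifespan_years: float | None = None

    def state_ui(self, state_id: str) -> ValueWithUI:
        row = self.state[self.state["state_id"] == state_id]
        if row.empty:
            raise KeyError(f"no state {state_id!r} in this result")
        r = row.iloc[0]
        return ValueWithUI(r["central"], r["lower"], r["upper"])


def _aggregate_pairs(pairs: pd.DataFrame) -> tuple[pd.DataFrame, ValueWithUI]:
    cols = ["central", "lower", "upper"]
    state = pairs.groupby("state_id", as_index=False)[cols].sum().sort_values("state_id")
    tot = pairs[cols].sum()
    return state.reset_index(drop=True), ValueWithUI(tot["central"], tot["lower"], tot["upper"])


def scenario_burden(
    conc: ConcentrationField,
    pop: PopulationGrid,
    rate_pairs: pd.DataFrame,
    model,
    endpoint: str,
    population_base: str = "population",
    age_range: tuple[float, float] | None = None,
    subgroup: str = "total",
    label: str = "baseline",
) -> BurdenResult:
    """Attributable burden of one scenario's concentration field.

    ``rate_pairs`` comes from :func:`airburden.spatial.attach_rates`:
    per-(county, cell) rows carrying the county rate (per 100,000/yr) and
    the pair's ``cell_share`` of the cell's population.
    """
    if getattr(model, "units", conc.units) != conc.units:
        raise ValueError(
            f"unit mismatch: model expects {model.units}, field is in {conc.units}"
        )
    if conc.grid != pop.grid:
        raise ValueError("concentration field and population are on different grids")
    if population_base == "births":
        base = pop.births_for(subgroup)
    elif population_base == "population":
        lo, hi = age_range if age_range is not None else getattr(model, "age_range", (0.0, 200.0))
        base = pop.select_age(lo, hi, subgroup)
    else:
        raise ValueError(f"unknown population base {population_base!r}")

    af = attributable_fraction(relative_risk(model, conc.values))
    rows = rate_pairs["row"].to_numpy()
    cols = rate_pairs["col"].to_numpy()
    pair_pop = base[rows, cols] * rate_pairs["cell_share"].to_numpy()
    scale = rate_pairs["rate"].to_numpy() / RATE_DENOMINATOR * pair_pop

    pairs = rate_pairs[["county_id", "state_id", "row", "col"]].copy()
    pairs["central"] = np.asarray(af.central)[rows, cols] * scale
    pairs["lower"] = np.asarray(af.low)[rows, cols] * scale
    pairs["upper"] = np.asarray(af.high)[rows, cols] * scale
    state, national = _aggregate_pairs(pairs)
    return BurdenResult(
        endpoint=endpoint,
        pollutant=conc.pollutant,
        label=label,
        pairs=pairs,
        state=state,
        national=national,
        population_base=population_base,
    )


def cancer_burden(
    hap_fields: list[ConcentrationField],
    pop: PopulationGrid,
    unit_risks: dict[str, UnitRisk],
    weight_pairs: pd.DataFrame,
    subgroup: str = "total",
    lifespan_years: float = DEFAULT_LIFESPAN_YEARS,
    label: str = "baseline",
) -> BurdenResult:
    """Lifetime and annualized cancer incidences from hazardous air pollutants.

    Cancer risks are treated as additive across pollutants: lifetime
    incidences = sum over pollutants and cells of C x UR x population
    (all ages); annual occurrences divide the lifetime total by the
    statistical lifespan. Unit risks carry no confidence bounds, so the
    interval is degenerate.
    """
    risk_per_cell = None
    for f in hap_fields:
        if f.pollutant not in HAPS:
            raise ValueError(f"{f.pollutant!r} is not a registered hazardous air pollutant")
        if f.pollutant not in unit_risks:
            raise ValueError(f"no unit risk registered for {f.pollutant!r}")
        if f.units != "ug/m3" or f.metric != "annual_mean":
            raise ValueError("cancer burden requires annual-mean fields in ug/m3")
        contrib = f.values * unit_risks[f.pollutant].risk_per_ugm3
        risk_per_cell = contrib if risk_per_cell is None else risk_per_cell + contrib
    if risk_per_cell is None:
        raise ValueError("no hazardous-air-pollutant fields supplied")

    base = pop.select_age(0.0, 200.0, subgroup)
    rows = weight_pairs["row"].to_numpy()
    cols = weight_pairs["col"].to_numpy()
    lifetime_pair = (
        risk_per_cell[rows, cols] * base[rows, cols] * weight_pairs["cell_share"].to_numpy()
    )
    pairs = weight_pairs[["county_id", "state_id", "row", "col"]].copy()
    for c in ("central", "lower", "upper"):
        pairs[c] = lifetime_pair
    state, lifetime_national = _aggregate_pairs(pairs)
    return BurdenResult(
        endpoint="hap_cancer",
        pollutant="+".join(f.pollutant for f in hap_fields),
        label=label,
        pairs=pairs,
        state=state,
        national=lifetime_national,
        population_base="population",
        lifetime=lifetime_national,
        lifespan_years=lifespan_years,
    )


def annualize_lifetime(lifetime: float, lifespan_years: float = DEFAULT_LIFESPAN_YEARS) -> float:
    """Convert lifetime incidences to occurrences per year."""
    if lifespan_years <= 0:
        raise ValueError("lifespan must be positive")
    return lifetime / lifespan_years


def attribute_stage(baseline: BurdenResult, sensitivity: BurdenResult, stage: str) -> BurdenResult:
    """Burden attributable to one lifecycle stage, by zero-out differencing.

    Central estimates subtract at every level; uncertainty intervals at
    the state and national reporting levels combine the two scenarios'
    relative errors in quadrature (never per cell).
    """
    if baseline.endpoint != sensitivity.endpoint or baseline.pollutant != sensitivity.pollutant:
        raise ValueError("baseline and sensitivity results are for different endpoints")
    key = ["county_id", "state_id", "row", "col"]
    merged = baseline.pairs.merge(
        sensitivity.pairs, on=key, suffixes=("_base", "_sens"), validate="one_to_one"
    )
    pairs = merged[key].copy()
    for c in ("central", "lower", "upper"):
        pairs[c] = merged[f"{c}_base"] - merged[f"{c}_sens"]

    state_rows = []
    for sid in baseline.state["state_id"]:
        ui = quadrature_ui(baseline.state_ui(sid), sensitivity.state_ui(sid))
        state_rows.append({"state_id": sid, "central": ui.central, "lower": ui.lower, "upper": ui.upper})
    state = pd.DataFrame(state_rows)
    national = quadrature_ui(baseline.national, sensitivity.national)
    lifetime = None
    if baseline.lifetime is not None and sensitivity.lifetime is not None:
        lifetime = quadrature_ui(baseline.lifetime, sensitivity.lifetime)
    return BurdenResult(
        endpoint=baseline.endpoint,
        pollutant=baseline.pollutant,
        label=stage,
        pairs=pairs,
        state=state,
        national=national,
        population_base=baseline.population_base,
        lifetime=lifetime,
        lifespan_years=baseline.lifespan_years,
    )


def apply_bias_offset(conc: ConcentrationField, offset: float) -> ConcentrationField:
    """Subtract a uniform bias offset, clamping at zero.

    Used for the sensitivity analysis that removes a systematic model
    overestimate (e.g. a robust-regression intercept) from every cell
    before burden computation; must be applied consistently to the
    baseline and all sensitivity fields.
    """
    if not np.isfinite(offset):
        raise ValueError("offset must be finite")
    return conc.with_values(np.maximum(0.0, conc.values - offset))


def threshold_crossing_population(
    baseline: ConcentrationField,
    removed: ConcentrationField,
    pop: PopulationGrid,
    threshold: float,
    subgroup: str = "total",
) -> float:
    """Persons moved below a risk threshold by removing a source.

    Counts the population of cells at/above the threshold in the baseline
    but below it once the source's contribution is removed.
    """
    if baseline.grid != removed.grid or baseline.grid != pop.grid:
        raise ValueError("fields and population must share one grid")
    crossing = (baseline.values >= threshold) & (removed.values < threshold)
    base = pop.select_age(0.0, 200.0, subgroup)
    return float(base[crossing].sum())
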