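"""In-memory containers shared across the pipeline.

``ConcentrationField`` wraps one pollutant's gridded exposure metric,
``ScenarioSet`` bundles a baseline simulation with its zero-out
sensitivity counterparts, and ``PopulationGrid`` holds cell x age-bin x
subgroup person counts plus annual births.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import GridDefinition

#: Pollutants the pipeline knows about, with their expected units.
POLLUTANT_UNITS = {
    "PM2.5": "ug/m3",
    "NO2": "ppb",
    "MDA8_O3": "ppb",
    "formaldehyde": "ug/m3",
    "acetaldehyde": "ug/m3",
    "benzene": "ug/m3",
}

#: Hazardous air pollutants assessed through lifetime unit cancer risks.
HAPS = ("formaldehyde", "acetaldehyde", "benzene")


@dataclass
class ConcentrationField:
    """One pollutant's gridded exposure metric on a shared grid.

    ``metric`` is ``"annual_mean"`` for PM2.5, NO2 and the HAPs and
    ``"peak_season_mda8"`` for ozone (maximum daily 8-hour mean averaged
    over the peak season).
    """

    pollutant: str
    values: np.ndarray
    grid: GridDefinition
    metric: str = "annual_mean"
    units: str = ""

    def __post_init__(self) -> None:
        if self.pollutant not in POLLUTANT_UNITS:
            raise ValueError(f"unknown pollutant {self.pollutant!r}")
        self.values = np.asarray(self.values, float)
        if self.values.shape != self.grid.shape:
            raise ValueError("field shape does not match the grid")
        if np.any(self.values < 0):
            raise ValueError("concentrations must be non-negative")
        if not self.units:
            self.units = POLLUTANT_UNITS[self.pollutant]
        if self.metric == "peak_season_mda8" and self.pollutant != "MDA8_O3":
            raise ValueError("the peak-season MDA8 metric applies only to ozone")
        if self.pollutant == "MDA8_O3" and self.metric != "peak_season_mda8":
            raise ValueError("ozone exposure uses the peak-season MDA8 metric")

    def with_values(self, values: np.ndarray) -> "ConcentrationField":
        return ConcentrationField(
            self.pollutant, values, self.grid, metric=self.metric, units=self.units
        )


@dataclass
class ScenarioSet:
    """Baseline plus named zero-out sensitivity concentration fields.

    ``sensitivities[stage][pollutant]`` is the field simulated with that
    lifecycle stage's emissions removed; ``baseline - sensitivity`` is the
    stage's contribution. The generator also stores the true contribution
    fields it used, so attribution can be checked against them exactly.
    """

    grid: GridDefinition
    baseline: dict[str, ConcentrationField]
    sensitivities: dict[str, dict[str, ConcentrationField]]
    contributions: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = list(self.sensitivities)
        if len(set(names)) != len(names):
            raise ValueError("scenario names must be unique")
        for f in self.baseline.values():
            if f.grid != self.grid:
                raise ValueError("all fields must share one grid")
        for stage, fields in self.sensitivities.items():
            if set(fields) != set(self.baseline):
                raise ValueError(f"stage {stage!r} is missing pollutants")

    @property
    def stages(self) -> list[str]:
        return list(self.sensitivities)

    @property
    def pollutants(self) -> list[str]:
        return list(self.baseline)

    def contribution(self, stage: str, pollutant: str) -> np.ndarray:
        """Stage contribution by zero-out differencing."""
        return self.baseline[pollutant].values - self.sensitivities[stage][pollutant].values

    def total_removed(self, pollutant: str) -> np.ndarray:
        """Baseline minus the summed contribution of every stage."""
        total = sum(self.contribution(s, pollutant) for s in self.stages)
        return np.maximum(0.0, self.baseline[pollutant].values - total)


@dataclass
class PopulationGrid:
    """Cell x age-bin x subgroup person counts plus annual births.

    ``counts`` has shape (n_subgroups, n_age_bins, nlat, nlon) and
    ``births`` (n_subgroups, nlat, nlon). The first subgroup is always
    ``"total"``; the remaining subgroups need not sum to it (a multiracial
    remainder is allowed).
    """

    grid: GridDefinition
    age_bins: list[tuple[float, float]]
    subgroups: list[str]
    counts: np.ndarray
    births: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, float)
        self.births = np.asarray(self.births, float)
        bins = self.age_bins
        if any(hi <= lo for lo, hi in bins):
            raise ValueError("age bins must have positive width")
        for (_lo, prev_hi), (lo, _hi) in zip(bins[:-1], bins[1:]):
            if not np.isclose(prev_hi, lo):
                raise ValueError("age bins must be contiguous (no gaps or overlaps)")
        if self.subgroups[0] != "total":
            raise ValueError('the first subgroup must be "total"')
        expected = (len(self.subgroups), len(bins)) + self.grid.shape
        if self.counts.shape != expected:
            raise ValueError(f"counts shape {self.counts.shape} != {expected}")
        if self.births.shape != (len(self.subgroups),) + self.grid.shape:
            raise ValueError("births shape must be (n_subgroups, nlat, nlon)")
        if np.any(self.counts < 0) or np.any(self.births < 0):
            raise ValueError("person counts must be non-negative")

    def subgroup_index(self, subgroup: str) -> int:
        try:
            return self.subgroups.index(subgroup)
        except ValueError:
            raise KeyError(f"unknown subgroup {subgroup!r}") from None

    def select_age(self, age_lo: float, age_hi: float, subgroup: str = "total") -> np.ndarray:
        """Persons per cell within an age range, one subgroup.

        Bins partially overlapping the range contribute the overlapping
        fraction of their count (ages assumed uniform within a bin).
        """
        k = self.subgroup_index(subgroup)
        out = np.zeros(self.grid.shape)
        for b, (lo, hi) in enumerate(self.age_bins):
            overlap = max(0.0, min(hi, age_hi) - max(lo, age_lo))
            if overlap > 0:
                out += self.counts[k, b] * (overlap / (hi - lo))
        return out

    def total_persons(self, subgroup: str = "total") -> float:
        return float(self.counts[self.subgroup_index(subgroup)].sum())

    def births_for(self, subgroup: str = "total") -> np.ndarray:
        return self.births[self.subgroup_index(subgroup)]
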