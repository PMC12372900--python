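"""Endpoint registry: risk-model parameters keyed by health endpoint.

The registry is a YAML file holding, per endpoint, the concentration-
response model and everything needed to apply it: pollutant, baseline-rate
cause, population base (persons within an age range, or births), and the
model parameters with confidence bounds. A default registry ships with
the package; alternative curves (e.g. a different PM2.5-mortality
function) are swapped in by pointing at a different file — supporting the
standard sensitivity analysis of exchanging risk models without touching
pipeline code.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import yaml

from .risk import LogLinearRR, PiecewiseRRCurve, UnitRisk


@dataclass(frozen=True)
class EndpointSpec:
    """One endpoint's risk model plus how to apply it."""

    endpoint: str
    pollutant: str
    cause: str
    population_base: str  # "population" | "births"
    model: LogLinearRR | PiecewiseRRCurve

    @property
    def age_range(self) -> tuple[float, float]:
        return self.model.age_range


@dataclass(frozen=True)
class Registry:
    endpoints: dict[str, EndpointSpec]
    unit_risks: dict[str, UnitRisk]
    lifespan_years: float

    def __getitem__(self, endpoint: str) -> EndpointSpec:
        return self.endpoints[endpoint]


def _build_model(name: str, cfg: dict):
    age_range = tuple(cfg.get("age_range", (0.0, 200.0)))
    units = cfg.get("units", "ug/m3")
    if cfg["model"] == "loglinear":
        central, low, high = cfg["rr"]
        return LogLinearRR(
            endpoint=name,
            rr_central=central,
            rr_low=low,
            rr_high=high,
            increment=float(cfg["increment"]),
            counterfactual=float(cfg["counterfactual"]),
            units=units,
            age_range=age_range,
        )
    if cfg["model"] == "piecewise":
        curve = cfg["curve"]
        return PiecewiseRRCurve(
            endpoint=name,
            concentrations=curve["concentrations"],
            rr_central=curve["rr_central"],
            rr_low=curve["rr_low"],
            rr_high=curve["rr_high"],
            units=units,
            age_range=age_range,
        )
    raise ValueError(f"unknown model kind {cfg['model']!r} for endpoint {name}")


def load_registry(path=None) -> Registry:
    """Load an endpoint registry from YAML (package default if no path)."""
    if path is None:
        text = resources.files("airburden").joinpath("data/endpoints.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    endpoints = {
        name: EndpointSpec(
            endpoint=name,
            pollutant=cfg["pollutant"],
            cause=cfg["cause"],
            population_base=cfg.get("population_base", "population"),
            model=_build_model(name, cfg),
        )
        for name, cfg in raw["endpoints"].items()
    }
    unit_risks = {
        p: UnitRisk(pollutant=p, risk_per_ugm3=float(v))
        for p, v in raw.get("unit_risks", {}).items()
    }
    return Registry(
        endpoints=endpoints,
        unit_risks=unit_risks,
        lifespan_years=float(raw.get("lifespan_years", 76.4)),
    )
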