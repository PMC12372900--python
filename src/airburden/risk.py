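"""Concentration-response models: relative risk and attributable fraction.

Three model families cover the chronic-exposure endpoints assessed:

* :class:`LogLinearRR` — the usual epidemiological log-linear form, where a
  published hazard ratio per fixed increment (e.g. 1.046 per 10 ppb NO2)
  is converted to a continuous relative risk above a counterfactual
  concentration ``c0``.
* :class:`PiecewiseRRCurve` — a tabulated (concentration, RR) curve with
  piecewise-linear interpolation, used for supralinear PM2.5-mortality
  functions that are published as curves rather than a single coefficient.
* :class:`UnitRisk` — a lifetime excess-cancer probability per 1 ug/m3 of
  continuous exposure, as used for hazardous air pollutants; no
  counterfactual applies.

Central, lower and upper risk estimates are carried through every
computation as three deterministic curves, so burden uncertainty intervals
come from evaluating the same pipeline at the confidence bounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_SIDES = ("central", "low", "high")


def _as_nonneg(concentration):
    c = np.asarray(concentration, float)
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    return c


@dataclass(frozen=True)
class RRTriple:
    """Relative risk with its confidence bounds (low <= central <= high)."""

    central: np.ndarray | float
    low: np.ndarray | float
    high: np.ndarray | float

    def __iter__(self):
        return iter((self.central, self.low, self.high))


@dataclass(frozen=True)
class LogLinearRR:
    """Log-linear relative-risk model RR(C) = exp(beta * max(0, C - c0)).

    ``beta = ln(rr_per_increment) / increment`` separately for the central
    estimate and each confidence bound.
    """

    endpoint: str
    rr_central: float
    rr_low: float
    rr_high: float
    increment: float
    counterfactual: float
    units: str = "ug/m3"
    age_range: tuple[float, float] = (0.0, 200.0)

    def __post_init__(self) -> None:
        if not (0 < self.rr_low <= self.rr_central <= self.rr_high):
            raise ValueError("require 0 < rr_low <= rr_central <= rr_high")
        if self.increment <= 0:
            raise ValueError("increment must be positive")
        if self.counterfactual < 0:
            raise ValueError("counterfactual must be non-negative")

    def beta(self, side: str = "central") -> float:
        rr = {"central": self.rr_central, "low": self.rr_low, "high": self.rr_high}[side]
        return float(np.log(rr) / self.increment)

    def relative_risk(self, concentration) -> RRTriple:
        c = _as_nonneg(concentration)
        excess = np.maximum(0.0, c - self.counterfactual)
        return RRTriple(*(np.exp(self.beta(s) * excess) for s in _SIDES))


@dataclass(frozen=True)
class PiecewiseRRCurve:
    """Tabulated relative-risk curve with piecewise-linear interpolation.

    Nodes are (concentration, RR_central, RR_low, RR_high), with
    concentrations strictly increasing. RR = 1 at and below the
    counterfactual (the first node) and is held constant above the last
    node (the saturation concentration).
    """

    endpoint: str
    concentrations: np.ndarray
    rr_central: np.ndarray
    rr_low: np.ndarray
    rr_high: np.ndarray
    units: str = "ug/m3"
    age_range: tuple[float, float] = (0.0, 200.0)

    def __post_init__(self) -> None:
        for name in ("concentrations", "rr_central", "rr_low", "rr_high"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        c = self.concentrations
        if c.ndim != 1 or c.size < 2:
            raise ValueError("a curve needs at least two nodes")
        if not np.all(np.diff(c) > 0):
            raise ValueError("node concentrations must be strictly increasing")
        if self.rr_central.shape != c.shape:
            raise ValueError("node arrays must share one shape")
        if not np.isclose(self.rr_central[0], 1.0):
            raise ValueError("RR must equal 1 at the counterfactual (first node)")
        for rr in (self.rr_central, self.rr_low, self.rr_high):
            if rr.shape != c.shape:
                raise ValueError("node arrays must share one shape")
            if np.any(np.diff(rr) < -1e-12):
                raise ValueError("RR must be non-decreasing in concentration")
        if np.any(self.rr_low > self.rr_central) or np.any(self.rr_central > self.rr_high):
            raise ValueError("require rr_low <= rr_central <= rr_high at every node")

    @property
    def counterfactual(self) -> float:
        return float(self.concentrations[0])

    @property
    def saturation(self) -> float:
        return float(self.concentrations[-1])

    def relative_risk(self, concentration) -> RRTriple:
        c = _as_nonneg(concentration)
        out = []
        for rr in (self.rr_central, self.rr_low, self.rr_high):
            v = np.interp(c, self.concentrations, rr)  # np.interp clamps at both ends
            v = np.where(c <= self.counterfactual, 1.0, v)
            out.append(v if v.ndim else float(v))
        return RRTriple(*out)


@dataclass(frozen=True)
class UnitRisk:
    """Lifetime excess cancer risk per 1 ug/m3 of continuous exposure."""

    pollutant: str
    risk_per_ugm3: float

    def __post_init__(self) -> None:
        if self.risk_per_ugm3 <= 0:
            raise ValueError("unit risk must be positive")


def relative_risk(model, concentration) -> RRTriple:
    """Evaluate a risk model at a concentration (scalar or field)."""
    return model.relative_risk(concentration)


def attributable_fraction(rr: RRTriple) -> RRTriple:
    """Population attributable fraction AF = (RR - 1) / RR per side.

    Requires RR >= 1 componentwise, which the counterfactual clamping in
    :func:`relative_risk` guarantees; RR < 1 signals a mis-specified curve.
    """
    out = []
    for v in rr:
        v = np.asarray(v, float)
        if np.any(v < 1.0 - 1e-12):
            raise ValueError("relative risk below 1; check the curve and counterfactual")
        af = (v - 1.0) / v
        out.append(af if af.ndim else float(af))
    return RRTriple(*out)


def unit_risk_ratio(a: UnitRisk, b: UnitRisk) -> float:
    """Ratio of two lifetime unit risks (how much more potent a is than b)."""
    return a.risk_per_ugm3 / b.risk_per_ugm3


def build_hybrid_curve(
    low_curve: PiecewiseRRCurve,
    high_curve: PiecewiseRRCurve,
    junction: float,
) -> PiecewiseRRCurve:
    """Splice a low-concentration curve onto a high-concentration curve.

    The result uses ``low_curve`` nodes below the junction and
    ``high_curve`` nodes at and above it. Continuity at the junction is
    enforced by inserting the junction node evaluated from the low curve
    and rescaling the high curve multiplicatively so the two agree there.
    """
    if not (low_curve.counterfactual <= junction <= low_curve.saturation):
        raise ValueError("junction outside the low curve's domain")
    if not (high_curve.counterfactual <= junction <= high_curve.saturation):
        raise ValueError("junction outside the high curve's domain")

    rr_low_at_j = low_curve.relative_risk(junction)
    rr_high_at_j = high_curve.relative_risk(junction)

    keep = low_curve.concentrations < junction
    above = high_curve.concentrations > junction

    conc = np.concatenate(
        [low_curve.concentrations[keep], [junction], high_curve.concentrations[above]]
    )
    nodes = {}
    for side, lo_j, hi_j in zip(_SIDES, rr_low_at_j, rr_high_at_j):
        lo_vals = getattr(low_curve, f"rr_{side}")
        hi_vals = getattr(high_curve, f"rr_{side}")
        scale = lo_j / hi_j
        nodes[side] = np.concatenate([lo_vals[keep], [lo_j], hi_vals[above] * scale])

    return PiecewiseRRCurve(
        endpoint=low_curve.endpoint,
        concentrations=conc,
        rr_central=nodes["central"],
        rr_low=nodes["low"],
        rr_high=nodes["high"],
        units=low_curve.units,
        age_range=low_curve.age_range,
    )
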