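"""Model-evaluation statistics against monitor observations.

Gridded model fields are evaluated against surface-monitor series with
the usual regional-modelling toolkit: a temporal-coverage filter (sites
must report at least 75% of each month of interest), normalized mean
bias, standard major axis regression (symmetric in model and
observation), and the outlier-robust Theil-Sen fit with its rank-based
confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_MIN_COVERAGE = 0.75


@dataclass
class ObservationSet:
    """Per-site observation series with monthly completeness bookkeeping.

    ``records`` columns: site_id, row, col, date, value.
    ``completeness`` columns: site_id, month (1-12), fraction.
    """

    records: pd.DataFrame
    completeness: pd.DataFrame

    def __post_init__(self) -> None:
        frac = self.completeness["fraction"]
        if ((frac < 0) | (frac > 1)).any():
            raise ValueError("completeness fractions must lie in [0, 1]")
        if not np.isfinite(self.records["value"]).all():
            raise ValueError("observed values must be finite")

    @property
    def sites(self) -> list:
        return sorted(self.records["site_id"].unique())

    def site_means(self) -> pd.DataFrame:
        """Per-site mean observed value with the site's grid cell."""
        return (
            self.records.groupby(["site_id", "row", "col"], as_index=False)["value"]
            .mean()
            .sort_values("site_id")
            .reset_index(drop=True)
        )


def coverage_filter(
    obs: ObservationSet,
    months: list[int],
    min_fraction: float = DEFAULT_MIN_COVERAGE,
) -> ObservationSet:
    """Retain only sites meeting the coverage threshold in every listed month."""
    if not months:
        raise ValueError("months must be non-empty")
    comp = obs.completeness
    sel = comp[comp["month"].isin(months)]
    ok_counts = sel[sel["fraction"] >= min_fraction].groupby("site_id").size()
    keep = set(ok_counts[ok_counts == len(months)].index)
    # sites with a month entirely absent from the bookkeeping fail the filter
    present = sel.groupby("site_id").size()
    keep &= set(present[present == len(months)].index)
    return ObservationSet(
        records=obs.records[obs.records["site_id"].isin(keep)].reset_index(drop=True),
        completeness=comp[comp["site_id"].isin(keep)].reset_index(drop=True),
    )


def nmb(model, obs) -> float:
    """Normalized mean bias in percent: 100 * sum(model - obs) / sum(obs)."""
    m = np.asarray(model, float)
    o = np.asarray(obs, float)
    if m.shape != o.shape or m.size == 0:
        raise ValueError("model and observations must be paired and non-empty")
    denom = o.sum()
    if denom <= 0:
        raise ValueError("sum of observations must be positive")
    return float(100.0 * (m - o).sum() / denom)


def sma_regression(x, y) -> tuple[float, float]:
    """Standard major axis fit: slope = sign(r) * sd(y)/sd(x).

    Symmetric in which variable is 'model' and which 'observation',
    unlike ordinary least squares.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need at least three points")
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    if sx == 0:
        raise ValueError("x has zero variance")
    r = np.corrcoef(x, y)[0, 1]
    slope = float(np.sign(r) * sy / sx) if r != 0 else float(sy / sx)
    intercept = float(y.mean() - slope * x.mean())
    return slope, intercept


def theil_sen(x, y, confidence: float = 0.95):
    """Theil-Sen fit: median pairwise slope with a rank-based slope CI.

    Returns (slope, intercept, (ci_low, ci_high)). The intercept is
    median(y - slope * x); the confidence interval comes from the
    distribution-free rank method on the ordered pairwise slopes.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need at least three points")
    if np.ptp(x) == 0:
        raise ValueError("all x values identical")
    res = stats.theilslopes(y, x, alpha=confidence, method="joint")
    return float(res.slope), float(res.intercept), (float(res.low_slope), float(res.high_slope))


def pearson_r(x, y) -> float:
    """Pearson correlation (the spatial-consistency statistic reported)."""
    return float(np.corrcoef(np.asarray(x, float), np.asarray(y, float))[0, 1])


def evaluation_report(
    pollutant: str,
    model_values,
    obs_values,
    n_sites: int,
) -> pd.DataFrame:
    """One-row evaluation summary (NMB %, R, SMA and Theil-Sen fits)."""
    slope, intercept = sma_regression(obs_values, model_values)
    ts_slope, ts_intercept, (lo, hi) = theil_sen(obs_values, model_values)
    return pd.DataFrame(
        [
            {
                "pollutant": pollutant,
                "n_sites": n_sites,
                "nmb_percent": nmb(model_values, obs_values),
                "pearson_r": pearson_r(obs_values, model_values),
                "sma_slope": slope,
                "sma_intercept": intercept,
                "theil_sen_slope": ts_slope,
                "theil_sen_intercept": ts_intercept,
                "theil_sen_ci_low": lo,
                "theil_sen_ci_high": hi,
            }
        ]
    )
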