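"""Seasonal compositing and linear trend tests for climate/NDVI series.

Observations within a season (spring = Mar–May, fall = Sep–Nov) are
reduced to a per-pixel median composite, the composite is reduced to a
single extent-wide median, and the resulting one-value-per-year series is
tested for a linear time trend with ordinary least squares (slope on
calendar year, two-sided t test on n − 2 degrees of freedom).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SEASON_MONTHS",
    "TrendFit",
    "seasonal_median_composite",
    "extent_median",
    "series_from_stacks",
    "fit_trend",
]

SEASON_MONTHS = {"spring": (3, 4, 5), "fall": (9, 10, 11)}


@dataclass(frozen=True)
class TrendFit:
    slope: float
    slope_se: float
    intercept: float
    t_stat: float
    p_value: float
    n_years: int
    degenerate: bool = False


def seasonal_median_composite(
    observations: list[tuple[object, np.ndarray]],
    season: str,
    year: int,
) -> np.ndarray:
    """Per-pixel median of all within-season observations for one year.

    ``observations`` pairs a date (anything with .year/.month, e.g.
    pandas Timestamps) with a 2D value lattice; NaN marks missing pixels.
    Pixels with no valid observation stay NaN in the composite.
    """
    months = SEASON_MONTHS[season]
    ts = [(pd.Timestamp(d), a) for d, a in observations]
    layers = [np.asarray(a, dtype=float) for d, a in ts
              if d.year == year and d.month in months]
    if not layers:
        raise ValueError(f"no observations for season {season!r} of year {year}")
    shapes = {a.shape for a in layers}
    if len(shapes) > 1:
        raise ValueError(f"observation lattices differ in shape: {shapes}")
    stack = np.stack(layers)
    with warnings.catch_warnings():
        # all-NaN pixels legitimately stay NaN in the composite
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmedian(stack, axis=0)


def extent_median(composite: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Median of the valid in-mask pixels of a composite."""
    composite = np.asarray(composite, dtype=float)
    if mask is not None:
        composite = composite[np.asarray(mask, dtype=bool)]
    composite = composite[np.isfinite(composite)]
    if composite.size == 0:
        raise ValueError("no valid pixels inside the mask")
    return float(np.median(composite))


def series_from_stacks(
    observations: list[tuple[object, np.ndarray]],
    season: str,
    mask: np.ndarray | None = None,
) -> pd.Series:
    """Yearly extent-median series from a multi-year observation stack."""
    years = sorted({pd.Timestamp(d).year for d, _ in observations
                    if pd.Timestamp(d).month in SEASON_MONTHS[season]})
    vals = {y: extent_median(seasonal_median_composite(observations, season, y), mask)
            for y in years}
    return pd.Series(vals, name=season).sort_index()


def fit_trend(series: pd.Series) -> TrendFit:
    """OLS trend of a yearly series: value ~ year.

    Closed-form slope and intercept with the year centered for numerical
    stability (the slope is unchanged); two-sided p from the t
    distribution with n − 2 df. A residual-free fit is returned with
    SE 0, p 0 and the ``degenerate`` flag set.
    """
    years = np.asarray(series.index, dtype=float)
    y = series.to_numpy(dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("trend fit needs at least 3 years")
    if len(np.unique(years)) != n:
        raise ValueError("duplicate years in series")
    xc = years - years.mean()
    sxx = float(xc @ xc)
    if sxx == 0:
        raise ValueError("year vector is constant")
    slope = float(xc @ (y - y.mean())) / sxx
    intercept = float(y.mean() - slope * years.mean())
    resid = y - (intercept + slope * years)
    ssr = float(resid @ resid)
    if ssr <= 1e-12 * max(float(y @ y), 1.0):
        return TrendFit(slope, 0.0, intercept, float("inf") if slope else 0.0,
                        0.0 if slope else 1.0, n, degenerate=True)
    s2 = ssr / (n - 2)
    se = float(np.sqrt(s2 / sxx))
    t = slope / se
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return TrendFit(slope, se, intercept, t, p, n)
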