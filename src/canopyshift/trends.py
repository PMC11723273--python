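"""Per-pixel, per-month linear trends of LAI/VLAI with significance classes.

The trend estimator is ordinary least squares of the monthly value on the
calendar year, with a two-sided t-test on the slope (n-2 degrees of
freedom).  Pixels are classified into four categories by slope sign and
significance at a fixed alpha (default 0.05, no multiple-testing
correction), and summarised per vegetation class as area percentages plus
the mean slope over significant pixels, reported in 1e-3 m2/m2 per year to
match the usual presentation scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .stack import CLASS_CODES, MonthlyStack, VegetationMask, VEG_CLASSES

log = logging.getLogger(__name__)

CATEGORY_CODES = {"sig_increase": 1, "nonsig_increase": 2,
                  "nonsig_decrease": 3, "sig_decrease": 4}
CATEGORY_NAMES = {v: k for k, v in CATEGORY_CODES.items()}
NODATA_CATEGORY = 0

DEFAULT_MIN_YEARS = 10
DEFAULT_ALPHA = 0.05
# symmetric |slope| bin edges, m2/m2 per year; configurable, right-open
DEFAULT_SLOPE_BINS = (0.002, 0.005, 0.010)


@dataclass
class TrendResult:
    """OLS slope, intercept and two-sided p-value for one pixel series."""

    slope: float
    intercept: float
    p_value: float
    n: int

    @property
    def is_nodata(self) -> bool:
        return not np.isfinite(self.slope)


def _ols_masked(x: np.ndarray, y: np.ndarray, w: np.ndarray, min_n: int):
    """Weighted-sums OLS of y on x along axis 0 with 0/1 weights.

    x has shape (n,) ; y, w have shape (n, ...).  Returns slope, intercept,
    p_value, n arrays; entries with fewer than ``min_n`` valid pairs are NaN.
    """
    w = w.astype(float)
    n = w.sum(axis=0)
    xb = np.einsum("i,i...->...", x, w) / np.maximum(n, 1)
    yb = np.nansum(y * w, axis=0) / np.maximum(n, 1)
    dx = x.reshape((-1,) + (1,) * (y.ndim - 1)) - xb
    dy = np.where(w > 0, y - yb, 0.0)
    sxx = np.sum(dx * dx * w, axis=0)
    sxy = np.sum(dx * dy * w, axis=0)
    syy = np.sum(dy * dy * w, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = sxy / sxx
        intercept = yb - slope * xb
        rss = np.maximum(syy - slope * sxy, 0.0)
        df = n - 2
        sigma2 = rss / np.maximum(df, 1)
        se = np.sqrt(sigma2 / sxx)
        tval = slope / se
    p = 2.0 * stats.t.sf(np.abs(tval), np.maximum(df, 1))
    # degenerate residuals: an exact constant has slope 0 -> p = 1 by
    # convention; an exact line has se 0 with nonzero slope -> p = 0
    exact = se == 0
    p = np.where(exact & (slope == 0), 1.0, p)
    p = np.where(exact & (slope != 0), 0.0, p)
    bad = (n < min_n) | (sxx <= 0)
    slope = np.where(bad, np.nan, slope)
    intercept = np.where(bad, np.nan, intercept)
    p = np.where(bad, np.nan, p)
    return slope, intercept, p, n.astype(int)


def fit_trend(years, values, min_years: int = DEFAULT_MIN_YEARS) -> TrendResult:
    """OLS trend of one series of yearly values.

    Constant series give slope 0 with p = 1; fewer than ``min_years``
    non-nodata pairs give a nodata result.
    """
    x = np.asarray(years, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.shape != y.shape:
        raise ValueError("years and values must have the same length")
    w = np.isfinite(y) & np.isfinite(x)
    slope, intercept, p, n = _ols_masked(x, np.where(w, y, 0.0), w, min_years)
    return TrendResult(float(slope), float(intercept), float(p), int(n))


def fit_trend_stack(stack: MonthlyStack, month: int,
                    min_years: int = DEFAULT_MIN_YEARS):
    """Per-pixel trend maps for one month: (slope, intercept, p_value, n)."""
    cube = stack.month_cube(month)
    x = stack.years.astype(float)
    w = np.isfinite(cube)
    return _ols_masked(x, np.where(w, cube, 0.0), w, min_years)


def classify_trend(slope, p_value, alpha: float = DEFAULT_ALPHA,
                   bins=DEFAULT_SLOPE_BINS):
    """Category code (1-4) and magnitude bin for slope/p maps or scalars.

    Significant requires p < alpha; increase/decrease by slope sign with an
    exact zero slope counted as (non-significant) increase.  Magnitude bins
    are right-open intervals over |slope|; a value on an edge falls in the
    higher bin.  Nodata slope gives category 0.
    """
    slope = np.asarray(slope, dtype=float)
    p_value = np.asarray(p_value, dtype=float)
    sig = p_value < alpha
    inc = slope >= 0
    cat = np.where(inc, np.where(sig, 1, 2), np.where(sig, 4, 3))
    cat = np.where(np.isfinite(slope) & np.isfinite(p_value), cat, NODATA_CATEGORY)
    mag = np.searchsorted(np.asarray(bins, dtype=float), np.abs(slope), side="right")
    mag = np.where(np.isfinite(slope), mag, -1)
    if cat.ndim == 0:
        return int(cat), int(mag)
    return cat.astype(np.int8), mag.astype(np.int8)


def summarize_trends(category: np.ndarray, slope: np.ndarray,
                     mask: VegetationMask, month: int) -> pd.DataFrame:
    """Vegetation-class area summary of a trend classification map.

    Returns one row per class x category with the percentage of the class's
    non-nodata pixels in that category; significant rows also carry the mean
    slope over those pixels in 1e-3 m2/m2 per year (``mean_sig_slope_e3``).
    """
    if category.shape != mask.grid.shape:
        raise ValueError("trend map and mask are on different grids")
    rows = []
    for cls in VEG_CLASSES:
        sel = mask.pixels_of(cls)
        cat = category[sel]
        slp = slope[sel]
        valid = cat != NODATA_CATEGORY
        total = int(valid.sum())
        if total == 0:
            warnings.warn(f"empty or all-nodata stratum {cls!r} for month {month}",
                          stacklevel=2)
        for name, code in CATEGORY_CODES.items():
            in_cat = valid & (cat == code)
            pct = 100.0 * in_cat.sum() / total if total else np.nan
            mean_e3 = np.nan
            if name in ("sig_increase", "sig_decrease") and in_cat.any():
                mean_e3 = float(np.nanmean(slp[in_cat])) * 1e3
            rows.append({"class": cls, "month": month, "category": name,
                         "pct": pct, "mean_sig_slope_e3": mean_e3})
    return pd.DataFrame(rows)
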