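"""Distributions and area-weighted means of selected preseason window lengths.

The "lag" of a pixel-month is the length (1-4 months, including the
response month) of the preseason window selected for a climate factor.
Statistics aggregate pixel x month cells within a vegetation class, over
configurable month groups of the growing season, and weight by pixel area
(constant for projected grids, cos(latitude) for geographic ones).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .attribution import AttributionMaps, FACTORS, WINDOW_LENGTHS
from .stack import VegetationMask, VEG_CLASSES

# month groups used in lag reporting
PERIODS = {
    "full": (4, 5, 6, 7, 8, 9, 10),
    "development": (4, 5, 6, 7, 8),
    "senescence": (9, 10),
    "early": (4, 5, 6, 7),
    "late": (8, 9, 10),
}


def _stratum_cells(monthly_maps: dict[int, AttributionMaps],
                   mask: VegetationMask, cls: str, factor: str, months):
    """Selected window lengths and area weights over a stratum's cells."""
    sel = mask.pixels_of(cls)
    areas = mask.grid.pixel_areas()
    ns, ws = [], []
    for m in months:
        if m not in monthly_maps:
            raise ValueError(f"attribution for month {m} not available")
        win = monthly_maps[m].factors[factor].best_window
        ok = sel & (win > 0)
        ns.append(win[ok].astype(float))
        ws.append(areas[ok])
    if not ns:
        return np.array([]), np.array([])
    return np.concatenate(ns), np.concatenate(ws)


def lag_distribution(monthly_maps: dict[int, AttributionMaps],
                     mask: VegetationMask, cls: str, factor: str,
                     months) -> dict[int, float]:
    """Percentage of stratum cells selecting each window length 1-4."""
    n, _ = _stratum_cells(monthly_maps, mask, cls, factor, months)
    if n.size == 0:
        return {k: np.nan for k in WINDOW_LENGTHS}
    return {k: 100.0 * np.sum(n == k) / n.size for k in WINDOW_LENGTHS}


def mean_lag(monthly_maps: dict[int, AttributionMaps],
             mask: VegetationMask, cls: str, factor: str, months) -> float:
    """Area-weighted mean selected window length, in months."""
    n, w = _stratum_cells(monthly_maps, mask, cls, factor, months)
    if n.size == 0:
        return np.nan
    return float(np.sum(w * n) / np.sum(w))


def summarize_lags(monthly_maps: dict[int, AttributionMaps],
                   mask: VegetationMask,
                   response_kind: str | None = None,
                   periods: dict | None = None) -> pd.DataFrame:
    """Lag table per class x factor x period.

    Columns: class, response, factor, period, pct_n1..pct_n4,
    mean_lag_months.  Percentages sum to 100 per row; with equal pixel
    areas ``mean_lag_months`` equals ``sum(pct_nk * k) / 100`` exactly.
    """
    if periods is None:
        periods = PERIODS
    if response_kind is None:
        any_map = next(iter(monthly_maps.values()))
        response_kind = any_map.response_kind
    available = set(monthly_maps)
    rows = []
    for cls in VEG_CLASSES:
        for factor in FACTORS:
            for period, months in periods.items():
                use = [m for m in months if m in available]
                if not use:
                    continue
                pct = lag_distribution(monthly_maps, mask, cls, factor, use)
                row = {"class": cls, "response": response_kind, "factor": factor,
                       "period": period}
                row.update({f"pct_n{k}": pct[k] for k in WINDOW_LENGTHS})
                row["mean_lag_months"] = mean_lag(monthly_maps, mask, cls,
                                                  factor, use)
                rows.append(row)
    return pd.DataFrame(rows)
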