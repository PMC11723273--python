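"""Monthly LAI increments (VLAI) and the growing-season stage partition.

VLAI(t) = LAI(t) - LAI(t-1) for consecutive calendar months of the same
year; positive values measure the rate of canopy development, negative
values the rate of senescence, and |VLAI| the speed of canopy change.

The growing season (April-October) is partitioned into three canopy
stages: development (April-June), maturity (July-August) and senescence
(September-October).
"""

from __future__ import annotations

import numpy as np

from .stack import MonthlyStack

ANALYSIS_MONTHS = tuple(range(4, 11))

STAGE_MONTHS = {
    "development": (4, 5, 6),
    "maturity": (7, 8),
    "senescence": (9, 10),
}


def stage_of(month: int) -> str:
    """Canopy stage of an analysis month (4-10)."""
    for stage, months in STAGE_MONTHS.items():
        if month in months:
            return stage
    raise ValueError(f"month {month} outside the growing season 4..10")


def compute_vlai(lai: MonthlyStack) -> MonthlyStack:
    """Difference consecutive monthly LAI into a VLAI stack (months 4-10).

    April's increment needs March LAI, so months 3..10 must be present for
    every analysis year.  VLAI(m) is nodata wherever LAI(m) or LAI(m-1) is.
    """
    if lai.variable != "LAI":
        raise ValueError(f"expected an LAI stack, got {lai.variable}")
    needed = range(3, 11)
    missing = [m for m in needed if m not in lai.months]
    if missing:
        raise ValueError(f"LAI stack lacks month(s) {missing}; March through "
                         "October are required to form April-October increments")
    idx = [lai.month_index(m) for m in needed]
    cube = lai.values[:, idx]                      # (years, 8, rows, cols)
    vlai = cube[:, 1:] - cube[:, :-1]              # nodata propagates as NaN
    return MonthlyStack(variable="VLAI", grid=lai.grid, years=lai.years.copy(),
                        months=np.arange(4, 11), values=vlai)


def seasonal_amplitudes(lai: MonthlyStack) -> tuple[np.ndarray, np.ndarray]:
    """Rising and falling LAI amplitudes per pixel-year.

    rising = LAI(July) - LAI(April); falling = LAI(July) - LAI(October).
    Both returned with shape (n_years, n_rows, n_cols).
    """
    missing = [m for m in (4, 7, 10) if m not in lai.months]
    if missing:
        raise ValueError(f"LAI stack lacks month(s) {missing} needed for amplitudes")
    apr = lai.month_cube(4)
    jul = lai.month_cube(7)
    octo = lai.month_cube(10)
    return jul - apr, jul - octo
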