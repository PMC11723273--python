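"""In-memory containers for monthly raster time series and vegetation masks.

A :class:`MonthlyStack` holds one variable (LAI, TEM, PRE or SRAD) as a dense
``(year, month, row, col)`` cube on a fixed :class:`~canopyshift.grid.GridSpec`.
Nodata cells are NaN in memory; the grid's sentinel value is applied only at
file I/O time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import GridSpec

VARIABLES = ("LAI", "VLAI", "TEM", "PRE", "SRAD")

CLASS_CODES = {"excluded": 0, "grassland": 1, "forest": 2, "farmland": 3}
CLASS_NAMES = {v: k for k, v in CLASS_CODES.items()}
VEG_CLASSES = ("grassland", "forest", "farmland")


@dataclass
class MonthlyStack:
    """A (year, month, row, col) cube of one variable on a fixed grid."""

    variable: str
    grid: GridSpec
    years: np.ndarray      # ordered calendar years, shape (n_years,)
    months: np.ndarray     # ordered month indices 1..12, shape (n_months,)
    values: np.ndarray     # float64, shape (n_years, n_months, n_rows, n_cols)

    def __post_init__(self) -> None:
        if self.variable not in VARIABLES:
            raise ValueError(f"unknown variable {self.variable!r}; expected one of {VARIABLES}")
        self.years = np.asarray(self.years, dtype=int)
        self.months = np.asarray(self.months, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.years) <= 0) or np.any(np.diff(self.months) <= 0):
            raise ValueError("years and months must be strictly ascending")
        if np.any((self.months < 1) | (self.months > 12)):
            raise ValueError("months must lie in 1..12")
        expected = (len(self.years), len(self.months), self.grid.n_rows, self.grid.n_cols)
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape} != expected {expected}")
        if self.variable == "LAI" and np.nanmin(self.values, initial=0.0) < 0:
            raise ValueError("LAI values must be nodata or >= 0")

    # -- indexing -----------------------------------------------------------

    def month_index(self, month: int) -> int:
        idx = np.flatnonzero(self.months == month)
        if idx.size == 0:
            raise KeyError(f"month {month} not present in {self.variable} stack")
        return int(idx[0])

    def year_index(self, year: int) -> int:
        idx = np.flatnonzero(self.years == year)
        if idx.size == 0:
            raise KeyError(f"year {year} not present in {self.variable} stack")
        return int(idx[0])

    def plane(self, year: int, month: int) -> np.ndarray:
        """The (row, col) plane for one calendar (year, month)."""
        return self.values[self.year_index(year), self.month_index(month)]

    def month_cube(self, month: int) -> np.ndarray:
        """All years of one month, shape (n_years, n_rows, n_cols)."""
        return self.values[:, self.month_index(month)]

    def has_months(self, months) -> bool:
        return np.all(np.isin(list(months), self.months))

    def require_same_grid(self, other: "MonthlyStack") -> None:
        if not self.grid.same_geometry(other.grid):
            raise ValueError(
                f"{self.variable} and {other.variable} stacks are on different grids; "
                "resample to a common grid first")


@dataclass
class VegetationMask:
    """Per-pixel vegetation class, restricted to stable land cover.

    ``labels`` holds the integer codes of :data:`CLASS_CODES`
    (0 = excluded, 1 = grassland, 2 = forest, 3 = farmland).
    """

    grid: GridSpec
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")
        if not np.all(np.isin(self.labels, list(CLASS_CODES.values()))):
            raise ValueError("mask contains unknown class codes")

    def pixels_of(self, cls: str) -> np.ndarray:
        """Boolean (row, col) selector for one vegetation class."""
        return self.labels == CLASS_CODES[cls]

    def class_counts(self) -> dict[str, int]:
        return {name: int(np.sum(self.labels == code))
                for name, code in CLASS_CODES.items()}
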