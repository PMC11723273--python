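"""Common raster grid definition.

All stages of the pipeline operate on a single master grid; two stacks may
be combined only when their :class:`GridSpec` objects are identical.  The
geotransform uses the GDAL convention ``(x0, dx, rx, y0, ry, dy)`` mapping
pixel (row, col) centres to map coordinates::

    x = x0 + (col + 0.5) * dx + (row + 0.5) * rx
    y = y0 + (col + 0.5) * ry + (row + 0.5) * dy

Rotated grids (``rx`` or ``ry`` nonzero) are rejected: nothing in this
pipeline needs them and the in-house resampler assumes axis alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """Shape, affine georeferencing and nodata sentinel of a raster grid."""

    n_rows: int
    n_cols: int
    geotransform: tuple[float, float, float, float, float, float] = (
        0.0, 1.0, 0.0, 0.0, 0.0, -1.0)
    crs: str = "local"
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        gt = tuple(float(v) for v in self.geotransform)
        if len(gt) != 6:
            raise ValueError("geotransform must have 6 coefficients")
        if gt[1] == 0.0 or gt[5] == 0.0:
            raise ValueError("pixel width and height must be nonzero")
        if gt[2] != 0.0 or gt[4] != 0.0:
            raise ValueError("rotated grids are not supported")
        object.__setattr__(self, "geotransform", gt)

    # -- coordinate helpers -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def x_centers(self) -> np.ndarray:
        x0, dx = self.geotransform[0], self.geotransform[1]
        return x0 + (np.arange(self.n_cols) + 0.5) * dx

    def y_centers(self) -> np.ndarray:
        y0, dy = self.geotransform[3], self.geotransform[5]
        return y0 + (np.arange(self.n_rows) + 0.5) * dy

    def is_geographic(self) -> bool:
        crs = self.crs.lower()
        return "4326" in crs or "wgs84" in crs or "geographic" in crs

    def pixel_areas(self) -> np.ndarray:
        """Per-pixel relative area weights, shape ``(n_rows, n_cols)``.

        Projected grids are treated as equal-area; geographic grids weight
        each row by the cosine of its centre latitude.
        """
        if not self.is_geographic():
            return np.ones(self.shape)
        w = np.cos(np.deg2rad(self.y_centers()))
        return np.repeat(w[:, None], self.n_cols, axis=1)

    def same_geometry(self, other: "GridSpec") -> bool:
        return (self.n_rows == other.n_rows and self.n_cols == other.n_cols
                and np.allclose(self.geotransform, other.geotransform)
                and self.crs == other.crs)
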