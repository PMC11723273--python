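"""Raster time-series input/output, alignment and masking.

Everything downstream of this module works on one master grid and one
vegetation mask.  Rasters are exchanged as multi-page TIFF (one page per
calendar (year, month) plane, georeferencing and band mapping stored as JSON
in the ImageDescription tag) or as NetCDF files with a ``(time, y, x)``
layout and a CF-style time coordinate.

Nodata is the grid's sentinel value on disk and NaN in memory; resampling
never fabricates values where the source window is entirely nodata.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import numpy as np
import tifffile

from .grid import DEFAULT_NODATA, GridSpec
from .stack import CLASS_CODES, MonthlyStack, VegetationMask

log = logging.getLogger(__name__)

RESAMPLE_METHODS = ("bilinear", "nearest", "mode")


# ---------------------------------------------------------------------------
# read / write
# ---------------------------------------------------------------------------

def write_stack(stack: MonthlyStack, path: str | Path) -> Path:
    """Write a stack as multi-page float64 TIFF with JSON metadata.

    The written file round-trips bit-exactly through :func:`read_stack`.
    """
    path = Path(path)
    bands = []
    pages = []
    for iy, year in enumerate(stack.years):
        for im, month in enumerate(stack.months):
            plane = stack.values[iy, im].astype(np.float64).copy()
            plane[~np.isfinite(plane)] = stack.grid.nodata
            pages.append(plane)
            bands.append([int(year), int(month)])
    meta = {
        "variable": stack.variable,
        "bands": bands,
        "geotransform": list(stack.grid.geotransform),
        "crs": stack.grid.crs,
        "nodata": stack.grid.nodata,
    }
    tifffile.imwrite(path, np.stack(pages), description=json.dumps(meta),
                     photometric="minisblack")
    return path


def _grid_from_meta(meta: Mapping, shape: tuple[int, int]) -> GridSpec:
    return GridSpec(n_rows=shape[0], n_cols=shape[1],
                    geotransform=tuple(meta.get("geotransform", (0, 1, 0, 0, 0, -1))),
                    crs=str(meta.get("crs", "local")),
                    nodata=float(meta.get("nodata", DEFAULT_NODATA)))


def _read_tiff_planes(path: Path, band_map=None):
    """Yield ((year, month), plane, grid) triples from one TIFF file."""
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        desc = tf.pages[0].description or "{}"
    try:
        meta = json.loads(desc)
    except json.JSONDecodeError:
        meta = {}
    if arr.ndim == 2:
        arr = arr[None]
    n_bands = arr.shape[0]
    if band_map is not None:
        mapping = [tuple(band_map[b]) if b in band_map else None
                   for b in range(n_bands)]
        missing = [b for b, m in enumerate(mapping) if m is None]
        if missing:
            raise ValueError(
                f"band mapping for {path} omits band(s) {missing} "
                f"(file has {n_bands} band(s))")
    else:
        bands = meta.get("bands")
        if bands is None or len(bands) != n_bands:
            raise ValueError(
                f"{path} has no embedded band->(year,month) mapping; "
                "pass band_maps explicitly")
        mapping = [tuple(b) for b in bands]
    grid = _grid_from_meta(meta, arr.shape[1:])
    nodata = grid.nodata
    for b, ym in enumerate(mapping):
        plane = arr[b].astype(np.float64)
        plane[plane == nodata] = np.nan
        yield ym, plane, grid


def _read_netcdf_planes(path: Path, variable_hint=None):
    import xarray as xr

    ds = xr.open_dataset(path, engine="scipy")
    try:
        names = [n for n in ds.data_vars if ds[n].ndim == 3]
        if not names:
            raise ValueError(f"{path} has no 3-D (time, y, x) variable")
        name = variable_hint if variable_hint in names else names[0]
        da = ds[name]
        tdim = da.dims[0]
        times = ds[tdim].values
        nodata = float(da.attrs.get("nodata", da.attrs.get("_FillValue", DEFAULT_NODATA)))
        gt = da.attrs.get("geotransform", (0, 1, 0, 0, 0, -1))
        grid = GridSpec(n_rows=da.shape[1], n_cols=da.shape[2],
                        geotransform=tuple(float(v) for v in gt),
                        crs=str(da.attrs.get("crs", "local")), nodata=nodata)
        for i, t in enumerate(times):
            ts = _as_datetime(t)
            plane = np.asarray(da.values[i], dtype=np.float64)
            plane[plane == nodata] = np.nan
            yield (ts.year, ts.month), plane, grid
    finally:
        ds.close()


def _as_datetime(value) -> _dt.datetime:
    if isinstance(value, np.datetime64):
        us = value.astype("datetime64[us]").astype("int64")
        return _dt.datetime(1970, 1, 1) + _dt.timedelta(microseconds=int(us))
    if isinstance(value, (_dt.datetime, _dt.date)):
        return _dt.datetime(value.year, value.month, getattr(value, "day", 1))
    raise TypeError(f"unsupported time coordinate type {type(value)!r}")


def read_stack(paths: Sequence[str | Path] | str | Path,
               variable: str,
               band_maps: Mapping[str | Path, Mapping[int, tuple[int, int]]] | None = None,
               ) -> MonthlyStack:
    """Read one variable from TIFF/NetCDF files into a :class:`MonthlyStack`.

    Parameters
    ----------
    paths
        One path or a list of paths; all files must share a grid and CRS.
    variable
        Variable name the stack carries (LAI, VLAI, TEM, PRE or SRAD).
    band_maps
        Optional per-file ``{band_index: (year, month)}`` mapping for TIFFs
        without embedded metadata.  Every band of every file must be covered
        exactly once.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    planes: dict[tuple[int, int], np.ndarray] = {}
    grid: GridSpec | None = None
    for p in paths:
        p = Path(p)
        bm = None if band_maps is None else band_maps.get(p, band_maps.get(str(p)))
        if p.suffix.lower() in (".nc", ".cdf", ".netcdf"):
            it = _read_netcdf_planes(p, variable_hint=variable)
        else:
            it = _read_tiff_planes(p, band_map=bm)
        for ym, plane, g in it:
            if grid is None:
                grid = g
            elif not grid.same_geometry(g):
                raise ValueError(
                    f"{p} is on a different grid than earlier files; "
                    "use resample_to_grid to align stacks first")
            if ym in planes:
                raise ValueError(f"(year, month) {ym} mapped more than once")
            planes[ym] = plane
    if not planes:
        raise ValueError("no raster planes read")
    years = np.array(sorted({y for y, _ in planes}))
    months = np.array(sorted({m for _, m in planes}))
    cube = np.full((len(years), len(months), grid.n_rows, grid.n_cols), np.nan)
    for (y, m), plane in planes.items():
        cube[np.searchsorted(years, y), np.searchsorted(months, m)] = plane
    return MonthlyStack(variable=variable, grid=grid, years=years,
                        months=months, values=cube)


# ---------------------------------------------------------------------------
# 8-day -> monthly aggregation
# ---------------------------------------------------------------------------

def aggregate_8day_to_monthly(composites: Sequence[tuple[_dt.date, np.ndarray]],
                              year: int,
                              grid: GridSpec,
                              variable: str = "LAI",
                              rule: str = "mean") -> MonthlyStack:
    """Aggregate 8-day composites into monthly planes for one year.

    Each composite is assigned to the month containing its start date; a
    month's value per pixel is the arithmetic mean (or, with ``rule="max"``,
    the maximum) over its composites, ignoring nodata.  Months with no
    contributing composite, or only nodata contributions at a pixel, are
    nodata.
    """
    if not composites:
        raise ValueError("empty composite list")
    if rule not in ("mean", "max"):
        raise ValueError(f"unknown aggregation rule {rule!r}")
    by_month: dict[int, list[np.ndarray]] = {}
    for start, arr in composites:
        if start.year != year:
            raise ValueError(f"composite start date {start} not within {year}")
        arr = np.asarray(arr, dtype=float)
        if arr.shape != grid.shape:
            raise ValueError("composite shape does not match grid")
        by_month.setdefault(start.month, []).append(arr)
    months = np.array(sorted(by_month))
    cube = np.full((1, len(months), grid.n_rows, grid.n_cols), np.nan)
    with np.errstate(invalid="ignore"):
        for i, m in enumerate(months):
            block = np.stack(by_month[m])
            agg = np.nanmean(block, axis=0) if rule == "mean" else np.nanmax(block, axis=0)
            cube[0, i] = agg
    return MonthlyStack(variable=variable, grid=grid,
                        years=np.array([year]), months=months, values=cube)


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def _source_fractional_indices(source: GridSpec, target: GridSpec):
    """Fractional (row, col) indices of the source grid at target pixel centres."""
    sx0, sdx, _, sy0, _, sdy = source.geotransform
    cols = (target.x_centers() - sx0) / sdx - 0.5
    rows = (target.y_centers() - sy0) / sdy - 0.5
    return rows, cols


def _resample_plane_bilinear(plane, source, target):
    rows, cols = _source_fractional_indices(source, target)
    r0 = np.floor(rows).astype(int)
    c0 = np.floor(cols).astype(int)
    fr = rows - r0
    fc = cols - c0
    out = np.zeros((target.n_rows, target.n_cols))
    wsum = np.zeros_like(out)
    for dr, wr in ((0, 1 - fr), (1, fr)):
        rr = np.clip(r0 + dr, 0, source.n_rows - 1)
        inside_r = (r0 + dr >= 0) & (r0 + dr <= source.n_rows - 1)
        # nearest-edge clamp keeps constant fields constant at the margins
        rr = np.where((r0 + dr < 0) | (r0 + dr > source.n_rows - 1),
                      np.clip(r0 + dr, 0, source.n_rows - 1), rr)
        for dc, wc in ((0, 1 - fc), (1, fc)):
            cc = np.clip(c0 + dc, 0, source.n_cols - 1)
            vals = plane[np.ix_(rr, cc)]
            w = np.outer(wr, wc)
            ok = np.isfinite(vals)
            out += np.where(ok, vals, 0.0) * w * ok
            wsum += w * ok
    with np.errstate(invalid="ignore", divide="ignore"):
        res = out / wsum
    res[wsum <= 0] = np.nan
    return res


def _resample_plane_nearest(plane, source, target):
    rows, cols = _source_fractional_indices(source, target)
    rr = np.clip(np.rint(rows).astype(int), 0, source.n_rows - 1)
    cc = np.clip(np.rint(cols).astype(int), 0, source.n_cols - 1)
    return plane[np.ix_(rr, cc)]


def _cell_edges(origin, step, n):
    edges = origin + step * np.arange(n + 1)
    return edges


def _resample_plane_mode(plane, source, target):
    """Majority resampling for categorical planes; ties -> smallest code."""
    sx0, sdx, _, sy0, _, sdy = source.geotransform
    tx0, tdx, _, ty0, _, tdy = target.geotransform
    xe = _cell_edges(tx0, tdx, target.n_cols)
    ye = _cell_edges(ty0, tdy, target.n_rows)
    out = np.full((target.n_rows, target.n_cols), np.nan)
    eps = 1e-9
    for i in range(target.n_rows):
        ylo, yhi = sorted((ye[i], ye[i + 1]))
        # source rows whose centres fall inside [ylo, yhi)
        r_f = (np.array([ylo, yhi]) - sy0) / sdy - 0.5
        r_lo, r_hi = sorted(r_f)
        ri0 = max(int(np.ceil(r_lo - eps)), 0)
        ri1 = min(int(np.floor(r_hi + eps)), source.n_rows - 1)
        if ri1 < ri0:   # target cell smaller than a source cell: use nearest
            yc = (ye[i] + ye[i + 1]) / 2.0
            ri0 = ri1 = int(np.clip(np.rint((yc - sy0) / sdy - 0.5), 0,
                                    source.n_rows - 1))
        for j in range(target.n_cols):
            xlo, xhi = sorted((xe[j], xe[j + 1]))
            c_f = (np.array([xlo, xhi]) - sx0) / sdx - 0.5
            c_lo, c_hi = sorted(c_f)
            ci0 = max(int(np.ceil(c_lo - eps)), 0)
            ci1 = min(int(np.floor(c_hi + eps)), source.n_cols - 1)
            if ci1 < ci0:
                xc = (xe[j] + xe[j + 1]) / 2.0
                ci0 = ci1 = int(np.clip(np.rint((xc - sx0) / sdx - 0.5), 0,
                                        source.n_cols - 1))
            window = plane[ri0:ri1 + 1, ci0:ci1 + 1].ravel()
            window = window[np.isfinite(window)]
            if window.size == 0:
                continue
            codes = window.astype(np.int64)
            counts = np.bincount(codes - codes.min())
            out[i, j] = codes.min() + int(np.argmax(counts))
    return out


def resample_to_grid(stack: MonthlyStack, target: GridSpec,
                     method: str = "bilinear") -> MonthlyStack:
    """Warp a stack onto ``target``.

    ``bilinear`` for continuous variables, ``nearest``/``mode`` for
    categorical ones.  Identical source and target grids return the values
    unchanged; windows containing only nodata stay nodata.
    """
    if method not in RESAMPLE_METHODS:
        raise ValueError(f"unknown resampling method {method!r}; "
                         f"expected one of {RESAMPLE_METHODS}")
    if stack.grid.same_geometry(target):
        return MonthlyStack(stack.variable, target, stack.years.copy(),
                            stack.months.copy(), stack.values.copy())
    fn = {"bilinear": _resample_plane_bilinear,
          "nearest": _resample_plane_nearest,
          "mode": _resample_plane_mode}[method]
    out = np.full((len(stack.years), len(stack.months),
                   target.n_rows, target.n_cols), np.nan)
    for iy in range(len(stack.years)):
        for im in range(len(stack.months)):
            out[iy, im] = fn(stack.values[iy, im], stack.grid, target)
    return MonthlyStack(stack.variable, target, stack.years.copy(),
                        stack.months.copy(), out)


# ---------------------------------------------------------------------------
# land-cover stability mask
# ---------------------------------------------------------------------------

def build_stability_mask(landcover_series: Iterable[np.ndarray],
                         class_map: Mapping[int, str],
                         grid: GridSpec) -> VegetationMask:
    """Label pixels whose vegetation class never changed over the series.

    A pixel gets a class iff ``class_map`` sends its raw code to that same
    class (grassland, forest or farmland) in *every* year; any change of
    class, or any unmapped code, excludes the pixel.  Unmapped codes are
    counted in a log summary.
    """
    for name in class_map.values():
        if name not in ("grassland", "forest", "farmland"):
            raise ValueError(f"class_map targets unknown class {name!r}")
    labels = None
    unmapped: dict[int, int] = {}
    n_years = 0
    for raw in landcover_series:
        raw = np.asarray(raw)
        if raw.shape != grid.shape:
            raise ValueError("land-cover raster shape does not match grid")
        n_years += 1
        year_lab = np.zeros(grid.shape, dtype=np.int8)
        for code in np.unique(raw[np.isfinite(raw.astype(float))]):
            code_i = int(code)
            cls = class_map.get(code_i)
            if cls is None:
                unmapped[code_i] = unmapped.get(code_i, 0) + int(np.sum(raw == code))
            else:
                year_lab[raw == code] = CLASS_CODES[cls]
        if labels is None:
            labels = year_lab
        else:
            labels = np.where(labels == year_lab, labels, 0).astype(np.int8)
    if labels is None:
        raise ValueError("empty land-cover series")
    labels[labels == 0] = 0
    if unmapped:
        log.info("stability mask: %d unmapped land-cover codes excluded: %s",
                 len(unmapped), unmapped)
    mask = VegetationMask(grid=grid, labels=labels)
    log.info("stability mask over %d years: %s", n_years, mask.class_counts())
    return mask


def write_mask(mask: VegetationMask, path: str | Path) -> Path:
    path = Path(path)
    meta = {"variable": "mask", "classes": CLASS_CODES,
            "geotransform": list(mask.grid.geotransform),
            "crs": mask.grid.crs, "nodata": 0}
    tifffile.imwrite(path, mask.labels.astype(np.int16),
                     description=json.dumps(meta), photometric="minisblack")
    return path


def read_mask(path: str | Path) -> VegetationMask:
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        meta = json.loads(tf.pages[0].description or "{}")
    grid = _grid_from_meta(meta, arr.shape)
    return VegetationMask(grid=grid, labels=arr.astype(np.int8))
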