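"""Preseason window selection and partial-correlation climate attribution.

For each pixel, analysis month and climate factor (TEM, PRE, SRAD) the
procedure:

1. builds candidate preseason series: yearly means of the factor over
   windows of length 1-4 months ending at (and including) the response
   month — length 1 is the month itself, length 4 reaches three months
   back;
2. selects the window whose yearly means have the strongest simple Pearson
   correlation (largest |r|) with the response (LAI or VLAI at that month),
   ties broken toward the shorter window;
3. computes the second-order partial correlation between the response and
   the factor at its selected window, controlling the other two factors at
   their own selected windows, with a two-sided t-test on n - 4 degrees of
   freedom;
4. classifies the pixel into one of eight factor-combination categories
   (No, TEM, PRE, SRAD, TEM+PRE, TEM+SRAD, PRE+SRAD, TEM+PRE+SRAD) from
   which factors are significant at alpha.

All statistics at a pixel-month use one common set of years: any year with
nodata in the response or any candidate window mean is dropped for that
pixel-month, so the selected window and the partial correlation are
computed on identical samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .stack import MonthlyStack, VegetationMask, VEG_CLASSES

FACTORS = ("TEM", "PRE", "SRAD")
WINDOW_LENGTHS = (1, 2, 3, 4)
DEFAULT_ALPHA = 0.05
DEFAULT_MIN_YEARS = 10

COMBO_ORDER = ("No", "TEM", "PRE", "SRAD", "TEM+PRE", "TEM+SRAD",
               "PRE+SRAD", "TEM+PRE+SRAD")
# significance bitmask (TEM=1, PRE=2, SRAD=4) -> combo code in COMBO_ORDER
_BITS_TO_CODE = np.array([0, 1, 2, 4, 3, 5, 6, 7], dtype=np.int8)
COMBO_NODATA = -1


# ---------------------------------------------------------------------------
# preseason series
# ---------------------------------------------------------------------------

def preseason_series(climate: MonthlyStack, target_month: int, n: int,
                     pixel: tuple[int, int] | None = None) -> np.ndarray:
    """Yearly mean of a climate factor over the n-month window ending at
    ``target_month`` (window includes the target month).

    Returns shape (n_years, n_rows, n_cols), or (n_years,) when ``pixel``
    is given.
    """
    if n not in WINDOW_LENGTHS:
        raise ValueError(f"window length must be in {WINDOW_LENGTHS}, got {n}")
    months = range(target_month - n + 1, target_month + 1)
    if target_month - n + 1 < 1:
        raise ValueError(f"window of length {n} ending at month {target_month} "
                         "reaches before January")
    missing = [m for m in months if m not in climate.months]
    if missing:
        raise ValueError(f"{climate.variable} stack lacks month(s) {missing} "
                         f"needed for the {n}-month window ending at {target_month}")
    cube = np.mean([climate.month_cube(m) for m in months], axis=0)
    if pixel is not None:
        return cube[:, pixel[0], pixel[1]]
    return cube


def _candidate_cube(climate: MonthlyStack, target_month: int,
                    lengths=WINDOW_LENGTHS) -> np.ndarray:
    """Stack of candidate window means, shape (n_windows, years, rows, cols)."""
    return np.stack([preseason_series(climate, target_month, n) for n in lengths])


# ---------------------------------------------------------------------------
# correlation primitives
# ---------------------------------------------------------------------------

def _masked_corr(a: np.ndarray, b: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Pearson correlation along axis 0 using a common 0/1 year mask."""
    n = w.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        am = np.sum(a * w, axis=0) / n
        bm = np.sum(b * w, axis=0) / n
        da = (a - am) * w
        db = (b - bm) * w
        cov = np.sum(da * db, axis=0)
        va = np.sum(da * da, axis=0)
        vb = np.sum(db * db, axis=0)
        r = cov / np.sqrt(va * vb)
    r = np.where((va > 0) & (vb > 0), r, np.nan)
    return np.clip(r, -1.0, 1.0)


def select_best_window(response: np.ndarray, candidates,
                       min_years: int = DEFAULT_MIN_YEARS) -> tuple[int, float]:
    """Pick the candidate preseason series with the largest |Pearson r|.

    ``candidates`` is a sequence of yearly series ordered by window length
    (1..len).  Ties go to the shorter window.  Returns (length, r); all
    candidates degenerate (zero variance or too few paired years) returns
    (0, nan).
    """
    y = np.asarray(response, dtype=float)
    best_n, best_r = 0, np.nan
    for i, cand in enumerate(candidates):
        c = np.asarray(cand, dtype=float)
        w = (np.isfinite(y) & np.isfinite(c)).astype(float)
        if w.sum() < max(min_years, 3):
            continue
        r = float(_masked_corr(y[:, None], c[:, None], w[:, None])[0])
        if np.isnan(r):
            continue
        if np.isnan(best_r) or abs(r) > abs(best_r):
            best_n, best_r = i + 1, r
    return best_n, best_r


def _first_order_partial(r_ab, r_ac, r_bc):
    with np.errstate(divide="ignore", invalid="ignore"):
        den = np.sqrt((1.0 - r_ac**2) * (1.0 - r_bc**2))
        out = (r_ab - r_ac * r_bc) / den
    return np.where(den > 0, out, np.nan)


def _second_order_partial(R: np.ndarray, iy: int, ix: int, ic1: int, ic2: int):
    """Second-order partial correlation from a stacked correlation matrix.

    ``R`` has shape (..., k, k).  Conditions on c1 first, then c2, via the
    standard recursion; the result is order-invariant.
    """
    r_yx_c1 = _first_order_partial(R[..., iy, ix], R[..., iy, ic1], R[..., ix, ic1])
    r_yc2_c1 = _first_order_partial(R[..., iy, ic2], R[..., iy, ic1], R[..., ic2, ic1])
    r_xc2_c1 = _first_order_partial(R[..., ix, ic2], R[..., ix, ic1], R[..., ic2, ic1])
    out = _first_order_partial(r_yx_c1, r_yc2_c1, r_xc2_c1)
    return np.clip(out, -1.0, 1.0)


def partial_correlation(y, x, controls,
                        min_years: int = DEFAULT_MIN_YEARS) -> tuple[float, float]:
    """Partial correlation of y with x given control series, with p-value.

    Second-order for two controls (first-order for one).  Years with nodata
    in any series are dropped.  The p-value is two-sided from
    ``t = r * sqrt((n - 2 - g) / (1 - r^2))`` with g controls and n - 2 - g
    degrees of freedom; |r| = 1 gives p = 0.
    """
    series = [np.asarray(y, float), np.asarray(x, float)] + \
             [np.asarray(c, float) for c in controls]
    g = len(series) - 2
    if g not in (1, 2):
        raise ValueError("one or two control series required")
    data = np.stack(series)                        # (k, n)
    ok = np.all(np.isfinite(data), axis=0)
    n = int(ok.sum())
    if n < max(min_years, g + 4):
        return np.nan, np.nan
    data = np.where(ok, data, 0.0)                 # masked entries must not be NaN
    k = data.shape[0]
    R = np.empty((k, k))
    for i in range(k):
        for j in range(k):
            R[i, j] = _masked_corr(data[i][:, None], data[j][:, None],
                                   ok.astype(float)[:, None])[0]
    if np.isnan(R[0, 1]):
        return np.nan, np.nan
    if g == 1:
        r = float(_first_order_partial(R[0, 1], R[0, 2], R[1, 2]))
    else:
        r = float(_second_order_partial(R, 0, 1, 2, 3))
    if np.isnan(r):
        return np.nan, np.nan
    r = float(np.clip(r, -1.0, 1.0))
    return r, _partial_p(r, n, g)


def _partial_p(r, n, g):
    """Two-sided p for a partial correlation on n samples with g controls."""
    df = np.asarray(n - 2 - g, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - np.asarray(r) ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1))
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    p = np.where(df < 1, np.nan, p)
    if np.ndim(p) == 0:
        return float(p)
    return p


# ---------------------------------------------------------------------------
# per-month attribution over a whole grid
# ---------------------------------------------------------------------------

@dataclass
class FactorMaps:
    """Per-pixel attribution maps for one factor at one response month."""

    best_window: np.ndarray    # int, 0 = nodata
    simple_r: np.ndarray
    partial_r: np.ndarray
    p_value: np.ndarray


@dataclass
class AttributionMaps:
    """Attribution of one response month over the grid."""

    response_kind: str         # "LAI" or "VLAI"
    target_month: int
    alpha: float
    factors: dict[str, FactorMaps]
    combo: np.ndarray          # int8 codes into COMBO_ORDER, -1 = nodata
    n_years: np.ndarray


def attribute_month(response_cube: np.ndarray,
                    climate: dict[str, MonthlyStack],
                    target_month: int,
                    response_kind: str = "VLAI",
                    alpha: float = DEFAULT_ALPHA,
                    min_years: int = DEFAULT_MIN_YEARS,
                    lengths=WINDOW_LENGTHS,
                    order: int = 2) -> AttributionMaps:
    """Vectorised attribution of one month's response over all pixels.

    ``response_cube`` has shape (n_years, n_rows, n_cols) aligned with the
    climate stacks' years.  ``order=2`` controls both other factors
    simultaneously (the default); ``order=1`` conditions on only the first
    other factor and is exposed for sensitivity checks.
    """
    n_years_total, n_rows, n_cols = response_cube.shape
    P = n_rows * n_cols
    y = response_cube.reshape(n_years_total, P)
    cands = {f: _candidate_cube(climate[f], target_month, lengths)
                  .reshape(len(lengths), n_years_total, P)
             for f in FACTORS}

    valid = np.isfinite(y)
    for f in FACTORS:
        valid &= np.all(np.isfinite(cands[f]), axis=0)
    w = valid.astype(float)
    n = valid.sum(axis=0)
    usable = n >= max(min_years, 6)

    yz = np.where(valid, y, 0.0)
    sel = {}
    chosen = np.empty((4, n_years_total, P))      # row 0 = response
    chosen[0] = yz
    simple_r = {}
    for k, f in enumerate(FACTORS):
        r_all = np.stack([_masked_corr(yz, np.where(valid, cands[f][i], 0.0), w)
                          for i in range(len(lengths))])     # (n_windows, P)
        absr = np.where(np.isnan(r_all), -np.inf, np.abs(r_all))
        idx = np.argmax(absr, axis=0)             # first max -> shortest window
        all_bad = ~np.isfinite(absr).any(axis=0) | np.all(absr == -np.inf, axis=0)
        sel[f] = np.where(all_bad, 0, np.asarray(lengths)[idx]).astype(np.int8)
        simple_r[f] = np.take_along_axis(r_all, idx[None, :], axis=0)[0]
        picked = np.take_along_axis(cands[f], idx[None, None, :], axis=0)[0]
        chosen[k + 1] = np.where(valid, picked, 0.0)

    # pairwise correlation matrix among response + three chosen series
    R = np.empty((P, 4, 4))
    for i in range(4):
        R[:, i, i] = 1.0
        for j in range(i + 1, 4):
            rij = _masked_corr(chosen[i], chosen[j], w)
            R[:, i, j] = rij
            R[:, j, i] = rij

    factors = {}
    sig_bits = np.zeros(P, dtype=np.int8)
    any_bad = ~usable
    controls = {"TEM": (2, 3), "PRE": (1, 3), "SRAD": (1, 2)}
    for k, f in enumerate(FACTORS):
        ix = k + 1
        ic1, ic2 = controls[f]
        if order == 2:
            pr = _second_order_partial(R, 0, ix, ic1, ic2)
        else:
            pr = _first_order_partial(R[:, 0, ix], R[:, 0, ic1], R[:, ix, ic1])
            pr = np.clip(pr, -1.0, 1.0)
        g = 2 if order == 2 else 1
        pv = _partial_p(pr, n, g)
        pr = np.where(usable, pr, np.nan)
        pv = np.where(usable, pv, np.nan)
        bad = ~np.isfinite(pr)
        any_bad |= bad
        sig_bits |= ((np.nan_to_num(pv, nan=1.0) < alpha) << k).astype(np.int8)
        factors[f] = FactorMaps(
            best_window=np.where(bad, 0, sel[f]).reshape(n_rows, n_cols),
            simple_r=np.where(bad, np.nan, simple_r[f]).reshape(n_rows, n_cols),
            partial_r=pr.reshape(n_rows, n_cols),
            p_value=pv.reshape(n_rows, n_cols))

    combo = _BITS_TO_CODE[sig_bits]
    combo = np.where(any_bad, COMBO_NODATA, combo).astype(np.int8)
    return AttributionMaps(response_kind=response_kind, target_month=target_month,
                           alpha=alpha, factors=factors,
                           combo=combo.reshape(n_rows, n_cols),
                           n_years=n.reshape(n_rows, n_cols))


@dataclass
class PixelAttribution:
    """Attribution of one pixel-month (scalar view of AttributionMaps)."""

    best_window: dict[str, int]
    simple_r: dict[str, float]
    partial_r: dict[str, float]
    p_value: dict[str, float]
    combo_class: str


def attribute_pixel(response: np.ndarray, climate: dict[str, MonthlyStack],
                    pixel: tuple[int, int], target_month: int,
                    response_kind: str = "VLAI",
                    alpha: float = DEFAULT_ALPHA,
                    min_years: int = DEFAULT_MIN_YEARS) -> PixelAttribution:
    """Attribution of a single pixel; ``response`` is its yearly series."""
    r, c = pixel
    cube = np.asarray(response, dtype=float)[:, None, None]
    sub = {f: MonthlyStack(variable=f, grid=_single_pixel_grid(climate[f]),
                           years=climate[f].years.copy(),
                           months=climate[f].months.copy(),
                           values=climate[f].values[:, :, r:r + 1, c:c + 1])
           for f in FACTORS}
    maps = attribute_month(cube, sub, target_month, response_kind=response_kind,
                           alpha=alpha, min_years=min_years)
    code = int(maps.combo[0, 0])
    return PixelAttribution(
        best_window={f: int(maps.factors[f].best_window[0, 0]) for f in FACTORS},
        simple_r={f: float(maps.factors[f].simple_r[0, 0]) for f in FACTORS},
        partial_r={f: float(maps.factors[f].partial_r[0, 0]) for f in FACTORS},
        p_value={f: float(maps.factors[f].p_value[0, 0]) for f in FACTORS},
        combo_class=COMBO_ORDER[code] if code >= 0 else "nodata")


def _single_pixel_grid(stack: MonthlyStack):
    from .grid import GridSpec
    g = stack.grid
    return GridSpec(n_rows=1, n_cols=1, geotransform=g.geotransform,
                    crs=g.crs, nodata=g.nodata)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def summarize_attribution(maps: AttributionMaps, mask: VegetationMask,
                          include_all: bool = True
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Signed-area and combo-class percentages per vegetation class.

    Returns ``(factor_df, combo_df)``.  ``factor_df`` has, per class and
    factor, the percentage of non-nodata pixels with significant positive /
    significant negative / any positive / any negative partial correlation.
    ``combo_df`` has the eight factor-combination percentages (summing to
    100 per class).
    """
    if maps.combo.shape != mask.grid.shape:
        raise ValueError("attribution maps and mask are on different grids")
    strata = [(cls, mask.pixels_of(cls)) for cls in VEG_CLASSES]
    if include_all:
        strata.append(("all", mask.labels > 0))
    frows, crows = [], []
    for cls, sel in strata:
        valid = sel & (maps.combo != COMBO_NODATA)
        total = int(valid.sum())
        for f in FACTORS:
            pr = maps.factors[f].partial_r[valid]
            pv = maps.factors[f].p_value[valid]
            sig = pv < maps.alpha
            row = {"class": cls, "month": maps.target_month,
                   "response": maps.response_kind, "factor": f, "n_pixels": total}
            if total == 0:
                row.update({k: np.nan for k in
                            ("pct_sig_pos", "pct_sig_neg", "pct_pos", "pct_neg")})
            else:
                row.update({
                    "pct_sig_pos": 100.0 * np.sum(sig & (pr > 0)) / total,
                    "pct_sig_neg": 100.0 * np.sum(sig & (pr < 0)) / total,
                    "pct_pos": 100.0 * np.sum(pr > 0) / total,
                    "pct_neg": 100.0 * np.sum(pr < 0) / total})
            frows.append(row)
        combo = maps.combo[valid]
        crow = {"class": cls, "month": maps.target_month,
                "response": maps.response_kind, "n_pixels": total}
        for code, name in enumerate(COMBO_ORDER):
            crow[f"pct_{name}"] = (100.0 * np.sum(combo == code) / total
                                   if total else np.nan)
        crows.append(crow)
    return pd.DataFrame(frows), pd.DataFrame(crows)
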