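"""Synthetic raster scenes with known trends, climate couplings and lags.

The generator emulates the statistical structure the analysis assumes in
real data: per-vegetation-class seasonal LAI curves, year-on-year trends in
the monthly LAI increment (VLAI), and climate anomaly series that drive
VLAI through preseason-window means with known window lengths.  Every
embedded quantity is recorded in a :class:`SyntheticTruth` so downstream
stages have a parameter-recovery target without any external data.

VLAI is generated directly and cumulated into LAI (rather than generating
LAI and differencing), so the coupling and lag truth is exact by
construction.  Climate anomalies are spatially constant within each
vegetation-class block; pixels differ only through their independent VLAI
noise, which is what makes per-pixel correlation statistics non-degenerate
while keeping the truth uniform within a class.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .grid import GridSpec
from .stack import CLASS_CODES, MonthlyStack, VegetationMask, VEG_CLASSES

FACTORS = ("TEM", "PRE", "SRAD")
ANALYSIS_MONTHS = tuple(range(4, 11))    # April..October
CLIMATE_MONTHS = tuple(range(1, 11))     # January..October


def _per_month(d, months=ANALYSIS_MONTHS):
    """Normalise a scalar or {month: value} mapping to a {month: float} dict."""
    if np.isscalar(d):
        return {m: float(d) for m in months}
    return {int(m): float(v) for m, v in d.items()}


@dataclass
class ClimateParams:
    """Monthly climatology and anomaly model for one climate factor."""

    mean: dict[int, float]          # climatology per calendar month 1..10
    sd: dict[int, float]            # anomaly scale per month (same units)
    ar1: float = 0.3                # lag-1 autocorrelation of anomalies

    def __post_init__(self):
        self.mean = _per_month(self.mean, CLIMATE_MONTHS)
        self.sd = _per_month(self.sd, CLIMATE_MONTHS)
        if not -1.0 < self.ar1 < 1.0:
            raise ValueError(f"lag-1 autocorrelation must lie in (-1, 1), got {self.ar1}")


@dataclass
class SceneConfig:
    """Everything needed to generate one synthetic scene deterministically."""

    n_rows: int = 60
    n_cols: int = 60
    years: tuple[int, int] = (2001, 2020)        # inclusive range
    pixel_size_m: float = 1000.0
    class_layout: str = "thirds"                  # vertical thirds G|F|C
    baseline_lai_march: dict[str, float] = field(default_factory=lambda: {
        "grassland": 0.2, "forest": 0.5, "farmland": 0.1})
    # mean VLAI per class x analysis month, m2/m2/month
    baseline_increment: dict[str, dict[int, float]] = field(default_factory=lambda: {
        "grassland": {4: 0.20, 5: 0.40, 6: 0.30, 7: 0.10, 8: 0.00, 9: -0.40, 10: -0.50},
        "forest":    {4: 0.50, 5: 0.80, 6: 0.60, 7: 0.20, 8: 0.00, 9: -0.80, 10: -1.00},
        "farmland":  {4: 0.15, 5: 0.50, 6: 0.60, 7: 0.30, 8: 0.10, 9: -0.70, 10: -0.80}})
    # annual change of VLAI, m2/m2/month per year: {class: {month: slope}}
    trend: dict[str, dict[int, float]] = field(default_factory=lambda: {
        "forest": {4: 0.004}, "farmland": {8: -0.004}})
    # {class: {(month, factor): coefficient}}, m2/m2/month per sd of the
    # standardized preseason-window mean of the factor
    coupling: dict[str, dict[tuple[int, str], float]] = field(default_factory=lambda: {
        "forest": {(5, "TEM"): 0.02, (8, "TEM"): -0.02},
        "grassland": {(m, "PRE"): 0.02 for m in ANALYSIS_MONTHS}})
    # {class: {(month, factor): window length 1..4}}
    true_window: dict[str, dict[tuple[int, str], int]] = field(default_factory=lambda: {
        "forest": {(5, "TEM"): 2, (8, "TEM"): 2},
        "grassland": {(m, "PRE"): 3 for m in ANALYSIS_MONTHS}})
    climate_params: dict[str, ClimateParams] = field(default_factory=lambda: {
        "TEM": ClimateParams(
            mean={1: -18, 2: -13, 3: -4, 4: 6, 5: 14, 6: 19, 7: 22, 8: 20, 9: 13, 10: 4},
            sd=1.5, ar1=0.3),
        "PRE": ClimateParams(
            mean={1: 4, 2: 6, 3: 14, 4: 32, 5: 52, 6: 95, 7: 145, 8: 120, 9: 62, 10: 28},
            sd={1: 2, 2: 3, 3: 7, 4: 14, 5: 20, 6: 35, 7: 50, 8: 45, 9: 25, 10: 12},
            ar1=0.2),
        "SRAD": ClimateParams(
            mean={1: 70, 2: 105, 3: 150, 4: 190, 5: 220, 6: 230, 7: 215, 8: 185,
                  9: 135, 10: 95},
            sd=12.0, ar1=0.3)})
    noise_sd: float = 0.01          # VLAI residual sd, m2/m2/month
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for cls, win in self.true_window.items():
            for key, n in win.items():
                if n not in (1, 2, 3, 4):
                    raise ValueError(f"true window length must be in 1..4, got {n} "
                                     f"for {cls} {key}")
        for cls, cpl in self.coupling.items():
            for key in cpl:
                if key not in self.true_window.get(cls, {}):
                    raise ValueError(f"coupling {cls} {key} has no true_window entry")

    @property
    def year_list(self) -> np.ndarray:
        return np.arange(self.years[0], self.years[1] + 1)

    def grid(self) -> GridSpec:
        px = self.pixel_size_m
        return GridSpec(n_rows=self.n_rows, n_cols=self.n_cols,
                        geotransform=(0.0, px, 0.0, 0.0, 0.0, -px),
                        crs="local-projected")

    def class_labels(self) -> np.ndarray:
        if self.class_layout != "thirds":
            raise ValueError(f"unknown class layout {self.class_layout!r}")
        labels = np.zeros((self.n_rows, self.n_cols), dtype=np.int8)
        edges = np.linspace(0, self.n_cols, 4).astype(int)
        for cls, (c0, c1) in zip(VEG_CLASSES, zip(edges[:-1], edges[1:])):
            labels[:, c0:c1] = CLASS_CODES[cls]
        return labels


def null_scene_config(seed: int = 0, **overrides) -> SceneConfig:
    """A scene with no trends and no climate couplings (noise only)."""
    return SceneConfig(trend={}, coupling={}, true_window={}, seed=seed, **overrides)


@dataclass
class SyntheticTruth:
    """The generator's record of what was embedded, for recovery tests."""

    config: SceneConfig
    labels: np.ndarray                                   # class codes per pixel
    trend: dict[str, dict[int, float]]                   # class -> month -> slope
    coupling: dict[str, dict[tuple[int, str], float]]
    true_window: dict[str, dict[tuple[int, str], int]]
    clip_count: int = 0
    clipped: np.ndarray | None = None                    # (year, row, col) bool

    def trend_sign(self, cls: str, month: int) -> int:
        return int(np.sign(self.trend.get(cls, {}).get(month, 0.0)))

    def coupling_sign(self, cls: str, month: int, factor: str) -> int:
        return int(np.sign(self.coupling.get(cls, {}).get((month, factor), 0.0)))

    def window_of(self, cls: str, month: int, factor: str) -> int | None:
        return self.true_window.get(cls, {}).get((month, factor))


# ---------------------------------------------------------------------------
# climate simulation
# ---------------------------------------------------------------------------

def _ar1_series(rng: np.random.Generator, n: int, phi: float) -> np.ndarray:
    """Unit-marginal-variance AR(1) sequence of length n."""
    eps = rng.standard_normal(n)
    a = np.empty(n)
    a[0] = eps[0]
    scale = np.sqrt(1.0 - phi * phi)
    for t in range(1, n):
        a[t] = phi * a[t - 1] + scale * eps[t]
    return a


def simulate_climate(config: SceneConfig) -> dict[str, MonthlyStack]:
    """Generate TEM/PRE/SRAD stacks covering months 1-10 of every year.

    Each factor is its monthly climatology plus an AR(1) anomaly drawn in
    year-month order, spatially constant within each vegetation-class block.
    """
    rng = np.random.default_rng([int(config.seed) % (2**31), 11])
    grid = config.grid()
    labels = config.class_labels()
    years = config.year_list
    n_y, n_m = len(years), len(CLIMATE_MONTHS)
    stacks = {}
    for factor in FACTORS:
        params = config.climate_params[factor]
        cube = np.empty((n_y, n_m, config.n_rows, config.n_cols))
        for cls in VEG_CLASSES:
            sel = labels == CLASS_CODES[cls]
            anom = _ar1_series(rng, n_y * n_m, params.ar1).reshape(n_y, n_m)
            for im, m in enumerate(CLIMATE_MONTHS):
                vals = params.mean[m] + params.sd[m] * anom[:, im]
                cube[:, im][:, sel] = vals[:, None]
        stacks[factor] = MonthlyStack(variable=factor, grid=grid, years=years,
                                      months=np.array(CLIMATE_MONTHS), values=cube)
    return stacks


# ---------------------------------------------------------------------------
# LAI simulation
# ---------------------------------------------------------------------------

def _standardized_window_mean(climate: MonthlyStack, cls_pixel: tuple[int, int],
                              target_month: int, n: int) -> np.ndarray:
    """Z-scored yearly preseason-window mean at one representative pixel."""
    r, c = cls_pixel
    months = range(target_month - n + 1, target_month + 1)
    series = np.mean([climate.month_cube(m)[:, r, c] for m in months], axis=0)
    sd = series.std(ddof=1)
    if sd == 0:
        return np.zeros_like(series)
    return (series - series.mean()) / sd


def simulate_lai(config: SceneConfig,
                 climate: dict[str, MonthlyStack]) -> tuple[MonthlyStack, SyntheticTruth]:
    """Cumulate generated VLAI into a monthly LAI stack (months 3-10).

    Per pixel, year y and analysis month m:
    ``VLAI = baseline + trend*(y - y0) + sum_f coupling_f * z_f(m) + noise``
    where ``z_f(m)`` is the z-scored yearly mean of factor f over its true
    preseason window ending at m.  March LAI is the class baseline; later
    months add VLAI, clipping at zero (clip events are counted and flagged).
    """
    grid = config.grid()
    labels = config.class_labels()
    years = config.year_list
    n_y = len(years)
    for f in FACTORS:
        need = set(CLIMATE_MONTHS)
        have = set(climate[f].months.tolist())
        if not need <= have:
            raise ValueError(f"climate stack {f} missing months {sorted(need - have)}")
    rng = np.random.default_rng([int(config.seed) % (2**31), 13])

    vlai = np.zeros((n_y, len(ANALYSIS_MONTHS), config.n_rows, config.n_cols))
    for cls in VEG_CLASSES:
        sel = labels == CLASS_CODES[cls]
        rep = tuple(np.argwhere(sel)[0])       # anomalies are block-constant
        for im, m in enumerate(ANALYSIS_MONTHS):
            base = config.baseline_increment[cls][m]
            slope = config.trend.get(cls, {}).get(m, 0.0)
            signal = base + slope * (years - years[0]).astype(float)
            for f in FACTORS:
                coef = config.coupling.get(cls, {}).get((m, f), 0.0)
                if coef != 0.0:
                    n_win = config.true_window[cls][(m, f)]
                    signal = signal + coef * _standardized_window_mean(
                        climate[f], rep, m, n_win)
            vlai[:, im][:, sel] = signal[:, None]
    vlai += rng.normal(0.0, config.noise_sd, size=vlai.shape)

    march = np.zeros((config.n_rows, config.n_cols))
    for cls in VEG_CLASSES:
        march[labels == CLASS_CODES[cls]] = config.baseline_lai_march[cls]
    lai = np.empty((n_y, 1 + len(ANALYSIS_MONTHS), config.n_rows, config.n_cols))
    lai[:, 0] = march[None]
    clipped = np.zeros((n_y, config.n_rows, config.n_cols), dtype=bool)
    for im in range(len(ANALYSIS_MONTHS)):
        raw = lai[:, im] + vlai[:, im]
        neg = raw < 0
        clipped |= neg
        lai[:, im + 1] = np.where(neg, 0.0, raw)

    truth = SyntheticTruth(config=config, labels=labels,
                           trend={c: dict(v) for c, v in config.trend.items()},
                           coupling={c: dict(v) for c, v in config.coupling.items()},
                           true_window={c: dict(v) for c, v in config.true_window.items()},
                           clip_count=int(clipped.sum()), clipped=clipped)
    stack = MonthlyStack(variable="LAI", grid=grid, years=years,
                         months=np.arange(3, 11), values=lai)
    return stack, truth


def simulate_scene(config: SceneConfig):
    """Full scene: (lai, climate dict, vegetation mask, truth)."""
    climate = simulate_climate(config)
    lai, truth = simulate_lai(config, climate)
    mask = VegetationMask(grid=config.grid(), labels=config.class_labels())
    return lai, climate, mask, truth
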