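# canopyshift

Per-pixel analysis of vegetation canopy growth rates from monthly leaf area
index (LAI) raster time series: trend detection in monthly LAI increments,
lag-optimised attribution to preseason climate, and vegetation-type-stratified
summaries.

## The problem

LAI-based phenology usually extracts start/end-of-season dates. A complementary
view asks how *fast* the canopy develops and senesces month by month, whether
that speed is changing over decades, and which climate factor drives it. The
metric is the monthly LAI increment

```
VLAI(t) = LAI(t) − LAI(t−1)        [m²/m²/month]
```

whose sign separates canopy development (+) from senescence (−) and whose
magnitude is the speed of canopy change. The growing season (April–October) is
partitioned into development (Apr–Jun), maturity (Jul–Aug) and senescence
(Sep–Oct) stages.

For each pixel and month the pipeline:

1. fits an ordinary-least-squares trend of VLAI (or LAI) on the year, with a
   two-sided t-test on the slope, and classifies pixels into significant /
   non-significant increase / decrease at α = 0.05;
2. builds candidate *preseason* series for each climate factor — air
   temperature (TEM), precipitation (PRE), solar radiation (SRAD) — as yearly
   means over windows of 1–4 months ending at the response month, and selects
   the window with the strongest simple Pearson correlation (ties to the
   shorter window);
3. computes the second-order partial correlation between the response and each
   factor at its selected window, controlling the other two factors at their
   own selected windows (t-test on n − 4 degrees of freedom), and assigns one
   of eight factor-combination classes (No, TEM, PRE, SRAD, TEM+PRE, TEM+SRAD,
   PRE+SRAD, TEM+PRE+SRAD);
4. summarises, per vegetation class (grassland / forest / farmland restricted
   to pixels with stable land cover), trend-category area percentages, signed
   significant-correlation percentages, combo-class percentages, selected
   window-length distributions and the area-weighted mean lag.

Because the satellite and climate rasters such an analysis consumes are not
redistributable, the package ships a synthetic scene generator that embeds
known trends, couplings and preseason window lengths, so every stage has an
exact parameter-recovery target.

## Worked example

```python
import canopyshift as cs

scene = cs.SceneConfig(seed=42)          # 60×60 px, 2001–2020, known truth
lai, climate, mask, truth = cs.simulate_scene(scene)
vlai = cs.compute_vlai(lai)

slope, _, p, _ = cs.fit_trend_stack(vlai, month=5)
cat, _ = cs.classify_trend(slope, p)
print(cs.summarize_trends(cat, slope, mask, month=5).round(2))

maps = cs.attribute_month(vlai.month_cube(5), climate, target_month=5)
fdf, cdf = cs.summarize_attribution(maps, mask)
print(fdf[fdf.factor == "TEM"].round(2))
```

prints (abridged):

```
    class  month        category   pct  mean_sig_slope_e3
   forest      5    sig_increase  1.42               1.83
   forest      5 nonsig_increase 97.08                NaN
 farmland      5    sig_decrease  2.58              -0.87
 ...

    class  month response factor  n_pixels  pct_sig_pos  pct_sig_neg
grassland      5     VLAI    TEM      1200         2.75         3.42
   forest      5     VLAI    TEM      1200       100.00         0.00
 farmland      5     VLAI    TEM      1200         5.75         5.25
```

Reading it: this scene embeds a positive May TEM coupling in forest only, so
100 % of forest pixels show a significant positive partial correlation with
preseason temperature while the uncoupled classes sit near the 5 % false-
positive floor of α = 0.05. The trend table shows no May VLAI trend was
embedded (significant fractions ≈ α); `mean_sig_slope_e3` is the mean slope
of the significant pixels in 10⁻³ m²/m² per year. The grassland PRE mean lag
for May evaluates to 3.14 months against an embedded 3-month preseason.

The same stages run from the shell on TIFF/NetCDF stacks:

```bash
canopyshift simulate --seed 7 --out scene/
canopyshift run config.yaml       # simulate/read → vlai → trends → attribution → lags
```

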