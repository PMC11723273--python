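# Methods

## The response metric and its partition

The analysis works on the monthly leaf-area-index increment
VLAI(t) = LAI(t) − LAI(t−1), computed per pixel for consecutive calendar
months of the same year. April's increment requires March LAI, so LAI input
stacks must cover months 3–10 of every analysis year; the increment months
are 4–10. Two identities are enforced as exact tests: the increments
telescope (the sum of May–October increments equals LAI(Oct) − LAI(Apr) to
machine precision) and VLAI is invariant to any constant offset in LAI.
The growing season is partitioned into development (April–June), maturity
(July–August) and senescence (September–October); month-group aggregations
in the lag tables additionally use an early (April–July) / late
(August–October) split and a wide development window (April–August) for
period-level comparisons.

## Trend model

Per pixel and month, VLAI (or LAI) is regressed on the calendar year with
ordinary least squares; significance is the two-sided t-test on the slope
with n − 2 degrees of freedom. A series that is exactly constant is reported
as slope 0 with p = 1; an exact line gets p = 0. Pixels with fewer than
`min_years` (default 10) non-nodata years are nodata. Nodata handling is
pairwise by year: a missing month at a pixel drops only that pixel-year.
Theil–Sen/Mann–Kendall variants were deliberately not implemented; the OLS
slope is the single tested estimator, and the vectorised weighted-sums
implementation is cross-checked against `scipy.stats.linregress` per series.

Classification uses four categories (significant/non-significant ×
increase/decrease) at α = 0.05 with no multiple-testing correction across
pixels, months or factors — a deliberate choice that matches how such maps
are conventionally reported, and a known limitation: the per-map false
discovery rate is not controlled. A slope of exactly zero counts as a
(non-significant) increase so the four categories partition every stratum.
Slope-magnitude bins (default edges 0.002/0.005/0.010 m²/m²/yr on |slope|,
right-open, edge values to the higher bin) are configuration only and feed
no downstream statistic.

## Preseason attribution

For response month m and factor f ∈ {TEM, PRE, SRAD}, candidate preseason
series are the yearly means of f over windows of length n ∈ {1, 2, 3, 4}
months ending at m — n = 1 is the response month itself, n = 4 reaches three
months back. The selected window maximises the absolute simple Pearson
correlation with the response; ties resolve to the smaller n (the most
parsimonious lag). Window lengths are reported as-is (1–4, including the
response month); "lag" in the outputs means selected window length in
months.

The attribution statistic is the second-order partial correlation between
the response and f at its selected window, controlling the *other two
factors at their own selected windows* — the controls mirror the per-factor
selection step so the three factors are treated symmetrically. It is
computed from the pairwise correlation matrix by the standard recursion
(condition on one control, then the other), which is algebraically identical
to the residual-regression definition but remains finite in the perfectly
collinear |r| = 1 case that noise-free synthetic pixels produce. The test
suite verifies equivalence with the residual-regression oracle and with
`pingouin.partial_corr` to 1e−10. The p-value uses
t = r·√((n − 2 − g)/(1 − r²)) with g = 2 controls, two-sided, df = n − 4;
|r| = 1 maps to p = 0. A first-order variant (single control) exists behind
the `order` parameter for sensitivity checks but is untested surface.

All statistics at a pixel-month share one sample: a year is dropped if the
response or any candidate window mean is nodata there, so the selected
window, the control series and the partial correlation always see identical
years. Pixels with fewer than max(min_years, 6) common years are nodata.

Selection-then-test inflates the per-factor type-I rate above α: with four
correlated candidate windows per factor the measured any-factor
false-positive rate on null scenes is ≈ 0.26 rather than 1 − 0.95³ ≈ 0.14.
The pipeline does not correct for this (the selected-window statistic is
the quantity of interest); the suite instead *measures* the rate and asserts
it is reproducibly stable across seeds (±0.02).

The eight factor-combination classes are coded 0–7 in the order No, TEM,
PRE, SRAD, TEM+PRE, TEM+SRAD, PRE+SRAD, TEM+PRE+SRAD, from which factors
have p < α. Signed area summaries report, per class × month × factor, the
percentage of pixels with significant positive / significant negative /
any positive / any negative partial correlation.

## Lag summaries

Window-length distributions count pixel × month cells (each month
contributes its own selected window) within a vegetation class and month
group, normalised to percent. The mean lag is the area-weighted mean of the
selected lengths: projected grids use constant pixel area; geographic grids
weight rows by cos(latitude of the pixel centre). With equal areas the mean
equals Σ pct(n)·n / 100 exactly, which is asserted.

## Raster handling

Stacks are dense (year, month, row, col) cubes on a single master grid;
nodata is NaN in memory and a sentinel (−9999 by default) on disk. I/O uses
multi-page TIFF with the grid geometry and band → (year, month) mapping
embedded as JSON in the ImageDescription tag (bit-exact round-trip), plus
NetCDF with a (time, y, x) layout read through xarray's scipy engine.
Eight-day composites are aggregated to months by assigning each composite to
the month containing its start date and averaging per pixel, ignoring nodata
(configurable maximum instead of mean); day-weighting across month
boundaries is deliberately not attempted. Resampling to the master grid is
bilinear for continuous variables (partial-nodata windows renormalise the
weights; all-nodata windows stay nodata) and nearest or majority for
categorical ones, with majority ties resolved to the smallest class code.
Rotated grids are rejected. The vegetation mask keeps a pixel only if its
mapped class (grassland/forest/farmland) is identical in every year of the
land-cover series; unmapped codes exclude the pixel and are counted in a log
summary. The mask is invariant to the order of the land-cover years.

## Synthetic scenes

The generator emulates the structure the analysis assumes: per-class
seasonal VLAI baselines cumulated into LAI from a class-specific March
value, year-linear trends in specific class-months, and climate couplings
through preseason-window means. VLAI is generated directly and cumulated
(clipping LAI at zero, with clip events counted and flagged) so the
telescoping identity and the coupling/lag truth are exact by construction.
Climate is a monthly climatology plus an AR(1) anomaly in year-month order,
spatially constant within each class block; pixels differ only through
independent Gaussian VLAI noise. Couplings multiply the z-scored yearly
window mean of the raw factor series, so the coefficient is in m²/m²/month
per standard deviation and the correlation truth is invariant to the
climatology's units.

Default conditions (chosen once as a realistic desk-scale study): 60×60
pixels in three equal class stripes, years 2001–2020, VLAI noise sd
0.01 m²/m²/month, couplings ±0.02 (signal-to-noise 2): forest TEM positive
in May and negative in August (window 2), grassland PRE positive in every
month (window 3); trends ±0.004 m²/m²/month per year placed on class-months
disjoint from the couplings (forest April +, farmland August −) so each
recovery test has a clean truth. Climatologies approximate a cold temperate
continental seasonal cycle; anomaly lag-1 autocorrelation is 0.3 (TEM,
SRAD) and 0.2 (PRE). The null scene zeroes all trends and couplings.

What the generator does not emulate — and hence what passing tests do not
establish about real data: spatially correlated noise and climate gradients
within a class, cloud/QA gaps and retrieval artefacts, mixed pixels and
land-cover legend ambiguity, and non-linear or threshold vegetation
responses. Recovery rates measured here are upper bounds for field data.

With these conditions, roughly 70 % of coupled pixels select exactly the
true window length (adjacent windows share most of their months, so their
yearly means are strongly correlated and selection noise spills into
lengths ±1), the modal window equals the truth, the stratum mean lag lands
within 0.1 of the embedded value, and sign recovery among significant
pixels is effectively 100 %.

## Numerical and design notes

- Seeds: every random draw derives from `numpy.random.default_rng` seeded
  from the scene seed (separate streams for climate and noise), so scenes,
  CSVs and truth files are bit-reproducible.
- Problem sizes in the test and verification runs (60×60 × 20 years, 1,000
  oracle replicates, three null seeds) were chosen to keep the whole suite
  in seconds on one core while leaving ≥ 3,000 pixels for rate assertions.
- Percentage tables are asserted to partition 100 % of each non-nodata
  stratum to 1e−9; empty strata yield NaN rows plus a warning rather than
  an error.
- The LAI and VLAI responses share one code path (`response_kind`
  parameter); both are exercised by the pipeline tests.
- Partial correlations are clipped to [−1, 1] to absorb last-bit floating
  error before the t-transform.
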