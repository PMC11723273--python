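"""Preseason window selection, partial correlation, combo classification."""

import numpy as np
import pandas as pd
import pytest

import canopyshift as cs
from canopyshift.attribution import COMBO_ORDER, _second_order_partial


def _stack_from_monthly(values_by_month, years=20, grid=None):
    """Climate stack with identical yearly values per month (plus optional noise)."""
    months = sorted(values_by_month)
    if grid is None:
        grid = cs.GridSpec(n_rows=1, n_cols=1)
    cube = np.empty((years, len(months), grid.n_rows, grid.n_cols))
    for im, m in enumerate(months):
        cube[:, im] = np.broadcast_to(np.asarray(values_by_month[m], float),
                                      (years,) + grid.shape)
    return cs.MonthlyStack("TEM", grid, np.arange(2001, 2001 + years),
                           np.asarray(months), cube)


class TestPreseasonSeries:
    def test_window_of_one_is_the_target_month(self, default_scene):
        tem = default_scene["climate"]["TEM"]
        series = cs.preseason_series(tem, 7, 1, pixel=(0, 0))
        np.testing.assert_array_equal(series, tem.month_cube(7)[:, 0, 0])

    def test_three_month_window_mean(self):
        stack = _stack_from_monthly({5: 10.0, 6: 14.0, 7: 18.0})
        series = cs.preseason_series(stack, 7, 3, pixel=(0, 0))
        np.testing.assert_allclose(series, 14.0)

    def test_constant_climate_gives_constant_series(self):
        stack = _stack_from_monthly({m: 3.0 for m in range(1, 11)})
        for n in (1, 2, 3, 4):
            np.testing.assert_allclose(
                cs.preseason_series(stack, 6, n, pixel=(0, 0)), 3.0)

    def test_missing_window_month_is_an_error(self):
        stack = _stack_from_monthly({6: 1.0, 7: 1.0})
        with pytest.raises(ValueError, match=r"\[5\]"):
            cs.preseason_series(stack, 7, 3)

    def test_window_cannot_reach_before_january(self):
        stack = _stack_from_monthly({m: 1.0 for m in range(1, 11)})
        with pytest.raises(ValueError, match="January"):
            cs.preseason_series(stack, 3, 4)


class TestSelectBestWindow:
    def test_exact_dependence_selects_true_window(self, default_scene):
        tem = default_scene["climate"]["TEM"]
        cands = [cs.preseason_series(tem, 7, n, pixel=(5, 5)) for n in (1, 2, 3, 4)]
        n_star, r = cs.select_best_window(cands[2], cands)
        assert n_star == 3
        assert r == pytest.approx(1.0)

    def test_tie_breaks_toward_smaller_window(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=20)
        c = rng.normal(size=20)
        d = rng.normal(size=20)
        y0 = y - y.mean()
        d = d - d.mean()
        d -= (d @ y0) / (y0 @ y0) * y0          # exactly uncorrelated with y
        # candidates 2, 3, 4 share |r|; tie resolves to the shortest, n=2
        n_star, _ = cs.select_best_window(y, [d, c, c, -c])
        assert n_star == 2

    def test_degenerate_candidates_give_nodata(self):
        y = np.random.default_rng(1).normal(size=20)
        n_star, r = cs.select_best_window(y, [np.ones(20)] * 4)
        assert n_star == 0 and np.isnan(r)

    def test_null_selection_matches_monte_carlo_max_null_r(self):
        """With no true coupling, the selected |r| is the max of 4 null
        correlations; compare its distribution to a brute-force null."""
        rng = np.random.default_rng(42)
        n_years, reps = 20, 2000
        selected = np.empty(reps)
        brute = np.empty(reps)
        for i in range(reps):
            y = rng.normal(size=n_years)
            cands = rng.normal(size=(4, n_years))
            _, r = cs.select_best_window(y, cands)
            selected[i] = abs(r)
            brute[i] = max(abs(np.corrcoef(y, c)[0, 1]) for c in cands)
        np.testing.assert_allclose(selected, brute, atol=1e-12)
        # distribution sanity: median of max-|r| null for n=20 is ~0.25-0.35
        assert 0.2 < np.median(selected) < 0.4


class TestPartialCorrelation:
    def test_orthogonal_controls_reduce_to_plain_pearson(self):
        rng = np.random.default_rng(21)
        n = 32
        y = rng.normal(size=n)
        x = 0.6 * y + rng.normal(size=n)
        # Gram-Schmidt controls exactly orthogonal to centred y and x
        basis = []
        for v in (np.ones(n), y, x):
            for b in basis:
                v = v - (v @ b) * b
            basis.append(v / np.linalg.norm(v))
        controls = []
        for _ in range(2):
            c = rng.normal(size=n)
            for b in basis:
                c = c - (c @ b) * b
            controls.append(c)
        r, _ = cs.partial_correlation(y, x, controls)
        assert r == pytest.approx(np.corrcoef(y, x)[0, 1], abs=1e-10)

    def test_identical_series_have_partial_r_one_and_p_zero(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=20)
        c1, c2 = rng.normal(size=(2, 20))
        r, p = cs.partial_correlation(x, x.copy(), [c1, c2])
        assert r == pytest.approx(1.0, abs=1e-12)
        assert p == 0.0

    def test_matches_residual_regression_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(10, 41))
            y, x, c1, c2 = rng.normal(size=(4, n))
            r, _ = cs.partial_correlation(y, x, [c1, c2], min_years=6)
            C = np.column_stack([np.ones(n), c1, c2])
            ry = y - C @ np.linalg.lstsq(C, y, rcond=None)[0]
            rx = x - C @ np.linalg.lstsq(C, x, rcond=None)[0]
            assert r == pytest.approx(np.corrcoef(ry, rx)[0, 1], abs=1e-10)

    def test_matches_pingouin_r_and_p(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(9)
        for _ in range(25):
            y, x, c1, c2 = rng.normal(size=(4, 20))
            r, p = cs.partial_correlation(y, x, [c1, c2])
            out = pg.partial_corr(pd.DataFrame({"y": y, "x": x, "c1": c1, "c2": c2}),
                                  "y", "x", covar=["c1", "c2"])
            assert r == pytest.approx(out["r"].iloc[0], abs=1e-10)
            assert p == pytest.approx(out["p_val"].iloc[0], abs=1e-10)

    def test_conditioning_order_is_irrelevant(self):
        rng = np.random.default_rng(13)
        y, x, c1, c2 = rng.normal(size=(4, 24))
        r12, _ = cs.partial_correlation(y, x, [c1, c2])
        r21, _ = cs.partial_correlation(y, x, [c2, c1])
        assert r12 == pytest.approx(r21, abs=1e-12)

    def test_nodata_years_dropped(self):
        rng = np.random.default_rng(5)
        y, x, c1, c2 = rng.normal(size=(4, 25))
        y2 = y.copy()
        y2[3] = np.nan
        r_full, _ = cs.partial_correlation(np.delete(y, 3), np.delete(x, 3),
                                           [np.delete(c1, 3), np.delete(c2, 3)])
        r_nan, _ = cs.partial_correlation(y2, x, [c1, c2])
        assert r_nan == pytest.approx(r_full, abs=1e-12)


class TestAttributePixelAndMonth:
    def test_single_factor_coupling_is_classified_as_that_factor(self):
        cfg = cs.SceneConfig(seed=0, n_rows=6, n_cols=6, noise_sd=0.0,
                             trend={},
                             coupling={"forest": {(6, "TEM"): 1.0}},
                             true_window={"forest": {(6, "TEM"): 3}})
        climate = cs.simulate_climate(cfg)
        lai, truth = cs.simulate_lai(cfg, climate)
        vlai = cs.compute_vlai(lai)
        r, c = map(int, np.argwhere(truth.labels == 2)[0])
        att = cs.attribute_pixel(vlai.month_cube(6)[:, r, c], climate, (r, c), 6)
        assert att.combo_class == "TEM"
        assert att.best_window["TEM"] == 3
        assert att.partial_r["TEM"] == pytest.approx(1.0, abs=1e-9)
        assert att.p_value["PRE"] >= 0.05 and att.p_value["SRAD"] >= 0.05

    def test_additive_two_factor_coupling_yields_combined_class(self):
        cfg = cs.SceneConfig(seed=2, n_rows=6, n_cols=6, noise_sd=0.0,
                             trend={},
                             coupling={"forest": {(6, "TEM"): 1.0, (6, "PRE"): 1.0}},
                             true_window={"forest": {(6, "TEM"): 2, (6, "PRE"): 2}})
        climate = cs.simulate_climate(cfg)
        lai, truth = cs.simulate_lai(cfg, climate)
        vlai = cs.compute_vlai(lai)
        r, c = map(int, np.argwhere(truth.labels == 2)[0])
        att = cs.attribute_pixel(vlai.month_cube(6)[:, r, c], climate, (r, c), 6)
        assert att.combo_class == "TEM+PRE"

    def test_affine_climate_transform_changes_nothing(self, default_scene,
                                                      default_vlai):
        climate = default_scene["climate"]
        base = cs.attribute_month(default_vlai.month_cube(5), climate, 5)
        tem = climate["TEM"]
        scaled = dict(climate)
        scaled["TEM"] = cs.MonthlyStack("TEM", tem.grid, tem.years, tem.months,
                                        tem.values * 1.8 + 273.15)
        out = cs.attribute_month(default_vlai.month_cube(5), scaled, 5)
        np.testing.assert_array_equal(out.factors["TEM"].best_window,
                                      base.factors["TEM"].best_window)
        np.testing.assert_allclose(out.factors["TEM"].partial_r,
                                   base.factors["TEM"].partial_r, atol=1e-9)

    def test_pixel_and_month_paths_agree(self, default_scene, default_vlai,
                                         default_attribution):
        maps = default_attribution[6]
        climate = default_scene["climate"]
        for pix in [(3, 3), (30, 30), (50, 55)]:
            att = cs.attribute_pixel(default_vlai.month_cube(6)[:, pix[0], pix[1]],
                                     climate, pix, 6)
            for f in ("TEM", "PRE", "SRAD"):
                assert att.best_window[f] == maps.factors[f].best_window[pix]
                assert att.partial_r[f] == pytest.approx(
                    maps.factors[f].partial_r[pix], abs=1e-12)

    def test_null_scene_false_positive_rate_is_stable_across_seeds(self):
        """Window selection inflates the three alpha=0.05 tests; the measured
        any-factor false-positive rate must be reproducibly stable."""
        rates = []
        for seed in (1, 2, 3):
            cfg = cs.null_scene_config(seed=seed)
            lai, climate, mask, _ = cs.simulate_scene(cfg)
            vlai = cs.compute_vlai(lai)
            fp = tot = 0
            for m in range(4, 11):
                maps = cs.attribute_month(vlai.month_cube(m), climate, m)
                fp += np.sum(maps.combo > 0)
                tot += np.sum(maps.combo >= 0)
            rates.append(fp / tot)
        assert max(rates) - min(rates) <= 0.02
        # selection-inflated: clearly above the no-selection bound 1-0.95^3
        assert min(rates) > 0.143


class TestSummaries:
    def test_hand_counted_sign_percentages(self, small_grid):
        from canopyshift.attribution import AttributionMaps, FactorMaps
        labels = np.zeros((4, 4), dtype=np.int8)
        labels[0, :4] = 1
        mask = cs.VegetationMask(grid=small_grid, labels=labels)
        pr = np.full((4, 4), np.nan)
        pv = np.full((4, 4), np.nan)
        pr[0] = [0.9, 0.3, -0.8, -0.7]
        pv[0] = [0.01, 0.5, 0.01, 0.02]        # +sig, +nonsig, -sig, -sig
        f = FactorMaps(best_window=np.where(np.isfinite(pr), 2, 0),
                       simple_r=pr, partial_r=pr, p_value=pv)
        combo = np.where(labels == 1, 1, -1).astype(np.int8)
        maps = AttributionMaps("VLAI", 5, 0.05,
                               {"TEM": f, "PRE": f, "SRAD": f}, combo,
                               np.full((4, 4), 20))
        fdf, cdf = cs.summarize_attribution(maps, mask)
        row = fdf[(fdf["class"] == "grassland") & (fdf.factor == "TEM")].iloc[0]
        assert row.pct_sig_pos == pytest.approx(25.0)
        assert row.pct_sig_neg == pytest.approx(50.0)
        assert row.pct_pos == pytest.approx(50.0)
        assert row.pct_neg == pytest.approx(50.0)

    def test_combo_percentages_partition_100(self, default_scene,
                                             default_attribution):
        _, cdf = cs.summarize_attribution(default_attribution[8],
                                          default_scene["mask"])
        pct_cols = [c for c in cdf.columns if c.startswith("pct_")]
        np.testing.assert_allclose(cdf[pct_cols].sum(axis=1), 100.0, atol=1e-9)
        assert list(cdf["class"]) == ["grassland", "forest", "farmland", "all"]

    def test_combo_order_matches_legend(self):
        assert COMBO_ORDER == ("No", "TEM", "PRE", "SRAD", "TEM+PRE",
                               "TEM+SRAD", "PRE+SRAD", "TEM+PRE+SRAD")


class TestRecovery:
    def test_coupling_sign_recovery_on_default_scene(self, default_scene,
                                                     default_attribution):
        truth = default_scene["truth"]
        mask = default_scene["mask"]
        for cls, month, factor in (("forest", 5, "TEM"), ("forest", 8, "TEM"),
                                   ("grassland", 6, "PRE")):
            sign = truth.coupling_sign(cls, month, factor)
            maps = default_attribution[month]
            sel = mask.pixels_of(cls)
            pr = maps.factors[factor].partial_r[sel]
            pv = maps.factors[factor].p_value[sel]
            sig = pv < 0.05
            assert sig.any()
            assert np.mean(np.sign(pr[sig]) == sign) >= 0.90

    def test_window_recovery_on_default_scene(self, default_scene,
                                              default_attribution):
        """Modal selected window equals the embedded truth; a solid majority
        of coupled pixels select it (threshold fixed for the default scene)."""
        truth = default_scene["truth"]
        mask = default_scene["mask"]
        gsel = mask.pixels_of("grassland")
        picks = np.concatenate(
            [default_attribution[m].factors["PRE"].best_window[gsel]
             for m in range(4, 11)])
        counts = np.bincount(picks, minlength=5)
        assert counts.argmax() == truth.window_of("grassland", 4, "PRE") == 3
        assert counts[3] / picks.size >= 0.70
        fsel = mask.pixels_of("forest")
        for month in (5, 8):
            bw = default_attribution[month].factors["TEM"].best_window[fsel]
            assert np.bincount(bw, minlength=5).argmax() == 2
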