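"""Synthetic landscape, climate, and EVI generators against injected truth."""

import numpy as np
import pandas as pd
import pytest

from droughtsense import spei, synthetic
from droughtsense.synthetic import (
    ClimateConfig,
    LandscapeConfig,
    SensitivityRule,
    aggregate_subgrid,
    generate_climate,
    generate_evi,
    generate_landscape,
    make_truth,
)


class TestGenerateLandscape:
    def test_deterministic_under_seed(self):
        cfg = LandscapeConfig(n_rows=8, n_cols=8, subgrid_size=4, smoothing_length=0, seed=5)
        a = generate_landscape(cfg)
        b = generate_landscape(cfg)
        pd.testing.assert_frame_equal(a.pixels, b.pixels)
        assert np.array_equal(a.hli_subgrid, b.hli_subgrid)
        assert np.array_equal(a.landcover_subgrid, b.landcover_subgrid)

    def test_covariates_within_ranges(self, small_landscape):
        for name, (lo, hi) in small_landscape.config.covariate_ranges.items():
            if name in ("hli", "cti"):
                continue  # pixel columns replaced by subgrid aggregates
            col = small_landscape.pixels[name]
            assert col.between(lo, hi).all(), name

    def test_biome_rule_applied(self, small_landscape):
        px = small_landscape.pixels
        thr = small_landscape.config.biome_rule.shrub_deficit_threshold
        assert (px.loc[px["deficit"] > thr, "biome"] == "shrub-steppe").all()
        assert (px.loc[px["deficit"] <= thr, "biome"] == "forest").all()
        assert px["ecosystem"].isin([1, 2, 3, 4, 5]).all()

    def test_invalid_range_rejected(self):
        ranges = dict(synthetic.DEFAULT_COVARIATE_RANGES)
        ranges["elev"] = (100.0, 0.0)
        with pytest.raises(ValueError, match="elev"):
            LandscapeConfig(covariate_ranges=ranges)

    def test_smoothing_raises_spatial_autocorrelation(self):
        """Adjacent-pixel correlation is larger with smoothing than without."""

        def adjacency_corr(smoothing, seed):
            cfg = LandscapeConfig(
                n_rows=25, n_cols=25, subgrid_size=1,
                smoothing_length=smoothing, seed=seed,
            )
            f = generate_landscape(cfg).pixels["elev"].to_numpy().reshape(25, 25)
            return np.corrcoef(f[:, :-1].ravel(), f[:, 1:].ravel())[0, 1]

        smooth = np.mean([adjacency_corr(5, s) for s in range(10)])
        rough = np.mean([adjacency_corr(0, s) for s in range(10, 20)])
        assert smooth > rough + 0.3


class TestAggregateSubgrid:
    def test_shade_boundary_inclusive(self):
        sub = np.full((4, 4), 0.5)
        lc = np.ones((4, 4), dtype=int)
        shade, _, _ = aggregate_subgrid(sub, lc, sub)
        assert shade == 100.0
        shade, _, _ = aggregate_subgrid(np.full((4, 4), 0.61), lc, sub)
        assert shade == 0.0
        shade, _, _ = aggregate_subgrid(np.full((4, 4), 0.6), lc, sub)
        assert shade == 100.0  # threshold is inclusive

    def test_majority_landcover_counts(self):
        lc = np.array([1] * 500 + [2] * 589).reshape(33, 33)
        hli = np.zeros((33, 33))
        _, maj, _ = aggregate_subgrid(hli, lc, hli)
        assert maj == 2

    def test_empty_subgrid_error(self):
        with pytest.raises(ValueError, match="empty"):
            aggregate_subgrid(np.empty((0, 0)), np.empty((0, 0), int), np.empty((0, 0)))

    def test_brute_force_oracle(self, rng):
        """Vectorized aggregation equals an explicit loop over subcells."""
        hli = rng.uniform(0, 1.2, (100, 6, 6))
        lc = rng.integers(1, 5, (100, 6, 6))
        cti = rng.normal(7, 2, (100, 6, 6))
        shade, maj, mcti = aggregate_subgrid(hli, lc, cti)
        for i in range(100):
            n_shaded = sum(
                1 for a in range(6) for b in range(6) if hli[i, a, b] <= 0.6
            )
            assert shade[i] == pytest.approx(100.0 * n_shaded / 36)
            counts = {}
            for a in range(6):
                for b in range(6):
                    counts[lc[i, a, b]] = counts.get(lc[i, a, b], 0) + 1
            best = max(sorted(counts), key=lambda c: counts[c])
            assert maj[i] == best
            assert mcti[i] == pytest.approx(np.mean([cti[i, a, b] for a in range(6) for b in range(6)]))


class TestGenerateClimate:
    def test_deterministic_under_seed(self):
        cfg = ClimateConfig(start_year=1990, n_years=30)
        a = generate_climate(np.arange(3), cfg, seed=9)
        b = generate_climate(np.arange(3), cfg, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_too_few_years_error(self):
        with pytest.raises(ValueError, match="unfittable"):
            ClimateConfig(n_years=4)

    def test_noop_drought_forcing(self):
        """Factor 1.0 leaves forced years statistically indistinguishable."""
        base = ClimateConfig(start_year=1980, n_years=30)
        forced = ClimateConfig(start_year=1980, n_years=30, drought_years={2000: 1.0})
        diffs = []
        for s in range(50):
            a = generate_climate(np.arange(1), base, seed=s)
            b = generate_climate(np.arange(1), forced, seed=s)
            diffs.append(a["precipitation"].mean() - b["precipitation"].mean())
        assert np.allclose(diffs, 0.0)

    def test_forced_drought_is_record_minimum(self):
        """A 0.3 precipitation factor makes that year the driest on record."""
        cfg = ClimateConfig(start_year=1980, n_years=30, drought_years={2000: 0.3})
        clim = generate_climate(np.arange(100), cfg, seed=77)
        d = spei.water_balance(clim)
        agg = spei.aggregate_balance(d, 12, end_month=8)
        is_min = agg.loc[agg.groupby("pixel_id")["balance"].idxmin(), "year"] == 2000
        assert is_min.mean() >= 0.95

    def test_seasonal_structure(self):
        clim = generate_climate(np.arange(30), ClimateConfig(start_year=1980, n_years=30), seed=4)
        monthly = clim.groupby("month")[["precipitation", "pet"]].mean()
        assert monthly["precipitation"].idxmax() in (11, 12, 1)  # winter wet
        assert monthly["pet"].idxmax() in (6, 7, 8)  # summer evaporative peak


class TestTruthTable:
    def test_invariants(self, small_landscape):
        truth = make_truth(small_landscape.pixels, disturbed_frac=0.2, trend_frac=0.2, seed=1)
        assert (truth["s_sev_true"] >= truth["s_mod_true"]).all()
        assert (truth["s_mod_true"] >= 0).all()
        assert truth["baseline_evi_true"].between(0, 1, inclusive="neither").all()
        assert truth["true_timescale"].isin([3, 6, 12]).all()

    def test_sensitivity_link_drivers(self, small_landscape):
        """Elevation carries the dominant share of the injected signal."""
        truth = make_truth(small_landscape.pixels, seed=1)
        merged = truth.merge(small_landscape.pixels, on="pixel_id")
        r_elev = np.corrcoef(merged["elev"], merged["s_mod_true"])[0, 1]
        r_wtd = np.corrcoef(merged["wtd"], merged["s_mod_true"])[0, 1]
        assert r_elev > 0.4
        assert abs(r_elev) > abs(r_wtd)


@pytest.fixture(scope="module")
def truth_and_spei(small_landscape, small_spei):
    truth = make_truth(small_landscape.pixels, timescale_choices=(12,), seed=2)
    return truth, small_spei


class TestGenerateEvi:
    def test_null_sensitivity_constant(self, truth_and_spei):
        truth, spei_tab = truth_and_spei
        t0 = truth.assign(s_mod_true=0.0, s_sev_true=0.0, disturbed_flag=False, trend_flag=False)
        evi = generate_evi(t0, spei_tab, noise_sd=0.0, seed=0)
        merged = evi.merge(t0, on="pixel_id")
        assert np.allclose(merged["evi_summer"], merged["baseline_evi_true"])

    def test_direct_formula(self, truth_and_spei):
        truth, spei_tab = truth_and_spei
        t0 = truth.assign(
            baseline_evi_true=0.40, s_mod_true=0.10, s_sev_true=0.20,
            disturbed_flag=False, trend_flag=False,
        )
        evi = generate_evi(t0, spei_tab, noise_sd=0.0, seed=0)
        cls = spei_tab[spei_tab["timescale"] == 12][["pixel_id", "year", "drought_class"]]
        merged = evi.merge(cls, on=["pixel_id", "year"])
        mod = merged[merged["drought_class"] == "moderate"]
        assert len(mod) > 0
        assert np.allclose(mod["evi_summer"], 0.36)
        sev = merged[merged["drought_class"] == "severe"]
        if len(sev):
            assert np.allclose(sev["evi_summer"], 0.32)

    def test_lognormal_noise_level(self, truth_and_spei):
        """Mean log-EVI in baseline years sits at log(baseline), sd at noise_sd."""
        truth, spei_tab = truth_and_spei
        t0 = truth.assign(s_mod_true=0.0, s_sev_true=0.0, disturbed_flag=False, trend_flag=False)
        evi = generate_evi(t0, spei_tab, noise_sd=0.05, seed=0)
        merged = evi.merge(t0, on="pixel_id")
        resid = np.log(merged["evi_summer"]) - np.log(merged["baseline_evi_true"])
        n = len(resid)
        assert abs(resid.mean()) < 3 * 0.05 / np.sqrt(n)
        assert resid.std() == pytest.approx(0.05, rel=0.1)

    def test_disturbance_and_trend_injection(self, truth_and_spei):
        truth, spei_tab = truth_and_spei
        t0 = truth.assign(s_mod_true=0.0, s_sev_true=0.0, trend_flag=False)
        t0.loc[t0.index[:20], "disturbed_flag"] = True
        t0.loc[t0.index[20:], "disturbed_flag"] = False
        evi = generate_evi(t0, spei_tab, noise_sd=0.0, seed=1)
        merged = evi.merge(t0, on="pixel_id")
        disturbed = merged[merged["disturbed_flag"]]
        ratio = disturbed["evi_summer"] / disturbed["baseline_evi_true"]
        assert set(np.round(ratio, 6)) == {0.6, 1.0}  # permanent 40% step drop
        # trend pixels drift linearly
        t1 = truth.assign(s_mod_true=0.0, s_sev_true=0.0, disturbed_flag=False, trend_flag=True)
        evi_t = generate_evi(t1, spei_tab, noise_sd=0.0, seed=1)
        one = evi_t[evi_t["pixel_id"] == t1["pixel_id"].iloc[0]].sort_values("year")
        slopes = np.diff(one["evi_summer"].to_numpy())
        assert np.allclose(slopes, t1["trend_slope"].iloc[0])

    def test_missing_spei_pixel_error(self, truth_and_spei):
        truth, spei_tab = truth_and_spei
        extra = truth.copy()
        extra.loc[extra.index[0], "pixel_id"] = 10_000
        with pytest.raises(ValueError, match="missing pixel"):
            generate_evi(extra, spei_tab, noise_sd=0.0, seed=0)

    def test_deterministic_under_seed(self, truth_and_spei):
        truth, spei_tab = truth_and_spei
        a = generate_evi(truth, spei_tab, noise_sd=0.03, seed=8)
        b = generate_evi(truth, spei_tab, noise_sd=0.03, seed=8)
        pd.testing.assert_frame_equal(a, b)


class TestAttributionDataset:
    def test_target_r2_controls_signal(self):
        tab = synthetic.make_attribution_dataset(n_pixels=2000, target_r2=0.6, seed=3)
        assert len(tab) == 2000
        assert "s_response" in tab.columns
        assert (tab["s_response"] >= 0).all()
        # realized linear-signal R^2 should be near the target
        import numpy.linalg as la

        X = np.column_stack(
            [np.ones(len(tab))]
            + [tab[c].to_numpy() for c in ("elev", "soil_bd", "deficit", "aet")]
        )
        y = tab["s_response"].to_numpy()
        beta, *_ = la.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        r2 = 1 - resid.var() / y.var()
        assert r2 == pytest.approx(0.6, abs=0.1)
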