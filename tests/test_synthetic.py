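"""Unit tests for the synthetic climate-field generator."""

import numpy as np
import pandas as pd
import pytest

import thermozone as tz


class TestGaussianRandomField:
    def test_zero_variance_model_returns_mean(self, rng):
        model = tz.VariogramModel("spherical", 0.0, 0.0, 1.0)
        coords = rng.uniform(0, 1, (30, 2))
        out = tz.generate_gaussian_random_field(model, coords, mean=3.5, seed=1)
        np.testing.assert_array_equal(out, np.full(30, 3.5))

    def test_seed_determinism(self, rng, spherical_model):
        coords = rng.uniform(0, 1, (50, 2))
        a = tz.generate_gaussian_random_field(spherical_model, coords, seed=42)
        b = tz.generate_gaussian_random_field(spherical_model, coords, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_coincident_locations_rejected(self, spherical_model):
        with pytest.raises(tz.InvalidInputError):
            tz.generate_gaussian_random_field(
                spherical_model, np.array([[0.0, 0.0], [0.0, 0.0]]), seed=0
            )

    def test_size_limit(self, spherical_model):
        with pytest.raises(tz.InvalidInputError):
            tz.generate_gaussian_random_field(spherical_model, np.zeros((7000, 2)), seed=0)

    def test_short_lag_semivariance_and_unit_variance(self, spherical_model):
        """Monte-Carlo: short-lag empirical semivariance sits below the
        near-range semivariance, and the sample variance matches the sill."""
        short, near, var = [], [], []
        for s in range(20):
            rng = np.random.default_rng(300 + s)
            coords = rng.uniform(0, 1, (400, 2))
            v = tz.generate_gaussian_random_field(spherical_model, coords, rng=rng)
            emp = tz.empirical_semivariogram(coords, v, n_lags=10, max_dist=0.5)
            short.append(emp.gamma_hat[0])  # lags well below the 0.3 range
            near.append(emp.gamma_hat[5])  # lags around the range
            var.append(v.var())
        assert np.mean(short) < np.mean(near)
        assert np.mean(var) == pytest.approx(1.0, rel=0.25)


class TestSyntheticConfig:
    def test_invariants_enforced(self):
        with pytest.raises(tz.InvalidInputError):
            tz.SyntheticConfig(grid_step=0.0)
        with pytest.raises(tz.InvalidInputError):
            tz.SyntheticConfig(precip_shape=-1.0)
        with pytest.raises(tz.InvalidInputError):
            tz.SyntheticConfig(drought_multiplier=1.5)
        with pytest.raises(tz.InvalidInputError):
            tz.SyntheticConfig(years=())


class TestGenerateClimateSeries:
    def test_bit_identical_under_same_config(self):
        cfg = tz.SyntheticConfig(grid_step=1.0, years=(2012, 2013), seed=9)
        a = tz.generate_climate_series(cfg).table
        b = tz.generate_climate_series(cfg).table
        pd.testing.assert_frame_equal(a, b)

    def test_mean_temperature_without_gradient_or_drought(self):
        cfg = tz.SyntheticConfig(
            grid_step=0.6, years=(2000,), seed=4, tair_gradient=0.0, drought_years=()
        )
        field = tz.generate_climate_series(cfg)
        tair = field.table["tair_c"]
        # spatial mean within 3 standard errors of the configured base; the
        # field is correlated, so use the full sill as a conservative scale
        se = np.sqrt(cfg.variogram.sill)  # upper bound: treats points as one draw
        assert abs(tair.mean() - cfg.base_tair) < 3 * se

    def test_drought_year_precipitation_is_scaled(self):
        cfg = tz.SyntheticConfig(
            grid_step=0.5, years=(2001, 2002), seed=12, drought_years=(2002,),
            drought_multiplier=0.5,
        )
        field = tz.generate_climate_series(cfg)
        by_year = field.table.groupby("year")["precip_mm"].mean()
        assert by_year[2002] / by_year[2001] == pytest.approx(0.5, rel=0.05)

    def test_wind_speed_is_positive(self, small_field):
        assert small_field.table["ws_ms"].min() > 0

    def test_latitudinal_gradient_has_configured_sign(self):
        cfg = tz.SyntheticConfig(grid_step=0.5, years=(2000,), seed=2, tair_gradient=0.5)
        t = tz.generate_climate_series(cfg).table
        corr = np.corrcoef(t["lat"], t["tair_c"])[0, 1]
        assert corr > 0.5

    def test_gamma_parameter_recovery(self):
        cfg = tz.SyntheticConfig(grid_step=0.5, years=(2000,), seed=21, drought_years=())
        field = tz.generate_climate_series(cfg)
        precip = field.table["precip_mm"].to_numpy()
        assert precip.size >= 200
        fit = tz.fit_gamma_mle(precip)
        assert fit.alpha == pytest.approx(cfg.precip_shape, rel=0.15)
        assert fit.beta == pytest.approx(cfg.precip_scale, rel=0.15)

    def test_variogram_recovery_multi_seed(self):
        """Average fitted sill/range over 10 seeds recover the generating
        model within 15%/25%."""
        truth = tz.VariogramModel("spherical", 0.05, 0.95, 0.8)
        sills, ranges = [], []
        for s in range(10):
            cfg = tz.SyntheticConfig(
                grid_step=0.28,
                grid_extent=(-47.5, -41.8, -10.2, -4.0),
                years=(2000,),
                seed=s,
                tair_gradient=0.0,
                drought_years=(),
                variogram=truth,
            )
            t = tz.generate_climate_series(cfg).table
            coords = t[["lon", "lat"]].to_numpy()
            emp = tz.empirical_semivariogram(coords, t["tair_c"].to_numpy())
            fit = tz.fit_variogram(emp, "spherical")
            sills.append(fit.sill)
            ranges.append(fit.range_a)
        assert np.mean(sills) == pytest.approx(truth.sill, rel=0.15)
        assert np.mean(ranges) == pytest.approx(truth.range_a, rel=0.25)

    def test_region_labels_cover_five_mesoregions(self, small_field):
        assert set(small_field.table["region"]) == {"north", "south", "east", "west", "central"}
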