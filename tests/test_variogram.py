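"""Unit tests for semivariogram estimation and variogram model fitting."""

import numpy as np
import pytest

import thermozone as tz
from thermozone.variogram import FAMILIES


def brute_force_semivariogram(coords, values, n_lags, max_dist):
    """Independent O(n²) double-loop estimator used as the oracle."""
    n = len(values)
    width = max_dist / n_lags
    sums = np.zeros(n_lags)
    counts = np.zeros(n_lags, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d = np.sqrt(((coords[i] - coords[j]) ** 2).sum())
            if d > max_dist:
                continue
            b = min(int(d / width), n_lags - 1)
            sums[b] += 0.5 * (values[i] - values[j]) ** 2
            counts[b] += 1
    gamma = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return gamma, counts


class TestEmpiricalSemivariogram:
    def test_equal_values_give_zero_semivariance(self):
        emp = tz.empirical_semivariogram([[0.0, 0.0], [1.0, 0.0]], [5.0, 5.0], n_lags=1, max_dist=2.0)
        assert emp.gamma_hat[0] == 0.0
        assert emp.pair_counts[0] == 1

    def test_single_pair_semivariance(self):
        # one pair with difference 2 -> gamma = (1/2)·2² / 1 = 2
        emp = tz.empirical_semivariogram([[0.0, 0.0], [1.0, 0.0]], [0.0, 2.0], n_lags=1, max_dist=2.0)
        assert emp.gamma_hat[0] == pytest.approx(2.0)

    def test_matches_brute_force_oracle(self, rng):
        coords = rng.uniform(0, 1, (20, 2))
        values = rng.normal(size=20)
        emp = tz.empirical_semivariogram(coords, values, n_lags=6, max_dist=0.8)
        gamma, counts = brute_force_semivariogram(coords, values, 6, 0.8)
        np.testing.assert_array_equal(emp.pair_counts, counts)
        np.testing.assert_allclose(emp.gamma_hat[counts > 0], gamma[counts > 0], rtol=1e-12)

    def test_default_cutoff_is_half_max_distance(self, rng):
        coords = rng.uniform(0, 2, (30, 2))
        emp = tz.empirical_semivariogram(coords, rng.normal(size=30))
        from scipy.spatial.distance import pdist

        assert emp.max_dist == pytest.approx(pdist(coords).max() / 2)

    def test_coincident_points_rejected(self):
        with pytest.raises(tz.DegenerateGeometryError):
            tz.empirical_semivariogram([[1.0, 1.0], [1.0, 1.0]], [0.0, 1.0])

    def test_empty_bins_flagged(self):
        coords = [[0.0, 0.0], [0.1, 0.0], [5.0, 0.0]]
        emp = tz.empirical_semivariogram(coords, [0.0, 1.0, 2.0], n_lags=10, max_dist=6.0)
        assert np.isnan(emp.gamma_hat[emp.pair_counts == 0]).all()


class TestModelSemivariance:
    def test_spherical_reaches_sill_at_range(self):
        m = tz.VariogramModel("spherical", 0.2, 0.8, 2.0)
        assert tz.model_semivariance(m, 2.0) == pytest.approx(1.0)
        assert tz.model_semivariance(m, 5.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("family", ["exponential", "gaussian"])
    def test_practical_range_convention(self, family):
        # both families reach C0 + C·(1 − e⁻³) ≈ C0 + 0.95021·C at h = a
        m = tz.VariogramModel(family, 0.2, 0.8, 2.0)
        expected = 0.2 + 0.8 * (1 - np.exp(-3))
        assert tz.model_semivariance(m, 2.0) == pytest.approx(expected, abs=1e-12)

    def test_origin_is_exactly_zero(self):
        for family in FAMILIES:
            m = tz.VariogramModel(family, 0.3, 0.7, 1.0)
            assert tz.model_semivariance(m, 0.0) == 0.0

    @pytest.mark.parametrize("family", FAMILIES)
    def test_sill_is_the_large_distance_limit(self, family):
        m = tz.VariogramModel(family, 0.15, 0.85, 0.5)
        assert tz.model_semivariance(m, 1e6) == pytest.approx(m.sill, rel=1e-9)

    def test_negative_distance_rejected(self):
        m = tz.VariogramModel("spherical", 0.0, 1.0, 1.0)
        with pytest.raises(tz.InvalidInputError):
            tz.model_semivariance(m, -0.1)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(tz.InvalidInputError):
            tz.VariogramModel("spherical", -0.1, 1.0, 1.0)
        with pytest.raises(tz.InvalidInputError):
            tz.VariogramModel("spherical", 0.1, 1.0, 0.0)
        with pytest.raises(tz.InvalidInputError):
            tz.VariogramModel("cubic", 0.1, 1.0, 1.0)


class TestFitVariogram:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_recovers_exact_model_values(self, family):
        """Noise-free gamma values generated from a known model are recovered
        to high relative accuracy."""
        truth = tz.VariogramModel(family, 0.15, 0.85, 0.4)
        h = np.linspace(0.05, 1.2, 12)
        emp = tz.EmpiricalVariogram(
            lag_centers=h,
            gamma_hat=tz.model_semivariance(truth, h),
            pair_counts=np.full(12, 50),
            max_dist=1.2,
        )
        fit = tz.fit_variogram(emp, family)
        assert fit.nugget == pytest.approx(truth.nugget, abs=1e-4)
        assert fit.partial_sill == pytest.approx(truth.partial_sill, rel=1e-4)
        assert fit.range_a == pytest.approx(truth.range_a, rel=1e-4)

    def test_flat_variogram_is_pure_nugget(self):
        emp = tz.EmpiricalVariogram(
            lag_centers=np.linspace(0.1, 1.0, 8),
            gamma_hat=np.full(8, 0.5),
            pair_counts=np.full(8, 30),
            max_dist=1.0,
        )
        with pytest.warns(tz.NoSpatialStructureWarning):
            fit = tz.fit_variogram(emp, "spherical")
        assert fit.sill == pytest.approx(0.5, rel=1e-6)
        assert fit.partial_sill == pytest.approx(0.0, abs=1e-6)

    def test_needs_four_occupied_lags(self):
        emp = tz.EmpiricalVariogram(
            lag_centers=np.array([0.1, 0.2, 0.3]),
            gamma_hat=np.array([0.1, 0.2, 0.3]),
            pair_counts=np.array([5, 5, 5]),
            max_dist=0.3,
        )
        with pytest.raises(tz.InvalidInputError):
            tz.fit_variogram(emp, "spherical")

    def test_simulation_recovery_single_realization(self, rng, spherical_model):
        """Fitting the generating family to one large realization recovers the
        sill within 30% and the range within 50% (realization variance)."""
        truth = tz.VariogramModel("spherical", 0.1, 0.9, 0.15)
        coords = rng.uniform(0, 1, (1500, 2))
        values = tz.generate_gaussian_random_field(truth, coords, rng=rng)
        fit = tz.fit_variogram(tz.empirical_semivariogram(coords, values), "spherical")
        assert fit.sill == pytest.approx(truth.sill, rel=0.30)
        assert fit.range_a == pytest.approx(truth.range_a, rel=0.50)
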