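"""Unit tests for cross-validation metrics, model selection, DSD and normality."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import thermozone as tz


def naive_metrics(observed, predicted, sigma):
    """Explicit-loop recomputation of the five cross-validation metrics."""
    n = len(observed)
    me = sum(predicted[i] - observed[i] for i in range(n)) / n
    mse = sum((predicted[i] - observed[i]) / sigma[i] for i in range(n)) / n
    ase = sum(sigma[i] for i in range(n)) / n
    rmse = math.sqrt(sum((predicted[i] - observed[i]) ** 2 for i in range(n)) / n)
    rmsse = math.sqrt(sum(((predicted[i] - observed[i]) / sigma[i]) ** 2 for i in range(n)) / n)
    return me, mse, ase, rmse, rmsse


class TestCrossValidationMetrics:
    def test_matches_naive_oracle(self, rng):
        for _ in range(20):
            n = rng.integers(5, 40)
            z = rng.normal(size=n)
            zhat = z + rng.normal(scale=0.3, size=n)
            s = rng.uniform(0.2, 1.0, size=n)
            cv = tz.cross_validation_metrics(z, zhat, s)
            me, mse, ase, rmse, rmsse = naive_metrics(z, zhat, s)
            assert cv.me == pytest.approx(me, abs=1e-10)
            assert cv.mse == pytest.approx(mse, abs=1e-10)
            assert cv.ase == pytest.approx(ase, abs=1e-10)
            assert cv.rmse == pytest.approx(rmse, abs=1e-10)
            assert cv.rmsse == pytest.approx(rmsse, abs=1e-10)

    def test_rmse_dominates_absolute_me(self, rng):
        for _ in range(20):
            z = rng.normal(size=30)
            zhat = z + rng.normal(size=30)
            s = rng.uniform(0.5, 2.0, size=30)
            cv = tz.cross_validation_metrics(z, zhat, s)
            assert cv.rmse >= abs(cv.me)

    def test_zero_sigma_rejected(self):
        with pytest.raises(tz.InvalidInputError):
            tz.cross_validation_metrics([1.0, 2.0], [1.0, 2.0], [0.0, 1.0])


class TestLooCrossValidate:
    def test_exact_interpolation_limit(self):
        """A noise-free linear surface with a zero-nugget model is recovered
        almost exactly by leave-one-out kriging."""
        model = tz.VariogramModel("spherical", 1e-6, 1.0, 3.0)
        g = np.linspace(0, 1, 5)
        gx, gy = np.meshgrid(g, g)
        coords = np.column_stack([gx.ravel(), gy.ravel()])
        values = 2.0 + 0.5 * coords[:, 0] + 0.25 * coords[:, 1]
        cv = tz.loo_cross_validate(coords, values, model, n_neighbors=None)
        # ordinary kriging is not drift-exact, so the residual interpolation
        # error is small but nonzero: well under 2% of the signal range
        assert abs(cv.me) < 1e-3
        assert cv.rmse < 0.05

    def test_matches_explicit_holdout_loop(self, rng, spherical_model):
        coords = rng.uniform(0, 1, (25, 2))
        values = tz.generate_gaussian_random_field(spherical_model, coords, rng=rng)
        cv = tz.loo_cross_validate(coords, values, spherical_model, n_neighbors=None)
        preds, sigmas = [], []
        for i in range(25):
            mask = np.arange(25) != i
            p = tz.ordinary_kriging(
                spherical_model, coords[mask], values[mask], coords[[i]], n_neighbors=None
            )
            preds.append(p.estimate[0])
            sigmas.append(p.std_error[0])
        ref = tz.cross_validation_metrics(values, np.array(preds), np.array(sigmas))
        assert cv.rmsse == pytest.approx(ref.rmsse, abs=1e-12)
        assert cv.me == pytest.approx(ref.me, abs=1e-12)

    def test_requires_three_points(self, spherical_model):
        with pytest.raises(tz.InvalidInputError):
            tz.loo_cross_validate(np.zeros((2, 2)), np.zeros(2), spherical_model)


class TestSelectModel:
    @staticmethod
    def _cv(me, rmse, mse, rmsse, ase, n=100):
        return tz.CrossValidation(me=me, mse=mse, ase=ase, rmse=rmse, rmsse=rmsse, n=n)

    def test_best_calibrated_family_wins(self):
        # cross-validation metrics of the three families for one annual
        # temperature-humidity field (spherical closest to RMSSE = 1)
        candidates = {
            "spherical": self._cv(-1.051e-4, 0.133694996, 0.000651064, 0.748842232, 0.178522544),
            "gaussian": self._cv(0.000106874, 0.193464814, 0.000758881, 0.657260615, 0.294165691),
            "exponential": self._cv(-0.00047885, 0.128458003, -0.001030727, 0.625094344, 0.205531904),
        }
        sel = tz.select_model(candidates)
        assert sel.family == "spherical"
        assert list(sel.ranking["family"]) == ["spherical", "gaussian", "exponential"]

    def test_identical_metrics_fall_back_to_family_order(self):
        cv = self._cv(0.0, 1.0, 0.0, 0.9, 1.0)
        sel = tz.select_model({"gaussian": cv, "exponential": cv, "spherical": cv})
        assert sel.family == "spherical"

    def test_tie_broken_by_rmse_ase_gap(self):
        a = self._cv(0.0, 1.0, 0.0, 0.9, 1.05)
        b = self._cv(0.0, 1.0, 0.0, 0.9, 1.30)
        sel = tz.select_model({"gaussian": a, "spherical": b})
        assert sel.family == "gaussian"

    def test_single_candidate(self):
        sel = tz.select_model({"exponential": self._cv(0.0, 1.0, 0.0, 0.5, 1.0)})
        assert sel.family == "exponential"

    def test_empty_candidates_rejected(self):
        with pytest.raises(tz.InvalidInputError):
            tz.select_model({})


class TestComputeDsd:
    def test_reference_ratio(self):
        # total sill 0.4263 with nugget 0.007121 -> 1.670% (strong dependence)
        m = tz.VariogramModel("spherical", 0.007121, 0.4263 - 0.007121, 9000.0)
        dep = tz.compute_dsd(m)
        assert round(dep.dsd_percent, 3) == 1.670
        assert dep.dsd_class == "strong"

    def test_no_nugget(self):
        dep = tz.compute_dsd(tz.VariogramModel("spherical", 0.0, 1.0, 1.0))
        assert dep.dsd_percent == 0.0
        assert dep.dsd_class == "strong"

    def test_pure_nugget(self):
        dep = tz.compute_dsd(tz.VariogramModel("spherical", 1.0, 0.0, 1.0))
        assert dep.dsd_percent == 100.0
        assert dep.dsd_class == "weak"

    @pytest.mark.parametrize(
        "pct, expected", [(24.99, "strong"), (25.0, "moderate"), (75.0, "moderate"), (75.01, "weak")]
    )
    def test_class_boundaries(self, pct, expected):
        m = tz.VariogramModel("spherical", pct, 100.0 - pct, 1.0)
        assert tz.compute_dsd(m).dsd_class == expected

    @given(
        c0=st.floats(0.001, 10),
        c=st.floats(0.001, 10),
        k=st.floats(0.01, 100),
    )
    @settings(max_examples=50, derandomize=True)
    def test_scale_invariance(self, c0, c, k):
        m1 = tz.VariogramModel("spherical", c0, c, 1.0)
        m2 = tz.VariogramModel("spherical", k * c0, k * c, 1.0)
        d1, d2 = tz.compute_dsd(m1), tz.compute_dsd(m2)
        assert d1.dsd_percent == pytest.approx(d2.dsd_percent, rel=1e-12)
        assert d1.dsd_class == d2.dsd_class

    def test_zero_sill_rejected(self):
        with pytest.raises(tz.InvalidInputError):
            tz.compute_dsd(tz.VariogramModel("spherical", 0.0, 0.0, 1.0))


class TestResidualNormality:
    def test_level_on_gaussian_samples(self):
        hits = sum(
            not tz.residual_normality(np.random.default_rng(s).normal(size=100)).non_normal
            for s in range(50)
        )
        assert hits >= 45  # p > 0.05 in at least 90% of null draws

    def test_power_on_lognormal_samples(self):
        hits = sum(
            tz.residual_normality(np.random.default_rng(s).lognormal(0, 1.0, size=100)).non_normal
            for s in range(50)
        )
        assert hits >= 45

    def test_constant_sample_rejected(self):
        with pytest.raises(tz.InvalidInputError):
            tz.residual_normality(np.full(10, 3.0))

    def test_unsupported_sizes_rejected(self):
        with pytest.raises(tz.InvalidInputError):
            tz.residual_normality([1.0, 2.0])
        with pytest.raises(tz.InvalidInputError):
            tz.residual_normality(np.random.default_rng(0).normal(size=5001))
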