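import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spherobridge.growthspace import (
    FitError,
    Normalization,
    RichardsParams,
    fit_richards,
    normalize_param_vectors,
    pca_feature_plane,
    quadrant_of,
    richards_eval,
)
from spherobridge.imaging import GrowthCurve


def sample_curve(params: RichardsParams, noise_sigma: float = 0.0,
                 seed: int = 0, n: int = 105) -> GrowthCurve:
    times = 2.0 + (3.0 / 24.0) * np.arange(n)  # 3 h grid over ~13 days
    values = richards_eval(params, times)
    if noise_sigma:
        rng = np.random.default_rng(seed)
        values = values * rng.lognormal(0.0, noise_sigma, size=n)
    return GrowthCurve(times_days=times, counts=np.maximum(values, 1.0))


class TestRichardsEval:
    def test_logistic_midpoint(self):
        p = RichardsParams(A=10.0, B=1.0, C=100.0, M=5.0, T=1.0)
        assert richards_eval(p, 5.0) == pytest.approx(10.0 + 50.0)

    def test_asymptotes(self):
        p = RichardsParams(A=3.0, B=2.0, C=500.0, M=8.0, T=0.7)
        assert richards_eval(p, -1e3) == pytest.approx(3.0, abs=1e-6)
        assert richards_eval(p, 1e3) == pytest.approx(503.0, abs=1e-6)

    def test_direct_value(self):
        p = RichardsParams(A=0.0, B=1.0, C=1000.0, M=8.0, T=1.0)
        assert richards_eval(p, 20.0) == pytest.approx(
            1000.0 / (1.0 + math.exp(-12.0)), rel=1e-9)

    def test_no_overflow_far_from_inflection(self):
        p = RichardsParams(A=1.0, B=50.0, C=1e4, M=8.0, T=0.2)
        values = richards_eval(p, np.array([-1e4, 1e4]))
        assert np.all(np.isfinite(values))

    @given(
        b=st.floats(0.05, 5.0), c=st.floats(1.0, 1e5),
        m=st.floats(0.0, 20.0), t=st.floats(0.05, 10.0),
    )
    @settings(deadline=None, max_examples=60)
    def test_monotone_in_time(self, b, c, m, t):
        p = RichardsParams(A=1.0, B=b, C=c, M=m, T=t)
        grid = np.linspace(m - 30.0, m + 30.0, 400)
        values = richards_eval(p, grid)
        assert np.all(np.diff(values) >= -1e-8 * c)


class TestFitRichards:
    def test_noiseless_round_trip(self):
        truth = RichardsParams(A=1.0, B=0.9, C=5000.0, M=7.5, T=1.3)
        fitted, rss = fit_richards(sample_curve(truth))
        assert fitted.B == pytest.approx(truth.B, rel=0.01)
        assert fitted.M == pytest.approx(truth.M, rel=0.01)
        assert rss < 1e-3 * truth.C

    def test_constant_curve_raises_degenerate_fit(self):
        curve = GrowthCurve(times_days=np.arange(10.0),
                            counts=np.full(10, 50.0))
        with pytest.raises(FitError):
            fit_richards(curve)

    def test_noisy_fit_recovers_rate_and_midpoint(self):
        truth = RichardsParams(A=1.0, B=0.8, C=4000.0, M=8.0, T=1.0)
        fitted, _ = fit_richards(sample_curve(truth, noise_sigma=0.05,
                                              seed=42))
        assert fitted.B == pytest.approx(truth.B, rel=0.10)
        assert fitted.M == pytest.approx(truth.M, rel=0.10)

    def test_deterministic_given_data(self):
        truth = RichardsParams(A=1.0, B=1.1, C=2000.0, M=6.0, T=0.8)
        curve = sample_curve(truth, noise_sigma=0.03, seed=5)
        p1, r1 = fit_richards(curve)
        p2, r2 = fit_richards(curve)
        assert p1 == p2 and r1 == r2


class TestNormalization:
    def test_columns_centred_and_unit_population_sd(self):
        cohort = [RichardsParams(1.0 + i, 0.5 + 0.1 * i, 100.0 * (i + 1),
                                 5.0 + i, 1.0 + 0.2 * i) for i in range(6)]
        z, norm = normalize_param_vectors(cohort)
        assert np.allclose(z.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(z.std(axis=0), 1.0, atol=1e-12)

    def test_zero_variance_parameter_centred_only(self, caplog):
        cohort = [RichardsParams(1.0, 0.5 + 0.1 * i, 100.0, 5.0 + i, 1.0)
                  for i in range(4)]
        z, norm = normalize_param_vectors(cohort)
        assert "zero variance" in caplog.text
        assert np.allclose(z[:, 0], 0.0)  # A was constant
        assert norm.scale[0] == 1.0

    def test_identical_cohort_all_zero(self, caplog):
        cohort = [RichardsParams(1.0, 0.5, 100.0, 5.0, 1.0)] * 3
        z, _ = normalize_param_vectors(cohort)
        assert np.allclose(z, 0.0)


class TestFeaturePlane:
    @staticmethod
    def _identity_norm() -> Normalization:
        return Normalization(mean=np.zeros(5), scale=np.ones(5))

    def test_contribution_rates_sum_to_100(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=(40, 5))
        z -= z.mean(axis=0)
        plane = pca_feature_plane(z, self._identity_norm())
        assert plane.contribution_rates.sum() == pytest.approx(100.0)
        assert plane.component_vectors @ plane.component_vectors.T \
            == pytest.approx(np.eye(2), abs=1e-10)

    def test_dominant_axis_recovered_from_diagonal_gaussian(self):
        rng = np.random.default_rng(7)
        variances = np.array([0.1, 0.1, 4.0, 0.1, 1.0])  # C and T dominate
        z = rng.normal(size=(500, 5)) * np.sqrt(variances)
        z -= z.mean(axis=0)
        plane = pca_feature_plane(z, self._identity_norm())
        # first component aligns with the variance-4 parameter (C)
        assert abs(plane.component_vectors[0, 2]) > 0.98
        total = variances.sum()
        assert plane.contribution_rates[0] == pytest.approx(
            100.0 * 4.0 / total, rel=0.08)
        assert plane.contribution_rates[1] == pytest.approx(
            100.0 * 1.0 / total, rel=0.12)

    def test_rank_deficient_cohort_rejected(self):
        direction = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        z = np.outer(np.array([-1.0, 0.0, 1.0]), direction)
        with pytest.raises(ValueError, match="rank"):
            pca_feature_plane(z, self._identity_norm())

    def test_scores_centred_and_projection_matches(self):
        cohort = [RichardsParams(1.0, 0.5 + 0.2 * i, 100.0 + 30.0 * (i % 3),
                                 5.0 + 0.7 * i, 1.0 + 0.1 * (i % 2))
                  for i in range(12)]
        z, norm = normalize_param_vectors(cohort)
        plane = pca_feature_plane(z, norm)
        assert np.allclose(plane.points.mean(axis=0), 0.0, atol=1e-10)
        for i, params in enumerate(cohort):
            assert np.allclose(plane.project(params), plane.points[i])

    def test_sign_convention_orients_c_and_b_loadings(self):
        rng = np.random.default_rng(3)
        z = rng.normal(size=(30, 5))
        z -= z.mean(axis=0)
        plane = pca_feature_plane(z, self._identity_norm())
        assert plane.component_vectors[0, 2] >= 0  # C on component 1
        assert plane.component_vectors[1, 1] >= 0  # B on component 2


class TestQuadrants:
    @pytest.mark.parametrize("point, expected", [
        ((1.0, 1.0), 1), ((-1.0, 1.0), 2), ((-1.0, -1.0), 3),
        ((1.0, -1.0), 4),
        ((0.0, 1.0), 1), ((0.0, -1.0), 3),
        ((1.0, 0.0), 1), ((-1.0, 0.0), 2),
        ((0.0, 0.0), 1),
    ])
    def test_sign_and_axis_tie_breaks(self, point, expected):
        assert quadrant_of(point) == expected
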