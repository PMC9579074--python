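"""Quantile mixtures, Fleishman polynomials and NORTA calibration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from semlrt.exceptions import CalibrationError, InfeasibleTargetError
from semlrt.mixtures import (
    COMPONENTS,
    fit_mixture_weights,
    fleishman_coefficients,
    fleishman_intermediate_corr,
    norta_intermediate_corr,
    norta_sample,
)


class TestComponents:
    @pytest.mark.parametrize(
        "name, kurt",
        [
            ("t4.1", 3 + 6 / (4.1 - 4)),  # Student t closed form: 63
            ("exponential", 9.0),
            ("normal", 3.0),
            ("uniform", 1.8),
        ],
    )
    def test_component_kurtosis(self, name, kurt):
        mix = fit_mixture_weights((name,), kurt)
        assert mix.kurtosis == pytest.approx(kurt, abs=1e-6)

    def test_component_moments_match_simulation(self):
        """Closed-form raw moments agree with plain Monte Carlo draws."""
        rng = np.random.default_rng(1)
        u = rng.uniform(size=200_000)
        for name in ("uniform", "normal", "exponential", "lognormal"):
            comp = COMPONENTS[name]
            draws = comp.ppf(u)
            assert np.mean(draws) == pytest.approx(comp.raw_moments[0], abs=0.02)
            assert np.mean(draws**2) == pytest.approx(comp.raw_moments[1], rel=0.05)

    def test_neg_lognormal_is_mirror(self):
        u = np.linspace(0.01, 0.99, 50)
        a = COMPONENTS["neg_lognormal"].ppf(u)
        b = -COMPONENTS["lognormal"].ppf(1 - u)
        assert np.allclose(a, b, atol=1e-10)


class TestFitMixtureWeights:
    def test_two_component_hits_target(self):
        mix = fit_mixture_weights(("t4.1", "uniform"), 3.0)
        assert mix.kurtosis == pytest.approx(3.0, abs=1e-8)
        assert mix.beta.sum() == pytest.approx(1.0)

    def test_variance_share_scales_target(self):
        # share 0.5 means the mixture itself must carry kurtosis 3 + 7/0.25
        mix = fit_mixture_weights(("lognormal", "exponential"), 10.0, variance_share=0.5)
        assert mix.kurtosis == pytest.approx(3 + 7 / 0.25, abs=1e-6)

    def test_three_component_constraint_met(self):
        mix = fit_mixture_weights(("cubic_normal", "uniform", "normal"), 3.0)
        assert mix.kurtosis == pytest.approx(3.0, abs=0.05)
        assert abs(mix.skewness) < 1e-6  # symmetric components

    def test_infeasible_target_reports_range(self):
        with pytest.raises(InfeasibleTargetError) as err:
            fit_mixture_weights(("uniform", "normal"), 40.0)
        assert err.value.achievable_range is not None

    def test_standardized_ppf_moments_by_simulation(self):
        mix = fit_mixture_weights(("lognormal", "exponential"), 17.0, variance_share=0.8)
        rng = np.random.default_rng(2)
        draws = mix.ppf(rng.uniform(size=2_000_000))
        assert np.mean(draws) == pytest.approx(0.0, abs=5e-3)
        assert np.var(draws) == pytest.approx(1.0, abs=2e-2)
        assert stats.kurtosis(draws, fisher=False) == pytest.approx(mix.kurtosis, rel=0.1)

    @given(st.floats(min_value=0.0, max_value=1.0))
    @settings(max_examples=25, deadline=None)
    def test_mixture_quantile_nondecreasing(self, beta_t):
        """Eq. of the quantile mixture: convex combinations of nondecreasing
        quantile functions are nondecreasing for any simplex weights."""
        u = np.linspace(1e-6, 1 - 1e-6, 513)
        comp_t = COMPONENTS["t4.1"].ppf(u)
        comp_u = COMPONENTS["uniform"].ppf(u)
        y = beta_t * comp_t + (1 - beta_t) * comp_u
        assert np.all(np.diff(y) >= -1e-12)


class TestFleishman:
    def test_identity_for_normal_targets(self):
        a, b, c, d = fleishman_coefficients(0.0, 3.0)
        assert (a, b, c, d) == pytest.approx((0.0, 1.0, 0.0, 0.0), abs=1e-8)

    def test_construction_constraints(self):
        a, b, c, d = fleishman_coefficients(1.5, 8.0)
        assert a == pytest.approx(-c)
        # variance equation holds by construction
        assert b**2 + 6 * b * d + 2 * c**2 + 15 * d**2 == pytest.approx(1.0, abs=1e-10)

    def test_moments_by_simulation(self):
        skew, kurt = 2.0, 17.0
        a, b, c, d = fleishman_coefficients(skew, kurt)
        rng = np.random.default_rng(3)
        z = rng.standard_normal(2_000_000)
        y = a + b * z + c * z**2 + d * z**3
        assert np.mean(y) == pytest.approx(0.0, abs=5e-3)
        assert np.var(y) == pytest.approx(1.0, abs=1e-2)
        assert stats.skew(y) == pytest.approx(skew, abs=0.1)
        assert stats.kurtosis(y, fisher=False) == pytest.approx(kurt, abs=0.6)

    def test_impossible_pair_rejected(self):
        with pytest.raises(InfeasibleTargetError):
            fleishman_coefficients(3.0, 4.0)  # violates kurt >= 1 + skew^2

    def test_intermediate_corr_recovers_target(self):
        coef = fleishman_coefficients(1.5, 10.0)
        rho = fleishman_intermediate_corr(0.4, coef, coef)
        rng = np.random.default_rng(4)
        z1 = rng.standard_normal(500_000)
        z2 = rho * z1 + math.sqrt(1 - rho**2) * rng.standard_normal(500_000)
        a, b, c, d = coef
        y1 = a + b * z1 + c * z1**2 + d * z1**3
        y2 = a + b * z2 + c * z2**2 + d * z2**3
        assert np.corrcoef(y1, y2)[0, 1] == pytest.approx(0.4, abs=0.01)


class TestNorta:
    def test_normal_marginals_identity_transform(self):
        target = np.array([[1.0, 0.55], [0.55, 1.0]])
        rho = norta_intermediate_corr(0.55, COMPONENTS["normal"].ppf, COMPONENTS["normal"].ppf)
        assert rho == pytest.approx(0.55, abs=1e-4)
        sample = norta_sample(target, COMPONENTS["normal"].ppf, 200_000, rng=5)
        assert np.corrcoef(sample.T)[0, 1] == pytest.approx(0.55, abs=0.01)

    def test_identity_target_gives_independence(self):
        mix = fit_mixture_weights(("lognormal", "exponential"), 10.0)
        sample = norta_sample(np.eye(3), mix.ppf, 100_000, rng=6)
        off = np.corrcoef(sample.T)[np.triu_indices(3, 1)]
        assert np.all(np.abs(off) < 0.015)

    def test_lognormal_needs_larger_intermediate_corr(self):
        """Heavy right skew attenuates correlations, so the intermediate
        normal correlation must exceed the target."""
        ppf = COMPONENTS["lognormal"].ppf
        mean, var = math.e**0.5, math.e**2 - math.e

        def std_ppf(u):
            return (ppf(u) - mean) / math.sqrt(var)

        rho = norta_intermediate_corr(0.5, std_ppf, std_ppf)
        assert rho > 0.5
        sample = norta_sample(
            np.array([[1.0, 0.5], [0.5, 1.0]]), std_ppf, 1_000_000, rng=7
        )
        assert np.corrcoef(sample.T)[0, 1] == pytest.approx(0.5, abs=0.01)

    def test_unreachable_correlation_raises(self):
        ppf = COMPONENTS["lognormal"].ppf
        mean, var = math.e**0.5, math.e**2 - math.e

        def std_ppf(u):
            return (ppf(u) - mean) / math.sqrt(var)

        # lognormal pairs cannot be correlated below (1/e - 1)/(e - 1) ~ -0.37
        with pytest.raises(CalibrationError):
            norta_intermediate_corr(-0.9, std_ppf, std_ppf)
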