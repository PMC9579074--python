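"""Moment matrices, eigenvalue weights and the corrected statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from semlrt import (
    compute_statistics,
    eigen_weights,
    fit_ml,
    gamma_adf,
    mixture_pvalue,
    normal_theory_weight,
    residual_u,
    trace_powers,
)
from semlrt.cfa import delta_jacobian, misspecified_spec
from semlrt.corrections import ScalingFactors, t_m, t_mb, t_mv1, t_mv2, t_ms


@pytest.fixture(scope="module")
def fitted(pop):
    rng = np.random.default_rng(42)
    data = rng.multivariate_normal(np.zeros(15), pop.sigma0, size=800, method="cholesky")
    spec = misspecified_spec()
    fit = fit_ml(spec, np.cov(data.T), n=800)
    gamma = gamma_adf(data)
    w_mat = normal_theory_weight(fit.sigma)
    delta = delta_jacobian(spec, fit.theta)
    return dict(data=data, fit=fit, gamma=gamma, w=w_mat, delta=delta, spec=spec)


class TestGammaAdf:
    def test_univariate_normal_variance_of_s2(self):
        rng = np.random.default_rng(0)
        gamma = gamma_adf(rng.standard_normal((400_000, 1)))
        assert gamma[0, 0] == pytest.approx(2.0, abs=0.05)

    def test_consistent_with_normal_theory(self, pop):
        rng = np.random.default_rng(1)
        data = rng.multivariate_normal(np.zeros(15), pop.sigma0, size=300_000,
                                       method="cholesky")
        gamma = gamma_adf(data)
        w_true = normal_theory_weight(pop.sigma0)
        assert np.abs(gamma - w_true).max() < 0.1

    def test_constant_column_degenerates(self):
        rng = np.random.default_rng(2)
        data = np.column_stack([rng.standard_normal(500), np.ones(500)])
        gamma = gamma_adf(data)
        assert np.allclose(gamma[1:, :], 0.0) and np.allclose(gamma[:, 1:], 0.0)

    def test_small_n_warns(self):
        rng = np.random.default_rng(3)
        with pytest.warns(RuntimeWarning):
            gamma_adf(rng.standard_normal((10, 15)))


class TestNormalTheoryWeight:
    def test_identity_covariance_entries(self):
        w_mat = normal_theory_weight(np.eye(3))
        diag = np.diag(w_mat)
        # variance rows get 2, covariance rows get 1; everything else 0
        assert sorted(diag.tolist()) == [1.0, 1.0, 1.0, 2.0, 2.0, 2.0]
        assert np.allclose(w_mat, np.diag(diag))

    def test_positive_definite(self, pop):
        w_mat = normal_theory_weight(pop.sigma0)
        assert np.linalg.eigvalsh(w_mat).min() > 0


class TestResidualU:
    def test_annihilates_jacobian(self, fitted):
        u_mat = residual_u(fitted["w"], fitted["delta"])
        assert np.abs(u_mat @ fitted["delta"]).max() < 1e-8

    def test_idempotent_in_w_metric(self, fitted):
        u_mat = residual_u(fitted["w"], fitted["delta"])
        assert np.allclose(u_mat @ fitted["w"] @ u_mat, u_mat, atol=1e-8)

    def test_trace_uw_equals_df(self, fitted):
        u_mat = residual_u(fitted["w"], fitted["delta"])
        assert np.trace(u_mat @ fitted["w"]) == pytest.approx(87, abs=1e-6)

    def test_rank_is_df(self, fitted):
        u_mat = residual_u(fitted["w"], fitted["delta"])
        assert np.linalg.matrix_rank(u_mat, tol=1e-8) == 87

    def test_empty_delta_returns_w_inverse(self, fitted):
        u_mat = residual_u(fitted["w"], np.zeros((120, 0)))
        assert np.allclose(u_mat, np.linalg.inv(fitted["w"]), atol=1e-8)


class TestEigenWeights:
    def test_gamma_equals_w_gives_unit_weights(self, fitted):
        u_mat = residual_u(fitted["w"], fitted["delta"])
        w = eigen_weights(u_mat, fitted["w"], 87)
        assert np.allclose(w, 1.0, atol=1e-6)

    def test_trace_identities(self, fitted):
        u_mat = residual_u(fitted["w"], fitted["delta"])
        t1, t2, t3 = trace_powers(u_mat, fitted["gamma"])
        w = eigen_weights(u_mat, fitted["gamma"], 87)
        assert w.sum() == pytest.approx(t1, abs=1e-8 * abs(t1))
        assert (w**2).sum() == pytest.approx(t2, abs=1e-8 * abs(t2))
        assert (w**3).sum() == pytest.approx(t3, abs=1e-6 * abs(t3))


class TestScaledStatistics:
    def _scal(self, weights, df):
        w = np.asarray(weights, dtype=float)
        return ScalingFactors(df, float(w.sum()), float((w**2).sum()), float((w**3).sum()))

    def test_unit_weights_collapse_all(self):
        """With all weights one, the seven statistics and p-values coincide."""
        scal = self._scal(np.ones(87), 87)
        stats_map = compute_statistics(100.0, scal, 200, 15, 3, weights=np.ones(87))
        bart = 1 - (2 * 15 + 4 * 3 + 5) / (6 * 199)
        for name, stat in stats_map.items():
            if name == "MB":
                assert stat.value == pytest.approx(100.0 * bart)
            else:
                assert stat.value == pytest.approx(100.0, abs=1e-9)
        pvals = {n: s.pvalue for n, s in stats_map.items() if n != "MB"}
        assert np.ptp(list(pvals.values())) < 1e-9

    def test_constant_weights_scale(self):
        scal = self._scal(np.full(87, 2.0), 87)
        assert t_m(100.0, scal.trace1, 87).value == pytest.approx(50.0)
        mv1 = t_mv1(100.0, scal.trace1, scal.trace2)
        assert mv1.df == pytest.approx(87)
        assert mv1.value == pytest.approx(50.0)
        ms = t_ms(100.0, scal.trace1, scal.trace2, scal.trace3)
        assert ms.df == pytest.approx(87)
        assert ms.value == pytest.approx(50.0)

    def test_bartlett_factor_value(self):
        stat = t_mb(t_m(100.0, 87.0, 87), p=15, h=3, n=200)
        assert stat.value / 100.0 == pytest.approx(1 - 47 / 1194, abs=1e-12)

    def test_bartlett_factor_monotone_in_n(self):
        base = t_m(100.0, 87.0, 87)
        vals = [t_mb(base, 15, 3, n).value for n in (100, 200, 400, 10**6)]
        assert np.all(np.diff(vals) > 0)
        assert vals[-1] == pytest.approx(100.0, abs=0.01)

    def test_bartlett_rejects_absurd_n(self):
        with pytest.raises(ValueError):
            t_mb(t_m(100.0, 87.0, 87), p=15, h=3, n=5)

    @given(
        st.lists(st.floats(min_value=0.05, max_value=50.0), min_size=5, max_size=87)
    )
    @settings(max_examples=50, deadline=None)
    def test_mv1_df_bounded_by_df(self, weights):
        """d = (sum w)^2 / sum w^2 <= df by Cauchy-Schwarz."""
        w = np.array(weights)
        df = len(w)
        stat = t_mv1(10.0, float(w.sum()), float((w**2).sum()))
        assert stat.df <= df + 1e-9

    @given(
        st.lists(st.floats(min_value=0.01, max_value=20.0), min_size=5, max_size=87),
        st.floats(min_value=0.0, max_value=30.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_mv2_nonnegative_with_valid_pvalue(self, weights, t_raw):
        """Cauchy-Schwarz gives tr(UG)^2 <= df tr[(UG)^2], so the shift never
        exceeds df and T_MV2 stays nonnegative for nonnegative T_ML; its
        upper-tail p-value is always well defined."""
        w = np.array(weights)
        scal = self._scal(w, len(w))
        stat = t_mv2(t_raw, len(w), scal.trace1, scal.trace2)
        assert stat.value >= -1e-9
        assert 0.0 <= stat.pvalue <= 1.0

    def test_mv2_moment_matching(self):
        """If T_ML has the mixture's mean/variance, T_MV2 has mean df and
        variance 2df (checked by simulating the mixture)."""
        rng = np.random.default_rng(8)
        w = rng.uniform(0.5, 2.0, 87)
        scal = self._scal(w, 87)
        draws = rng.chisquare(1.0, size=(100_000, 87)) @ w
        mv2 = draws * np.sqrt(87 / scal.trace2) + 87 - np.sqrt(87 * scal.trace1**2 / scal.trace2)
        assert np.mean(mv2) == pytest.approx(87, abs=0.5)
        assert np.var(mv2) == pytest.approx(2 * 87, rel=0.05)

    def test_ms_v_from_weights_matches_traces(self):
        rng = np.random.default_rng(9)
        w = rng.uniform(0.2, 3.0, 87)
        scal = self._scal(w, 87)
        v_traces = scal.trace2**3 / scal.trace3**2
        assert t_ms(50.0, scal.trace1, scal.trace2, scal.trace3).df == pytest.approx(
            v_traces, abs=1e-8
        )


class TestMixturePvalue:
    def test_unit_weights_equal_chi_square(self):
        for t in (60.0, 87.0, 120.0):
            assert mixture_pvalue(t, np.ones(87)) == pytest.approx(
                stats.chi2.sf(t, 87), abs=1e-10
            )

    def test_single_weight_scaling(self):
        assert mixture_pvalue(5.0, np.array([2.0])) == pytest.approx(
            stats.chi2.sf(2.5, 1), abs=1e-8
        )

    def test_matches_monte_carlo_oracle(self):
        rng = np.random.default_rng(10)
        w = rng.uniform(0.3, 2.5, 87)
        draws = rng.chisquare(1.0, size=(1_000_000, 87)) @ w
        for q in (0.90, 0.95, 0.99):
            t = float(np.quantile(draws, q))
            mc = float((draws > t).mean())
            se = np.sqrt(mc * (1 - mc) / 1_000_000)
            assert mixture_pvalue(t, w) == pytest.approx(mc, abs=3 * se)

    def test_all_zero_weights_rejected(self):
        from semlrt.exceptions import SemlrtError

        with pytest.raises(SemlrtError):
            mixture_pvalue(1.0, np.zeros(5))
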