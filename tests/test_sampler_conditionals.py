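"""Each full conditional against an independent brute-force oracle.

Conjugate conditionals are checked two ways: the closed form the sampler uses
is compared pointwise with a dense grid evaluation of the unnormalised joint
(total variation at quadrature accuracy), and the actual draws are compared
with the closed-form distribution (KS / moment checks on large replicated
draws).  The replication trick: the updates are vectorised over clinics, so a
single call on one clinic's data copied M times yields M iid draws.
"""

import numpy as np
import pytest
from scipy import stats

from cdid.data_model import DesignMatrix, build_block_covariance
from cdid.priors import IGHyper
from cdid.sampler import (ClinicData, GibbsState, clinic_mean_posterior,
                          coefficient_posterior, draw_variance, equal_tail_ci,
                          update_clinic_means, update_covariate_params,
                          update_covariate_params_full,
                          update_outcome_variances, update_system_effects)


def _state(J, sigma2=0.8, tau2=0.7, lambda2=1.3, **kw):
    base = dict(mu09=np.zeros(J), mudiff=np.zeros(J),
                sigma2=np.full(J, sigma2), Theta=np.zeros(1),
                ThetaTilde=np.zeros(1), psi=np.zeros(1), upsilon=np.zeros(1),
                tau2=tau2, lambda2=lambda2, zeta2=1.0, omega2=1.0)
    base.update(kw)
    return GibbsState(**base)


def _single_clinic_data(y09, y12, reps=1):
    y09, y12 = np.asarray(y09, float), np.asarray(y12, float)
    return ClinicData(
        system=np.zeros(reps, dtype=int),
        n09=np.full(reps, y09.size), n12=np.full(reps, y12.size),
        sum09=np.full(reps, y09.sum()), sum12=np.full(reps, y12.sum()),
        sumsq09=np.full(reps, (y09 ** 2).sum()),
        sumsq12=np.full(reps, (y12 ** 2).sum()))


class TestClinicMeanConditional:
    y09 = [6.8, 8.1]
    y12 = [7.9, 8.6, 9.4]

    def test_closed_form_matches_2d_grid_oracle(self):
        """TV between the sampler's bivariate normal and a dense grid
        evaluation of the joint restricted to (mu2009, mudiff) is < 0.01."""
        data = _single_clinic_data(self.y09, self.y12)
        st_ = _state(1)
        mb, md = np.array([7.0]), np.array([1.2])
        m1, m2, c11, c12, c22 = (float(v[0]) for v in
                                 clinic_mean_posterior(st_, data, mb, md))
        s1, s2 = np.sqrt(c11), np.sqrt(c22)
        g1 = np.linspace(m1 - 6 * s1, m1 + 6 * s1, 401)
        g2 = np.linspace(m2 - 6 * s2, m2 + 6 * s2, 401)
        G1, G2 = np.meshgrid(g1, g2, indexing="ij")
        sig2, lam2, tau2 = 0.8, 1.3, 0.7
        n09, n12 = len(self.y09), len(self.y12)
        S09, S12 = np.sum(self.y09), np.sum(self.y12)
        SS = np.sum(np.square(self.y09)) + np.sum(np.square(self.y12))
        M12 = G1 + G2
        logf = (-(SS - 2 * G1 * S09 + n09 * G1 ** 2
                  - 2 * M12 * S12 + n12 * M12 ** 2) / (2 * sig2)
                - (G1 - mb[0]) ** 2 / (2 * lam2) - (G2 - md[0]) ** 2 / (2 * tau2))
        grid = np.exp(logf - logf.max())
        grid /= grid.sum()
        rho = c12 / (s1 * s2)
        z1 = (G1 - m1) / s1
        z2 = (G2 - m2) / s2
        logg = -(z1 ** 2 - 2 * rho * z1 * z2 + z2 ** 2) / (2 * (1 - rho ** 2))
        gauss = np.exp(logg - logg.max())
        gauss /= gauss.sum()
        assert 0.5 * np.abs(grid - gauss).sum() < 0.01

    def test_draws_match_closed_form_moments(self, rng):
        M = 200_000
        data = _single_clinic_data(self.y09, self.y12, reps=M)
        st_ = _state(M)
        mb, md = np.full(M, 7.0), np.full(M, 1.2)
        m1, m2, c11, c12, c22 = clinic_mean_posterior(st_, data, mb, md)
        d1, d2 = update_clinic_means(st_, data, mb, md, rng)
        tol = 5.0 / np.sqrt(M)
        assert d1.mean() == pytest.approx(m1[0], abs=tol * np.sqrt(c11[0]))
        assert d2.mean() == pytest.approx(m2[0], abs=tol * np.sqrt(c22[0]))
        assert np.cov(d1, d2) == pytest.approx(
            np.array([[c11[0], c12[0]], [c12[0], c22[0]]]), rel=0.05)

    def test_flat_prior_limit_recovers_conjugate_formula(self):
        """With tau2, lambda2 -> inf, mu2009 | mudiff has the textbook
        pooled-sample conditional mean and variance sigma^2/(n09+n12)."""
        data = _single_clinic_data(self.y09, self.y12)
        st_ = _state(1, tau2=1e12, lambda2=1e12)
        mudiff = 0.9
        m1, m2, c11, c12, c22 = (float(v[0]) for v in clinic_mean_posterior(
            st_, data, np.zeros(1), np.zeros(1)))
        cond_mean = m1 + (c12 / c22) * (mudiff - m2)
        cond_var = c11 - c12 ** 2 / c22
        n09, n12 = len(self.y09), len(self.y12)
        expect = (np.sum(self.y09) + np.sum(self.y12) - n12 * mudiff) / (n09 + n12)
        assert cond_mean == pytest.approx(expect, rel=1e-6)
        assert cond_var == pytest.approx(0.8 / (n09 + n12), rel=1e-6)

    def test_no_data_returns_regression_prior(self):
        data = _single_clinic_data([], [])
        st_ = _state(1)
        m1, m2, c11, c12, c22 = (float(v[0]) for v in clinic_mean_posterior(
            st_, data, np.array([7.0]), np.array([1.2])))
        assert (m1, m2) == pytest.approx((7.0, 1.2))
        assert (c11, c12, c22) == pytest.approx((1.3, 0.0, 0.7))


class TestOutcomeVarianceConditional:
    def test_no_data_draws_from_prior(self, rng):
        M = 100_000
        data = _single_clinic_data([], [], reps=M)
        st_ = _state(M)
        draws = update_outcome_variances(st_, data, IGHyper(3.0, 2.0), rng)
        ks = stats.kstest(draws, stats.invgamma(3.0, scale=2.0).cdf)
        assert ks.statistic < 0.01

    def test_conjugacy_shape_and_scale(self, rng):
        """Residual sum S with n total observations gives IG(a+n/2, b+S/2)."""
        y09, y12 = [1.0, 3.0], [4.0]
        data = _single_clinic_data(y09, y12, reps=100_000)
        st_ = _state(100_000)
        st_.mu09 = np.full(100_000, 2.0)
        st_.mudiff = np.full(100_000, 1.0)   # year-2012 mean 3.0
        a, b = 3.0, 2.0
        S = (1 - 2) ** 2 + (3 - 2) ** 2 + (4 - 3) ** 2
        draws = update_outcome_variances(st_, data, IGHyper(a, b), rng)
        ks = stats.kstest(draws, stats.invgamma(a + 1.5, scale=b + S / 2).cdf)
        assert ks.statistic < 0.01


class TestCoefficientPosterior:
    def test_dense_matrix_oracle_five_clinics_two_systems(self, rng):
        X = rng.standard_normal((5, 3))
        y = rng.standard_normal(5)
        system = np.array([0, 0, 0, 1, 1])
        tau2, zeta2 = 0.6, 0.3
        mean, cov = coefficient_posterior(y, X, tau2, zeta2, system)
        Sigma = build_block_covariance(tau2, zeta2, [3, 2]).to_dense()
        Si = np.linalg.inv(Sigma)
        B = np.linalg.inv(X.T @ Si @ X)
        assert cov == pytest.approx(B, rel=1e-9)
        assert mean == pytest.approx(B @ X.T @ Si @ y, rel=1e-9)

    def test_intercept_only_identity_sigma_is_sample_mean(self, rng):
        y = rng.standard_normal(8)
        X = np.ones((8, 1))
        mean, cov = coefficient_posterior(y, X, 1.0, 0.0, np.zeros(8, dtype=int))
        assert mean[0] == pytest.approx(y.mean())
        assert cov[0, 0] == pytest.approx(1.0 / 8)

    def test_zero_system_variance_equals_wls(self, rng):
        X = rng.standard_normal((6, 2))
        y = rng.standard_normal(6)
        tau2 = 0.4
        mean, cov = coefficient_posterior(y, X, tau2, 0.0,
                                          np.array([0, 0, 1, 1, 2, 2]))
        B = np.linalg.inv(X.T @ X / tau2)
        assert cov == pytest.approx(B, rel=1e-9)
        assert mean == pytest.approx(B @ X.T @ y / tau2, rel=1e-9)

    def test_collinear_columns_raise(self):
        X = np.ones((4, 2))  # duplicated intercept
        with pytest.raises(np.linalg.LinAlgError):
            mean, cov = coefficient_posterior(np.zeros(4), X, 1.0, 0.0,
                                              np.zeros(4, dtype=int))
            np.linalg.cholesky(cov)


class TestSystemEffectConditional:
    def test_grid_oracle_three_clinic_system(self, rng):
        """The psi conditional matches a 1-D grid evaluation of
        prod_j N(r_j | psi, tau2) * N(psi | 0, zeta2)."""
        resid = np.array([0.4, -0.2, 0.9])
        tau2, zeta2 = 0.5, 0.8
        M = 200_000
        draws = np.concatenate([
            update_system_effects(resid, np.zeros(3, dtype=int), 1, tau2, zeta2, rng)
            for _ in range(M // 50)])
        g = np.linspace(-3, 3, 2001)
        logf = -((resid[:, None] - g[None, :]) ** 2).sum(0) / (2 * tau2) \
            - g ** 2 / (2 * zeta2)
        f = np.exp(logf - logf.max())
        f /= np.trapezoid(f, g)
        grid_mean = np.trapezoid(g * f, g)
        grid_var = np.trapezoid((g - grid_mean) ** 2 * f, g)
        assert draws.mean() == pytest.approx(grid_mean, abs=0.01)
        assert draws.var() == pytest.approx(grid_var, rel=0.05)

    def test_flat_limit_posterior_mean_is_mean_residual(self, rng):
        resid = np.array([1.0, 2.0, 3.0])
        draws = np.array([
            update_system_effects(resid, np.zeros(3, dtype=int), 1, 0.3, 1e12, rng)[0]
            for _ in range(4000)])
        assert draws.mean() == pytest.approx(2.0, abs=0.03)

    def test_empty_system_draws_from_prior(self, rng):
        draws = update_system_effects(np.array([]), np.array([], dtype=int),
                                      5000, 0.3, 0.9, rng)
        assert draws.mean() == pytest.approx(0.0, abs=0.06)
        assert draws.var() == pytest.approx(0.9, rel=0.1)


class TestVarianceConditional:
    def test_two_unit_residuals_give_ig_1_1(self, rng):
        draws = np.array([draw_variance(2.0, 2, rng) for _ in range(50_000)])
        ks = stats.kstest(draws, stats.invgamma(1.0, scale=1.0).cdf)
        assert ks.statistic < 0.01

    def test_degenerate_residuals_floored_with_warning(self, rng):
        with pytest.warns(UserWarning, match="flooring"):
            v = draw_variance(0.0, 4, rng)
        assert 0 < v < 1e-9

    def test_no_residuals_improper_prior_holds_value(self, rng):
        with pytest.warns(UserWarning, match="holding"):
            assert draw_variance(0.0, 0, rng, current=0.37) == 0.37

    def test_proper_prior_conjugacy(self, rng):
        draws = np.array([draw_variance(3.0, 4, rng, prior_ab=(2.0, 1.0))
                          for _ in range(50_000)])
        ks = stats.kstest(draws, stats.invgamma(4.0, scale=2.5).cdf)
        assert ks.statistic < 0.01


class TestCovariateLatentConditional:
    def _data(self, x, n, reps):
        d = _single_clinic_data([], [], reps=reps)
        d.n09 = np.full(reps, n)
        d.n12 = np.full(reps, n)
        d.x_comm = np.full((reps, 2), x)
        d.x_fem = np.zeros((reps, 2), dtype=int)
        d.x_ivd = np.zeros((reps, 2), dtype=int)
        return d

    def test_uniform_prior_beta_conjugacy(self, rng):
        M = 100_000
        data = self._data(x=5, n=10, reps=M)
        st_ = _state(M, theta=np.full((M, 2), 0.5), gamma=np.full((M, 2), 0.5),
                     kappa=np.full((M, 2), 0.5))
        update_covariate_params(st_, data, rng)
        ks = stats.kstest(st_.theta[:, 0], stats.beta(6, 6).cdf)
        assert ks.statistic < 0.01

    def test_no_data_draws_uniform(self, rng):
        M = 50_000
        data = self._data(x=0, n=0, reps=M)
        st_ = _state(M, theta=np.full((M, 2), 0.5), gamma=np.full((M, 2), 0.5),
                     kappa=np.full((M, 2), 0.5))
        update_covariate_params(st_, data, rng)
        ks = stats.kstest(st_.theta[:, 1], stats.uniform.cdf)
        assert ks.statistic < 0.01

    def test_jeffreys_variant_shifts_beta(self, rng):
        M = 100_000
        data = self._data(x=5, n=10, reps=M)
        st_ = _state(M, theta=np.full((M, 2), 0.5), gamma=np.full((M, 2), 0.5),
                     kappa=np.full((M, 2), 0.5))
        update_covariate_params(st_, data, rng, beta_prior=(0.5, 0.5))
        ks = stats.kstest(st_.theta[:, 0], stats.beta(5.5, 5.5).cdf)
        assert ks.statistic < 0.01


class TestFullFeedbackLatent:
    def test_stationary_marginal_matches_grid_posterior(self, rng):
        """Metropolis target for theta includes the regression factor: on a
        single-clinic model the long-run marginal of theta(2012) must match a
        2-D grid posterior with the N(mudiff | alpha1 * theta_diff, tau2)
        factor included."""
        M = 20_000
        n, x09, x12 = 10, 3, 7
        mudiff_val, slope, tau2 = 1.0, 2.0, 0.5
        data = _single_clinic_data([], [], reps=M)
        data.n09 = np.full(M, n)
        data.n12 = np.full(M, n)
        data.x_comm = np.tile([x09, x12], (M, 1))
        design = DesignMatrix(X=np.column_stack([np.ones(M), np.full(M, 0.4)]),
                              columns=["intercept", "comm_diff"],
                              clinic_ids=None, system_index=np.zeros(M, dtype=int),
                              latent_columns={"comm_diff": 1})
        baseline = DesignMatrix(X=np.ones((M, 1)), columns=["intercept"],
                                clinic_ids=None,
                                system_index=np.zeros(M, dtype=int))
        st_ = _state(M, tau2=tau2,
                     mudiff=np.full(M, mudiff_val),
                     Theta=np.array([0.0, slope]), ThetaTilde=np.zeros(1),
                     theta=np.full((M, 2), 0.5))
        for _ in range(120):
            update_covariate_params_full(st_, data, design, baseline, rng,
                                         baseline_shared=False)
        g = np.linspace(1e-4, 1 - 1e-4, 400)
        T09, T12 = np.meshgrid(g, g, indexing="ij")
        logf = (x09 * np.log(T09) + (n - x09) * np.log1p(-T09)
                + x12 * np.log(T12) + (n - x12) * np.log1p(-T12)
                - (mudiff_val - slope * (T12 - T09)) ** 2 / (2 * tau2))
        f = np.exp(logf - logf.max())
        f /= f.sum()
        marg12 = f.sum(axis=0)
        edges = np.linspace(0, 1, 21)
        grid_bins = np.add.reduceat(marg12, np.searchsorted(g, edges[:-1]))
        grid_bins /= grid_bins.sum()
        emp, _ = np.histogram(st_.theta[:, 1], bins=edges, density=False)
        emp = emp / emp.sum()
        assert 0.5 * np.abs(emp - grid_bins).sum() < 0.05


class TestEqualTailCI:
    def test_linear_interpolation_convention(self):
        lo, hi = equal_tail_ci(np.arange(1.0, 1001.0))
        assert (lo, hi) == pytest.approx((25.975, 975.025))

    def test_constant_chain(self):
        assert equal_tail_ci(np.full(10, 3.3)) == (3.3, 3.3)

    def test_standard_normal_limit(self, rng):
        lo, hi = equal_tail_ci(rng.standard_normal(10**6))
        assert lo == pytest.approx(-1.96, abs=0.01)
        assert hi == pytest.approx(1.96, abs=0.01)

    def test_empty_chain_rejected(self):
        with pytest.raises(ValueError):
            equal_tail_ci(np.array([]))
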