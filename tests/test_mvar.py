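"""MVAR process simulation, estimation, and analytic/estimated PDC."""

import numpy as np
import pytest
from scipy import linalg

from pdcconnect.mvar import (MVAR, MVARProcess, UnstableModelError,
                             companion_matrix, spectral_radius)

from .conftest import random_stable_process


class TestSimulate:
    def test_white_noise_degenerate_case(self):
        """With all coefficients zero the output is plain white noise."""
        proc = MVARProcess(np.zeros((1, 3, 3)))
        y = proc.simulate(100_000, seed=0)
        cov = np.cov(y)
        assert np.abs(cov - np.eye(3)).max() < 0.05

    def test_autocovariance_matches_yule_walker(self, bivariate_process):
        """Sample lag-0/lag-1 autocovariances agree with the Lyapunov solution."""
        proc = bivariate_process
        n = 200_000
        y = proc.simulate(n, seed=1)
        # oracle: companion-form discrete Lyapunov equation for Gamma(0),
        # then Gamma(1) = A Gamma(0)
        a = companion_matrix(proc.coeffs)
        q = np.zeros_like(a)
        q[:2, :2] = proc.noise_cov
        gamma0 = linalg.solve_discrete_lyapunov(a, q)[:2, :2]
        gamma1 = (a @ linalg.solve_discrete_lyapunov(a, q))[:2, :2]
        samp0 = y @ y.T / n
        samp1 = y[:, 1:] @ y[:, :-1].T / (n - 1)
        # Monte-Carlo standard error of an autocovariance entry is O(1/sqrt(n))
        mc_se = 3.0 / np.sqrt(n) * 3
        assert np.abs(samp0 - gamma0).max() < mc_se
        assert np.abs(samp1 - gamma1).max() < mc_se

    def test_seeded_determinism(self, bivariate_process):
        y1 = bivariate_process.simulate(500, seed=7)
        y2 = bivariate_process.simulate(500, seed=7)
        np.testing.assert_array_equal(y1, y2)

    def test_unstable_model_rejected(self):
        proc = MVARProcess([[[1.05, 0.0], [0.0, 0.5]]])
        assert not proc.is_stable
        with pytest.raises(UnstableModelError):
            proc.simulate(100)

    def test_noise_cov_validation(self):
        with pytest.raises(ValueError, match="positive definite"):
            MVARProcess(np.zeros((1, 2, 2)), [[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            MVARProcess(np.zeros((1, 2, 2)), [[1.0, 0.5], [0.0, 1.0]])

    def test_accepted_models_stay_bounded(self):
        """Stability check agrees with empirical boundedness of simulations."""
        rng = np.random.default_rng(3)
        for _ in range(5):
            proc = random_stable_process(rng)
            y = proc.simulate(10_000, seed=rng)
            assert np.isfinite(y).all()
            assert np.abs(y).max() < 1e3


class TestAnalyticPDC:
    def test_diagonal_model_identity_pattern(self):
        proc = MVARProcess(np.stack([np.diag([0.5, 0.3, 0.2])]))
        for omega in (0.0, 1.0, np.pi):
            p = proc.analytic_pdc(omega)
            assert np.allclose(np.diag(p), 1.0)
            assert np.allclose(p - np.diag(np.diag(p)), 0.0)

    def test_hand_computed_bivariate_value(self, bivariate_process):
        """At omega=0, A_bar = I - C1 gives PDC(2,1) = 0.16/0.41 exactly."""
        p = bivariate_process.analytic_pdc(0.0)
        assert p[1, 0] == pytest.approx(0.16 / 0.41, abs=1e-12)
        assert p[0, 0] == pytest.approx(0.25 / 0.41, abs=1e-12)
        assert p[0, 1] == 0.0
        assert p[1, 1] == pytest.approx(1.0, abs=1e-12)

    def test_columns_sum_to_one_for_random_models(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            proc = random_stable_process(rng)
            omega = rng.uniform(0, np.pi)
            p = proc.analytic_pdc(omega)
            assert np.abs(p.sum(axis=0) - 1.0).max() < 1e-12

    def test_granger_nullity(self):
        """A structurally absent coupling w->v gives PDC(v,w) = 0 at all omega."""
        coeffs = np.array([[[0.5, 0.0, 0.2], [0.0, 0.4, 0.0], [0.3, 0.1, 0.3]]])
        proc = MVARProcess(coeffs)
        for omega in np.linspace(0, np.pi, 17):
            p = proc.analytic_pdc(omega)
            assert p[0, 1] == 0.0  # c_12 = 0 at every lag
            assert p[1, 0] == 0.0
            assert p[1, 2] == 0.0

    def test_omega_domain_error(self, bivariate_process):
        with pytest.raises(ValueError, match="omega"):
            bivariate_process.analytic_pdc(-0.1)
        with pytest.raises(ValueError, match="omega"):
            bivariate_process.analytic_pdc(4.0)


class TestSpectralTransform:
    def test_no_dynamics_gives_identity(self):
        res = MVAR(np.random.default_rng(0).standard_normal((2, 200))).fit(order=1)
        res.coeffs[:] = 0.0
        spec = res.spectral_transform(np.linspace(0, np.pi, 5))
        assert np.allclose(spec.a_bar, np.eye(2))

    def test_closed_forms_at_grid_ends(self, bivariate_process):
        c1 = bivariate_process.coeffs[0]
        a = bivariate_process.transfer([0.0, np.pi])
        assert np.allclose(a[0], np.eye(2) - c1)  # e^0 = 1
        assert np.allclose(a[1], np.eye(2) + c1)  # e^{-j pi} = -1
        assert np.abs(a[0].imag).max() == 0.0

    def test_empty_grid_error(self, bivariate_process):
        res = MVAR(bivariate_process.simulate(300, seed=0)).fit(order=1)
        with pytest.raises(ValueError, match="empty"):
            res.spectral_transform([])


class TestFit:
    def test_recovers_known_coefficients(self, bivariate_process):
        y = bivariate_process.simulate(100_000, seed=5)
        res = MVAR(y).fit(order=1)
        assert np.abs(res.coeffs[0] - bivariate_process.coeffs[0]).max() < 0.02

    def test_matches_statsmodels_var(self):
        """OLS coefficients agree with statsmodels' VAR on the same data."""
        from statsmodels.tsa.api import VAR

        rng = np.random.default_rng(2)
        proc = random_stable_process(rng, n_channels=3, order=2)
        y = proc.simulate(2_000, seed=9)
        res = MVAR(y).fit(order=2)
        sm_res = VAR((y - y.mean(axis=1, keepdims=True)).T).fit(2, trend="n")
        assert np.allclose(res.coeffs, sm_res.coefs, atol=1e-8)
        assert np.allclose(res.sigma_u, sm_res.sigma_u, atol=1e-8)

    def test_white_noise_null_coefficient_bound(self):
        """Estimated couplings on 512-sample white 18-channel segments stay at
        the OLS noise floor: each entry is ~N(0, 1/sqrt(507)), so the 99th
        percentile of the max over 324 entries sits near
        sigma * sqrt(2 ln 324) plus an extreme-value tail allowance."""
        rng = np.random.default_rng(21)
        maxima = []
        for _ in range(100):
            y = rng.standard_normal((18, 512))
            res = MVAR(y).fit(order=1)
            maxima.append(np.abs(res.coeffs).max())
        sigma = 1.0 / np.sqrt(512 - 1)  # OLS coef sd under the null, n_eff = 511
        bound = sigma * (np.sqrt(2 * np.log(2 * 324)) + 1.0)
        assert np.quantile(maxima, 0.99) <= bound
        assert np.median(maxima) >= 2 * sigma  # sanity: the floor is not zero

    def test_bic_selects_true_order(self):
        """BIC order selection recovers rho=3 on ample data."""
        rng = np.random.default_rng(8)
        proc = random_stable_process(rng, n_channels=3, order=3)
        hits = 0
        for i in range(20):
            y = proc.simulate(5_000, seed=100 + i)
            hits += MVAR(y).select_order(max_order=8) == 3
        assert hits >= 18

    def test_too_few_samples_error(self):
        with pytest.raises(ValueError, match="too few samples"):
            MVAR(np.random.default_rng(0).standard_normal((18, 50))).fit(order=5)

    def test_rank_deficient_error(self):
        data = np.zeros((3, 100))
        data[0] = np.random.default_rng(0).standard_normal(100)
        # duplicated channel makes the lagged regressor matrix rank-deficient
        data[1] = data[0]
        data[2] = np.random.default_rng(1).standard_normal(100)
        with pytest.raises(np.linalg.LinAlgError):
            MVAR(data).fit(order=2)

    def test_summary_mentions_key_quantities(self, bivariate_process):
        res = MVAR(bivariate_process.simulate(1_000, seed=0)).fit(order=1)
        text = res.summary()
        assert "order" in text and "stable" in text and "BIC" in text


def test_spectral_radius_matches_root_criterion():
    """Companion spectral radius < 1 iff all lag-polynomial roots lie outside
    the unit circle (checked via numpy's polynomial roots on det expansion)."""
    rng = np.random.default_rng(4)
    for _ in range(20):
        c = rng.normal(0, 0.6, (1, 2, 2))
        sr = spectral_radius(c)
        # det(I - C z) = 0  <=>  1/z is an eigenvalue of C
        eig = np.abs(np.linalg.eigvals(c[0])).max()
        assert (sr < 1) == (eig < 1)
        assert sr == pytest.approx(eig, rel=1e-9)
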