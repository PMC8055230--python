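"""Stick-breaking, concentration prior, kernels, GP covariances, LKJ transform."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.integrate import quad

from clonodyn.priors import (
    KERNEL_KINDS,
    KernelSpec,
    MultiOutputSpec,
    alpha_prior_logdensity,
    build_cov_gp0,
    build_cov_multi,
    corr_cholesky_from_unconstrained,
    kernel_g,
    lkj_logdensity_unconstrained,
    stick_breaking,
    trajectory_log_prior,
)


class TestStickBreaking:
    def test_single_stick_takes_everything(self):
        assert stick_breaking(np.array([0.3])) == pytest.approx([1.0])

    def test_hand_evaluated_product_formula(self):
        w = stick_breaking(np.array([0.5, 0.5, 0.5]))
        assert w == pytest.approx([0.5, 0.25, 0.25])

    @given(st.lists(st.floats(1e-6, 1 - 1e-6), min_size=1, max_size=25))
    @settings(max_examples=200, deadline=None)
    def test_exact_simplex(self, sticks):
        w = stick_breaking(np.array(sticks))
        assert np.all(w >= 0)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            stick_breaking(np.array([0.5, 1.0]))


class TestAlphaPrior:
    def test_values(self):
        assert alpha_prior_logdensity(0.0) == pytest.approx(0.0)
        assert alpha_prior_logdensity(1.0) == pytest.approx(-2 * np.log(2))

    def test_proper_prior(self):
        total, _ = quad(lambda a: np.exp(alpha_prior_logdensity(a)), 0, np.inf)
        assert total == pytest.approx(1.0, abs=1e-8)


class TestKernels:
    @pytest.mark.parametrize("kind", KERNEL_KINDS)
    def test_unit_at_zero_lag_and_symmetry(self, kind):
        assert kernel_g(kind, 1.7, 0.0) == pytest.approx(1.0)
        dt = np.linspace(0.01, 2, 17)
        np.testing.assert_allclose(kernel_g(kind, 1.7, dt), kernel_g(kind, 1.7, -dt))

    def test_exponential_hand_value(self):
        assert kernel_g("Exp", 1.0, 1.0) == pytest.approx(np.exp(-1.0))

    @pytest.mark.parametrize("kind", KERNEL_KINDS)
    def test_infinite_timescale_limit(self, kind):
        assert kernel_g(kind, 1e-12, 0.7) == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("kind", KERNEL_KINDS)
    def test_monotone_decay(self, kind):
        vals = kernel_g(kind, 2.0, np.linspace(0, 3, 200))
        assert np.all(np.diff(vals) < 0)

    def test_smoothness_ordering_at_small_lag(self):
        # 1 - g vanishes linearly for Exp but quadratically for ExpQ
        dt = 1e-3
        assert 1 - kernel_g("Exp", 1.0, dt) == pytest.approx(dt, rel=1e-2)
        assert 1 - kernel_g("ExpQ", 1.0, dt) == pytest.approx(dt**2 / 2, rel=1e-2)


class TestCovarianceBuilders:
    def test_gp0_single_sample(self):
        K = build_cov_gp0([0.0], KernelSpec("Exp", tau=1.0, amplitude_sq=2.0))
        assert K.shape == (1, 1)
        assert K[0, 0] == pytest.approx(2.0, rel=1e-5)

    def test_gp0_two_sample_elementwise(self):
        K = build_cov_gp0([0.0, 1.0], KernelSpec("Exp", tau=1.0, amplitude_sq=1.0))
        assert K[0, 1] == pytest.approx(np.exp(-1.0))
        assert K[0, 0] == pytest.approx(1.0, rel=1e-5)

    @pytest.mark.parametrize("kind", KERNEL_KINDS)
    def test_cholesky_succeeds_on_random_draws(self, kind):
        rng = np.random.default_rng(1)
        times = np.linspace(0, 1, 6)
        for _ in range(100):
            spec = KernelSpec(kind, tau=float(rng.gamma(1, 1) + 1e-3),
                              amplitude_sq=float(rng.gamma(1, 1) + 1e-3))
            np.linalg.cholesky(build_cov_gp0(times, spec))

    def test_gp2_identity_correlation_equals_gp1(self):
        times = np.linspace(0, 1, 4)
        h2 = np.array([1.0, 2.0, 0.5])
        gp1 = build_cov_multi(times, "Mat32", MultiOutputSpec("GP1", amplitudes_sq=h2))
        gp2 = build_cov_multi(times, "Mat32",
                              MultiOutputSpec("GP2", amplitudes_sq=h2,
                                              correlation=np.eye(3)))
        np.testing.assert_allclose(gp1, gp2)

    def test_gp1_equal_amplitudes_replicates_gp0_blocks(self):
        times = np.linspace(0, 1, 3)
        lam = build_cov_multi(times, "Exp",
                              MultiOutputSpec("GP1", amplitudes_sq=np.full(2, 1.5)))
        K0 = build_cov_gp0(times, KernelSpec("Exp", tau=1.0, amplitude_sq=1.5))
        np.testing.assert_allclose(lam[:3, :3], K0, atol=1e-6)
        np.testing.assert_allclose(lam[3:, 3:], K0, atol=1e-6)
        np.testing.assert_allclose(lam[:3, 3:], 0.0)

    def test_gp3_collapses_to_gp1_when_parameters_shared(self):
        times = np.linspace(0, 1, 3)
        h2 = np.full(2, 2.0)
        gp3 = build_cov_multi(times, "Mat52",
                              MultiOutputSpec("GP3", amplitudes_sq=h2,
                                              taus=np.full(2, 1.0)))
        gp1 = build_cov_multi(times, "Mat52",
                              MultiOutputSpec("GP1", amplitudes_sq=h2,
                                              taus=np.array([1.0])))
        np.testing.assert_allclose(gp3, gp1, atol=1e-5)

    def test_min_eigenvalue_across_random_draws(self):
        rng = np.random.default_rng(2)
        times = np.linspace(0, 1, 5)
        for _ in range(200):
            kind = KERNEL_KINDS[rng.integers(4)]
            spec = KernelSpec(kind, tau=float(rng.gamma(1, 1) + 1e-3),
                              amplitude_sq=float(rng.gamma(1, 1) + 1e-3))
            G = spec.amplitude_sq * kernel_g(kind, spec.tau,
                                             times[:, None] - times[None, :])
            assert np.linalg.eigvalsh(G).min() >= -1e-8

    def test_non_psd_correlation_rejected(self):
        C = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError):
            MultiOutputSpec("GP2", amplitudes_sq=np.ones(2), correlation=C)


class TestTrajectoryLogPrior:
    def test_zero_trajectories_give_normalizing_constant(self):
        times = np.linspace(0, 1, 3)
        lam = build_cov_multi(times, "Exp", MultiOutputSpec("GP1", amplitudes_sq=np.ones(2)))
        psi = np.zeros((3, 2))
        expected = -0.5 * np.linalg.slogdet(2 * np.pi * lam)[1]
        assert trajectory_log_prior(psi, lam, "GP1") == pytest.approx(expected)

    def test_matches_dense_multivariate_normal(self):
        rng = np.random.default_rng(3)
        times = np.linspace(0, 1, 3)
        for variant in ("GP1", "GP3"):
            mspec = MultiOutputSpec(variant, amplitudes_sq=rng.gamma(2, 1, 3),
                                    taus=rng.gamma(2, 1, 3))
            lam = build_cov_multi(times, "Mat32", mspec)
            psi = rng.standard_normal((3, 3))
            oracle = stats.multivariate_normal(np.zeros(9), lam).logpdf(
                psi.reshape(-1, order="F")
            )
            assert trajectory_log_prior(psi, lam, variant) == pytest.approx(oracle)

    def test_gp0_scalar_reduction(self):
        # M=1, h^2=1: each psi_1k is standard normal
        K0 = build_cov_gp0([0.0], KernelSpec("ExpQ", tau=1.0, amplitude_sq=1.0))
        psi = np.array([[0.3, -1.2]])
        oracle = stats.norm(0, np.sqrt(K0[0, 0])).logpdf([0.3, -1.2]).sum()
        assert trajectory_log_prior(psi, K0, "GP0") == pytest.approx(oracle)

    def test_flat_logit_prior_is_standard_logistic(self):
        # uniform CCF corresponds to a standard logistic density on the logit scale
        rng = np.random.default_rng(4)
        psi = rng.standard_normal(1000) * 2
        phi = 1 / (1 + np.exp(-psi))
        ours = np.log(phi) + np.log1p(-phi)
        np.testing.assert_allclose(ours, stats.logistic.logpdf(psi), atol=1e-12)
        draws = stats.logistic.rvs(size=10000, random_state=5)
        phi_draws = 1 / (1 + np.exp(-draws))
        assert stats.kstest(phi_draws, "uniform").pvalue > 0.01


class TestLkjTransform:
    def test_cholesky_gives_valid_correlation(self):
        rng = np.random.default_rng(6)
        for K in (2, 3, 5):
            y = rng.standard_normal(K * (K - 1) // 2) * 1.5
            L, _ = corr_cholesky_from_unconstrained(y, K)
            C = L @ L.T
            np.testing.assert_allclose(np.diag(C), 1.0, atol=1e-12)
            assert np.linalg.eigvalsh(C).min() > 0

    @pytest.mark.parametrize("eta", [1.0, 2.0, 4.0])
    def test_k2_pushforward_matches_marginal(self, eta):
        # for K=2 the pushforward density on rho is proportional to (1-rho^2)^(eta-1)
        total, _ = quad(lambda y: np.exp(lkj_logdensity_unconstrained(
            np.array([y]), 2, eta)[1]), -12, 12)
        expected, _ = quad(lambda r: (1 - r * r) ** (eta - 1), -1, 1)
        assert total == pytest.approx(expected, rel=1e-6)
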