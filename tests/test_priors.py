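"""Prior densities: normalization, moments, sampling, elicitation."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import kstest

import thermokin as tk
from thermokin.priors import _log_erfc


class TestVariancePrior:
    def test_moments(self, var_hyper):
        assert var_hyper.mean == pytest.approx(0.5)
        assert var_hyper.variance == pytest.approx(0.25)

    def test_normalizes_by_quadrature(self, var_hyper):
        val, _ = quad(lambda s2: np.exp(tk.variance_prior_logpdf(s2, var_hyper)), 0, np.inf)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_domain_error(self, var_hyper):
        with pytest.raises(ValueError):
            tk.variance_prior_logpdf(-0.1, var_hyper)


class TestForwardRatePrior:
    def test_log_erfc_stable_far_in_the_tail(self):
        u = np.array([-40.0, 0.0, 40.0])
        out = _log_erfc(u)
        assert np.all(np.isfinite(out))
        assert out[1] == pytest.approx(0.0)
        # Gaussian tail: log erfc(u) ~ -u^2 for large u
        assert out[2] == pytest.approx(-(40.0**2), rel=0.01)

    def test_normalizes_at_reference_hyperparameters(self, paper_hyper):
        f = lambda x: np.exp(tk.forward_rate_prior_logpdf(x, paper_hyper))
        val, _ = quad(f, -60, 20, limit=200)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_mean_is_kappa0_minus_tau(self, paper_hyper):
        f = lambda x: np.exp(tk.forward_rate_prior_logpdf(x, paper_hyper))
        mean, _ = quad(lambda x: x * f(x), -60, 20, limit=200)
        assert mean == pytest.approx(-7.0, abs=1e-4)

    def test_small_lambda_limit_is_shifted_exponential(self):
        h = tk.ArrheniusHyperparams(kappa0=0.0, tau=2.0, lam=1e-4)
        below = tk.forward_rate_prior_logpdf(-1.0, h)
        assert below == pytest.approx(np.log(np.exp(-(-1.0) / -2.0) / 2.0), abs=1e-3)
        assert tk.forward_rate_prior_logpdf(0.5, h) < -100.0

    def test_sampler_moments(self, paper_hyper):
        rng = np.random.default_rng(7)
        s = tk.sample_forward_rate_prior(paper_hyper, 0, 100_000, rng)
        mean_true = float(paper_hyper.mean)
        sd_true = float(paper_hyper.sd)
        assert s.mean() == pytest.approx(mean_true, abs=3 * sd_true / np.sqrt(s.size))
        assert s.var() == pytest.approx(sd_true**2, rel=0.03)

    def test_sampler_matches_density_ks(self, paper_hyper):
        # density-vs-sampler cross-check through the numeric CDF
        rng = np.random.default_rng(11)
        s = tk.sample_forward_rate_prior(paper_hyper, 0, 100_000, rng)
        grid = np.linspace(-40, 5, 4001)
        pdf = np.exp(tk.forward_rate_prior_logpdf(grid, paper_hyper))
        cdf = np.cumsum(pdf)
        cdf = cdf / cdf[-1]
        stat = kstest(s, lambda x: np.interp(x, grid, cdf))
        assert stat.pvalue > 0.01

    def test_mode_matches_grid_argmax(self, paper_hyper):
        grid = np.linspace(-12, 0, 240_001)
        dense = tk.forward_rate_prior_logpdf(grid, paper_hyper)
        assert tk.forward_rate_prior_mode(paper_hyper) == pytest.approx(
            grid[np.argmax(dense)], abs=1e-4
        )


class TestEquilibriumStats:
    def test_two_state_noiseless_recovers_z(self, two_state, var_hyper):
        net, _, ktrue, design = two_state
        xbar = tk.steady_state(net, ktrue, design)
        stats = tk.equilibrium_stats(np.log(xbar)[:, None], net, var_hyper)
        assert stats.y_tilde == pytest.approx([float(ktrue.z[0])], abs=1e-7)

    def test_noiseless_feasible_system_exact_for_all_reactions(self, chain3, var_hyper):
        net, _, ktrue, design = chain3
        cols = [np.log(tk.steady_state(net, ktrue, design, p)) for p in design.labels]
        stats = tk.equilibrium_stats(np.stack(cols, axis=1), net, var_hyper)
        assert np.allclose(stats.y_tilde, ktrue.z, atol=1e-6)

    def test_replicates_average(self, two_state, var_hyper):
        net = two_state[0]
        ybar = np.array([[0.1, 0.3], [0.5, 0.9]])  # two replicate columns
        stats = tk.equilibrium_stats(ybar, net, var_hyper)
        # s = (-1, 1): per-replicate sums are 0.4 and 0.6
        assert stats.y_tilde == pytest.approx([0.5])
        assert stats.P == 1

    def test_unbiasedness_under_noise(self, two_state, var_hyper):
        net, _, ktrue, design = two_state
        lnxbar = np.log(tk.steady_state(net, ktrue, design))
        rng = np.random.default_rng(5)
        sigma = 0.1
        draws = []
        for _ in range(1000):
            noisy = lnxbar + rng.normal(0, sigma, size=2)
            draws.append(
                tk.equilibrium_stats(noisy[:, None], net, var_hyper).y_tilde[0]
            )
        se = sigma * np.sqrt(2) / np.sqrt(1000)
        assert np.mean(draws) == pytest.approx(float(ktrue.z[0]), abs=3 * se)

    def test_incomplete_table_rejected(self, two_state, var_hyper):
        with pytest.raises(ValueError, match="incomplete"):
            tk.equilibrium_stats(np.array([[0.1], [np.nan]]), two_state[0], var_hyper)


class TestEquilibriumPriorLogpdf:
    def test_maximum_at_y_tilde(self, var_hyper):
        stats = tk.EquilibriumPriorStats(
            y_tilde=np.array([np.log(2.0)]), theta=np.array([[0.5]]), P=0,
            alpha=var_hyper.alpha, b=var_hyper.b,
        )
        at_mode = tk.equilibrium_prior_logpdf(stats.y_tilde, stats)
        assert at_mode == pytest.approx(-3.0 * np.log(2.0))
        assert tk.equilibrium_prior_logpdf(stats.y_tilde + 0.3, stats) < at_mode

    def test_two_state_scalar_hand_value(self, two_state, var_hyper):
        # H = [2], theta = [1/2]; at b=1, P=0, alpha=3, z - y_tilde = 1
        net = two_state[0]
        stats = tk.equilibrium_stats(np.zeros((2, 1)), net, var_hyper)
        assert np.allclose(stats.theta, [[0.5]])
        val = tk.equilibrium_prior_logpdf(stats.y_tilde + 1.0, stats)
        assert val == pytest.approx(-3.0 * np.log(2.5))

    def test_invariant_along_null_directions(self, triangle, var_hyper):
        net = triangle[0]
        rng = np.random.default_rng(2)
        stats = tk.equilibrium_stats(rng.normal(size=(3, 1)), net, var_hyper)
        _, null = tk.rank_and_nullspace(net.net_stoich)
        z = rng.normal(size=3)
        v = null[:, 0]
        assert tk.equilibrium_prior_logpdf(z + 2.0 * v, stats) == pytest.approx(
            tk.equilibrium_prior_logpdf(z, stats), abs=1e-10
        )

    def test_theta_inverts_full_rank_gram_matrix(self, chain3):
        net = chain3[0]
        from thermokin.priors import _theta_from_net

        S = net.net_stoich.astype(float)
        theta = _theta_from_net(net)
        assert np.allclose(theta @ (S.T @ S), np.eye(net.n_reactions), atol=1e-10)


class TestElicitation:
    def test_reproduces_reference_values(self):
        # range implied by mean -7 and sd sqrt(4.1551)
        sd = np.sqrt(1.8990**2 + 0.7409**2)
        k_low, k_high = np.exp(-7.0 - 2 * sd), np.exp(-7.0 + 2 * sd)
        h = tk.elicit_arrhenius_hyperparams(k_low, k_high)
        assert h.kappa0 == pytest.approx(-5.1010, abs=5e-3)
        assert h.tau == pytest.approx(1.8990, abs=5e-3)
        assert h.lam == pytest.approx(0.7409, abs=5e-3)
        assert float(h.mean) == pytest.approx(-7.0, abs=1e-9)

    def test_symmetric_unit_range_gives_kappa0_equal_tau(self):
        h = tk.elicit_arrhenius_hyperparams(1e-3, 1e3)
        assert h.kappa0 == pytest.approx(h.tau)

    def test_monotone_in_range_width(self):
        hs = [tk.elicit_arrhenius_hyperparams(np.exp(-w), np.exp(w)) for w in (5, 7, 9)]
        taus = [h.tau for h in hs]
        lams = [h.lam for h in hs]
        assert taus == sorted(taus) and lams == sorted(lams)

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            tk.elicit_arrhenius_hyperparams(2.0, 1.0)
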