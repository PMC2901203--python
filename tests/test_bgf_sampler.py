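"""MCMC correctness: priors, full conditionals, MH ratios, stationary distribution."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import logit
from scipy.stats import invgamma

from gfmap.bgf_sampler import (
    BGFSummary,
    ChainConfig,
    PosteriorChain,
    PriorConfig,
    ProposalConfig,
    _log_prior_pi,
    _log_prior_sigma2e,
    _log_prior_x,
    beta_full_conditional,
    log_prior,
    mh_update_pi_mu_l,
    mh_update_sigma2e,
    run_chain,
    sample_beta,
    summarize,
)
from gfmap.gf_model import BGFState, log_likelihood, n_candidates
from gfmap.ld_simulator import synthesize_ld_study

from conftest import make_study, random_study


def _log_posterior(study, state, prior, L):
    return log_likelihood(study, state) + log_prior(state, prior, L)


class TestLogPrior:
    def test_logit_normal_value_at_half(self):
        # density at pi = 0.5 under unit logit variance: phi(0) * 4
        expected = math.log(math.exp(-0.0) / math.sqrt(2 * math.pi) * 4.0)
        assert _log_prior_pi(np.array([0.5]), 1.0) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.467356, abs=1e-5)

    @pytest.mark.parametrize("s2x", [1.0, 4.0])
    def test_logit_normal_integrates_to_one(self, s2x):
        val, err = quad(
            lambda p: math.exp(_log_prior_pi(np.array([p]), s2x)), 0.0, 1.0
        )
        assert val == pytest.approx(1.0, abs=max(1e-8, 10 * err))

    def test_logit_normal_symmetry(self):
        for p in (0.1, 0.25, 0.4):
            assert _log_prior_pi(np.array([p]), 4.0) == pytest.approx(
                _log_prior_pi(np.array([1 - p]), 4.0), abs=1e-10
            )

    def test_boundary_pi_has_zero_support(self):
        assert _log_prior_pi(np.array([0.0]), 1.0) == -np.inf
        assert _log_prior_pi(np.array([1.0]), 1.0) == -np.inf

    def test_scaled_inv_chisq_matches_invgamma_oracle(self):
        nu, s2 = 4.0, 0.5
        for v in (0.1, 0.7, 2.5):
            oracle = invgamma.logpdf(v, a=nu / 2, scale=nu * s2 / 2)
            assert _log_prior_sigma2e(v, nu, s2) == pytest.approx(oracle, abs=1e-10)

    def test_location_prior_is_uniform_over_candidates(self):
        state = BGFState([0.0], [0.4, 0.6], 0.1, 0, 1.0)
        prior = PriorConfig()
        assert log_prior(state, prior, 10) - log_prior(state, prior, 1) == pytest.approx(
            -math.log(10), abs=1e-12
        )


class TestBetaFullConditional:
    def test_intercept_only_homogeneous_mean_is_sample_mean(self, rng):
        study = random_study(rng, n=60, n_markers=3)
        state = BGFState([0.0], [0.3, 0.3], 0.0, 0, 1.7)
        mean, cov = beta_full_conditional(study, state)
        assert mean[0] == pytest.approx(study.y.mean(), abs=1e-10)
        # conditional variance of the intercept scales as sigma^2 / n
        assert cov[0, 0] == pytest.approx(1.7 / 60, abs=1e-10)

    def test_matches_weighted_normal_equations_oracle(self, rng):
        study = random_study(rng, n=20, n_markers=4)
        study.X = np.column_stack([np.ones(20), rng.normal(size=20)])
        state = BGFState([0.0, 0.0], [0.2, 0.7], 0.5, 2, 0.9)
        mean, cov = beta_full_conditional(study, state)

        from gfmap.gf_model import haplotype_codes

        m, p = haplotype_codes(study, 2, 1)
        pi = state.pi
        qhat = pi[m] + pi[p]
        var = 0.9 + (pi[m] * (1 - pi[m]) + pi[p] * (1 - pi[p])) * 0.25
        R_inv = np.diag(1.0 / var)
        A = study.X.T @ R_inv @ study.X
        rhs = study.X.T @ R_inv @ (study.y - qhat * 0.5)
        np.testing.assert_allclose(mean, np.linalg.solve(A, rhs), atol=1e-10)
        np.testing.assert_allclose(cov, np.linalg.inv(A), atol=1e-10)

    def test_sample_beta_reproducible(self, rng):
        study = random_study(rng, n=30, n_markers=3)
        state = BGFState([0.0], [0.4, 0.6], 0.2, 1, 1.0)
        d1 = sample_beta(study, state, np.random.default_rng(5))
        d2 = sample_beta(study, state, np.random.default_rng(5))
        np.testing.assert_array_equal(d1, d2)


class TestMetropolisHastings:
    def test_pi_mu_l_decision_matches_brute_force_ratio(self, rng):
        # replicate the proposal stream and verify accept/reject against a
        # direct evaluation of the joint posterior-density ratio in the
        # sampling coordinates (normal prior on x = logit(pi); the pi-space
        # Jacobian cancels against the transformed proposal density)
        study = random_study(rng, n=5, n_markers=4)
        prior = PriorConfig()
        prop = ProposalConfig(adapt=False)
        state = BGFState([0.1], [0.3, 0.6], 0.2, 1, 0.8)
        L = n_candidates(4, 1)
        n_accept = 0
        for seed in range(200):
            r = np.random.default_rng(seed)
            x_cur = logit(state.pi)
            x_new = x_cur + r.normal(0, math.sqrt(prop.sigma2_x_prop), size=2)
            pi_new = 1 / (1 + np.exp(-x_new))
            mu_new = state.mu + r.normal(0, math.sqrt(prop.sigma2_mu_prop))
            l_new = int(r.integers(0, L))
            u = r.random()
            cand = BGFState(state.beta, pi_new, mu_new, l_new, state.sigma2_e)

            def lp(st, x):
                return (
                    log_likelihood(study, st)
                    + _log_prior_x(x, prior.sigma2_x)
                    - 0.5 * st.mu**2 / prior.sigma2_mu
                )

            log_alpha = lp(cand, x_new) - lp(state, x_cur)
            expect_accept = math.log(u) < log_alpha

            got, accepted = mh_update_pi_mu_l(
                study, state, prior, prop, np.random.default_rng(seed)
            )
            assert accepted == expect_accept
            n_accept += accepted
            if accepted:
                np.testing.assert_allclose(got.pi, pi_new, atol=1e-12)
                assert got.mu == pytest.approx(mu_new, abs=1e-12)
                assert got.location == l_new
            else:
                assert got is state
        assert 0 < n_accept < 200  # both branches exercised

    def test_sigma2e_decision_matches_brute_force_ratio(self, rng):
        study = random_study(rng, n=5, n_markers=3)
        prior = PriorConfig()
        prop = ProposalConfig(adapt=False)
        state = BGFState([0.0], [0.3, 0.6], 0.3, 0, 0.6)
        L = n_candidates(3, 1)
        n_accept = 0
        for seed in range(200):
            r = np.random.default_rng(seed)
            s2e_new = state.sigma2_e + r.normal(0, math.sqrt(prop.sigma2_e_prop))
            u = r.random()
            if s2e_new <= 0:
                expect_accept = False
            else:
                cand = BGFState(state.beta, state.pi, state.mu, 0, s2e_new)
                log_alpha = _log_posterior(study, cand, prior, L) - _log_posterior(
                    study, state, prior, L
                )
                expect_accept = math.log(u) < log_alpha
            got, accepted = mh_update_sigma2e(
                study, state, prior, prop, np.random.default_rng(seed)
            )
            assert accepted == expect_accept
            n_accept += accepted
        assert 0 < n_accept < 200

    def test_nonpositive_sigma2e_proposal_always_rejected(self, rng):
        study = random_study(rng, n=5, n_markers=3)
        state = BGFState([0.0], [0.3, 0.6], 0.3, 0, 1e-4)
        # huge step variance: most proposals fall below zero and must keep state
        prop = ProposalConfig(sigma2_e_prop=25.0, adapt=False)
        for seed in range(30):
            got, accepted = mh_update_sigma2e(
                study, state, PriorConfig(), prop, np.random.default_rng(seed)
            )
            if got.sigma2_e != state.sigma2_e:
                assert got.sigma2_e > 0


class TestChain:
    def test_deterministic_given_seed(self, rng):
        study = random_study(rng, n=40, n_markers=5)
        cfg = ChainConfig(400, 100, 2, seed=3)
        a = run_chain(study, chain=cfg)
        b = run_chain(study, chain=cfg)
        np.testing.assert_array_equal(a.mu, b.mu)
        np.testing.assert_array_equal(a.location, b.location)
        np.testing.assert_array_equal(a.sigma2_e, b.sigma2_e)

    def test_acceptance_rates_interior(self):
        study = synthesize_ld_study(300, (0.2, 0.8), 0.05, rng=11)
        ch = run_chain(study, chain=ChainConfig(2000, 500, 2, seed=1))
        assert 0 < ch.accept_rate_pi_mu_l < 1
        assert 0 < ch.accept_rate_sigma2e < 1

    def test_retained_sample_count(self, rng):
        study = random_study(rng, n=30, n_markers=4)
        ch = run_chain(study, chain=ChainConfig(1000, 400, 3, seed=0))
        assert ch.n_samples == (1000 - 400) // 3

    def test_location_uniform_under_flat_likelihood(self, rng):
        # mu pinned at zero: the likelihood carries no information on l,
        # so retained locations must be uniform over the candidates
        study = random_study(rng, n=40, n_markers=11)
        ch = run_chain(
            study, fix_mu=0.0, chain=ChainConfig(15000, 1000, 1, seed=2)
        )
        freqs = np.bincount(ch.location, minlength=11) / ch.n_samples
        assert np.max(np.abs(freqs - 1 / 11)) < 0.025

    def test_sigma2e_posterior_matches_homogeneous_closed_form(self):
        # with mu fixed at 0 the model is a homoscedastic Gaussian; the
        # posterior of sigma_e^2 is scaled-inv-chi-square around the RSS
        rng = np.random.default_rng(8)
        study = random_study(rng, n=2000, n_markers=3)
        prior = PriorConfig()
        ch = run_chain(
            study, prior=prior, fix_mu=0.0, chain=ChainConfig(3000, 800, 2, seed=5)
        )
        beta0, *_ = np.linalg.lstsq(study.X, study.y, rcond=None)
        rss = np.sum((study.y - study.X @ beta0) ** 2)
        expected = (prior.nu_e * prior.S2_e + rss) / (prior.nu_e + 2000 - 2)
        assert np.mean(ch.sigma2_e) == pytest.approx(expected, rel=0.05)

    def test_pure_noise_pi_posterior_stays_near_prior_mean(self):
        rng = np.random.default_rng(17)
        study = random_study(rng, n=500, n_markers=5)
        ch = run_chain(study, chain=ChainConfig(10000, 2000, 2, seed=9))
        np.testing.assert_allclose(ch.pi.mean(axis=0), 0.5, atol=0.1)

    def test_recovers_location_under_strong_ld(self):
        # a single dataset: the modal location lands on or next to the QTL
        # marker (aggregate recovery rates are checked in the acceptance suite)
        study = synthesize_ld_study(400, (0.05, 0.95), 0.05, rng=23)
        ch = run_chain(study, chain=ChainConfig(4000, 1000, 2, seed=4))
        assert abs(summarize(ch).estimated_location - 3) <= 1

    def test_stationary_location_marginal_matches_grid_oracle(self):
        # small instance: numerically normalize the posterior over a dense
        # (pi0, pi1, mu, sigma2) grid — the flat-prior intercept integrates
        # out analytically — and compare P(l) with the chain's marginal
        y = np.array([1.1, 0.9, -1.0, -1.2, 1.0, -0.8])
        mat = np.array([[1, 1], [1, 0], [0, 1], [0, 0], [1, 1], [0, 0]])
        pat = np.array([[1, 0], [1, 1], [0, 0], [0, 1], [1, 1], [0, 0]])
        study = make_study(mat, pat, y)
        prior = PriorConfig()
        n = len(y)

        n_pi, n_mu, n_s2 = 61, 61, 41
        pi_g = np.linspace(0.5 / n_pi, 1 - 0.5 / n_pi, n_pi)
        mu_g = np.linspace(-3.5, 3.5, n_mu)
        s2_g = np.exp(np.linspace(np.log(0.05), np.log(8.0), n_s2))
        w_s2 = np.gradient(s2_g)  # log-grid cell widths

        lp_pi = np.array([_log_prior_pi(np.array([p]), prior.sigma2_x) for p in pi_g])
        lp_mu = -0.5 * (np.log(2 * np.pi * prior.sigma2_mu) + mu_g**2 / prior.sigma2_mu)
        lp_s2 = np.array([_log_prior_sigma2e(v, prior.nu_e, prior.S2_e) for v in s2_g])

        P0, P1, M, S = np.ix_(pi_g, pi_g, mu_g, s2_g)
        masses = []
        for l in (0, 1):
            s_inv = np.zeros((n_pi, n_pi, n_mu, n_s2))
            s_r = np.zeros_like(s_inv)
            s_r2 = np.zeros_like(s_inv)
            s_logv = np.zeros_like(s_inv)
            for i in range(n):
                pim = P0 if mat[i, l] == 0 else P1
                pip = P0 if pat[i, l] == 0 else P1
                var = S + (pim * (1 - pim) + pip * (1 - pip)) * M**2
                r = y[i] - (pim + pip) * M
                s_inv += 1.0 / var
                s_r += r / var
                s_r2 += r * r / var
                s_logv += np.log(var)
            # flat-prior intercept integrated out of the Gaussian likelihood
            ll = (
                -0.5 * (n - 1) * np.log(2 * np.pi)
                - 0.5 * s_logv
                - 0.5 * np.log(s_inv)
                - 0.5 * (s_r2 - s_r**2 / s_inv)
            )
            lp = (
                ll
                + lp_pi[:, None, None, None]
                + lp_pi[None, :, None, None]
                + lp_mu[None, None, :, None]
                + lp_s2[None, None, None, :]
            )
            masses.append(lp)
        top = max(lp.max() for lp in masses)
        m0, m1 = (np.sum(np.exp(lp - top) * w_s2) for lp in masses)
        p_l0_grid = m0 / (m0 + m1)

        ch = run_chain(study, k=1, prior=prior, chain=ChainConfig(60000, 3000, 1, seed=6))
        p_l0_chain = np.mean(ch.location == 0)
        assert p_l0_chain == pytest.approx(p_l0_grid, abs=0.05)
        assert not 0.45 < p_l0_grid < 0.55  # the instance is informative


class TestSummaries:
    def _chain(self, locations, mu):
        n = len(mu)
        return PosteriorChain(
            beta=np.zeros((n, 1)),
            pi=np.full((n, 2), 0.5),
            mu=np.asarray(mu, dtype=float),
            location=np.asarray(locations),
            sigma2_e=np.ones(n),
            qtl_variance=np.zeros(n),
            explained_variance=np.zeros(n),
            accept_rate_pi_mu_l=0.3,
            accept_rate_sigma2e=0.3,
            k=1,
            candidate_positions_cM=np.arange(5) * 0.1,
            hap_freqs=np.full((5, 2), 0.5),
            config=ChainConfig(10, 0, 1, 0),
        )

    def test_modal_location_and_posterior_means(self):
        s = summarize(self._chain([3, 3, 3], [1.0, 2.0, 3.0]))
        assert s.estimated_location == 3
        assert s.post_mean_mu == pytest.approx(2.0)

    def test_location_mode_tie_breaks_low(self):
        s = summarize(self._chain([0, 0, 1, 1], [0.0] * 4))
        assert s.estimated_location == 0

    def test_empty_chain_rejected(self):
        with pytest.raises(ValueError):
            summarize(self._chain([], []))

    def test_statistic_is_mean_of_per_sample_values(self, rng):
        study = random_study(rng, n=50, n_markers=4)
        ch = run_chain(study, chain=ChainConfig(600, 200, 2, seed=1))
        s = summarize(ch)
        assert s.explained_variance == pytest.approx(
            np.mean(ch.explained_variance), abs=1e-14
        )
        assert s.qtl_variance == pytest.approx(np.mean(ch.qtl_variance), abs=1e-14)


class TestConfigValidation:
    def test_burn_in_must_precede_end(self):
        with pytest.raises(ValueError):
            ChainConfig(n_iterations=100, burn_in=100)

    def test_positive_proposal_variances(self):
        with pytest.raises(ValueError):
            ProposalConfig(sigma2_x_prop=0.0)

    def test_positive_prior_hyperparameters(self):
        with pytest.raises(ValueError):
            PriorConfig(nu_e=-1.0)
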