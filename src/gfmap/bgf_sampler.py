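"""Blocked Gibbs sampler with Metropolis–Hastings steps for the gene-frequency model.

The joint posterior of (beta, pi, mu, l, sigma_e^2) is targeted with three
blocks per sweep:

1. beta — drawn exactly from its multivariate-normal full conditional
   (the weighted normal equations of the heteroscedastic Gaussian model).
2. (pi, mu, l) — joint Metropolis–Hastings move: a Gaussian random walk on
   x = logit(pi) (mapped back through the inverse logit), a Gaussian
   random walk on mu, and an independent uniform draw of the candidate
   location l.  All proposals are symmetric on their sampling scales, so
   the acceptance ratio is the posterior-density ratio in those
   coordinates; for pi that means the x-space normal prior enters and the
   logit Jacobian of the pi-space prior cancels against the transformed
   proposal density.
3. sigma_e^2 — Gaussian random-walk Metropolis–Hastings; non-positive
   proposals have zero prior support and are rejected outright.

Priors: flat for beta; logit-normal (null mean, diagonal Sigma_x) for pi;
normal (null mean) for mu; discrete uniform over the L candidate
locations; scaled inverse chi-square for sigma_e^2.

Under a proposed location move the current pi vector is re-interpreted
with respect to the SNP(s) at the proposed location; its dimension never
changes.  The sign of mu is not identified jointly with the pi <-> 1-pi
flip, so summaries report |mu| alongside mu.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .gf_model import (
    BGFState,
    candidate_positions,
    haplotype_codes,
    haplotype_frequencies,
    n_candidates,
    qtl_variance_statistic,
)
from .ld_simulator import StudyData

__all__ = [
    "PriorConfig",
    "ProposalConfig",
    "ChainConfig",
    "PosteriorChain",
    "BGFSummary",
    "log_prior",
    "beta_full_conditional",
    "sample_beta",
    "mh_update_pi_mu_l",
    "mh_update_sigma2e",
    "run_chain",
    "summarize",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class PriorConfig:
    """Hyperparameters of the prior; weakly informative on unit-variance phenotypes.

    sigma2_mu   prior variance of the QTL substitution effect mu
    nu_e, S2_e  degrees of freedom and scale of the scaled inverse
                chi-square prior on sigma_e^2
    sigma2_x    diagonal prior variance of x = logit(pi) (elements of pi
                a priori uncorrelated).  The default of 4 (logit-scale SD
                of 2) keeps the prior 95% interval of each pi near
                (0.02, 0.98); a unit variance measurably shrinks strong
                disequilibrium (pi near 0 or 1) toward 0.5 and inflates
                the QTL effect along the poorly identified pi-spread x mu
                ridge.
    """

    sigma2_mu: float = 1.0
    nu_e: float = 4.0
    S2_e: float = 0.5
    sigma2_x: float = 4.0

    def __post_init__(self) -> None:
        for name in ("sigma2_mu", "nu_e", "S2_e", "sigma2_x"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ProposalConfig:
    """Random-walk variances; small enough to stay in the neighbourhood of
    the previous sample.  During burn-in they are rescaled toward an
    acceptance rate of 0.2-0.5 and then frozen, so the sampling phase uses
    fixed, symmetric proposals."""

    sigma2_x_prop: float = 0.25
    sigma2_mu_prop: float = 0.01
    sigma2_e_prop: float = 0.01
    adapt: bool = True

    def __post_init__(self) -> None:
        for name in ("sigma2_x_prop", "sigma2_mu_prop", "sigma2_e_prop"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class ChainConfig:
    n_iterations: int = 20_000
    burn_in: int = 5_000
    thinning: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iterations:
            raise ValueError("need 0 <= burn_in < n_iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")


@dataclass
class PosteriorChain:
    """Retained post-burn-in samples plus per-block acceptance rates."""

    beta: np.ndarray
    pi: np.ndarray
    mu: np.ndarray
    location: np.ndarray
    sigma2_e: np.ndarray
    qtl_variance: np.ndarray
    explained_variance: np.ndarray
    accept_rate_pi_mu_l: float
    accept_rate_sigma2e: float
    k: int
    candidate_positions_cM: np.ndarray
    hap_freqs: np.ndarray
    config: ChainConfig

    @property
    def n_samples(self) -> int:
        return len(self.mu)

    def to_frame(self) -> pd.DataFrame:
        """Flat named-value records, one row per retained sample."""
        data = {"iteration": np.arange(self.n_samples)}
        for j in range(self.beta.shape[1]):
            data[f"beta{j}"] = self.beta[:, j]
        for j in range(self.pi.shape[1]):
            data[f"pi{j}"] = self.pi[:, j]
        data["mu"] = self.mu
        data["location"] = self.location
        data["sigma2_e"] = self.sigma2_e
        data["qtl_variance"] = self.qtl_variance
        data["explained_variance"] = self.explained_variance
        return pd.DataFrame(data)


@dataclass
class BGFSummary:
    """Point summaries of a chain: the mapping result of the Bayesian analysis."""

    estimated_location: int
    estimated_position_cM: float
    post_mean_mu: float
    post_mean_abs_mu: float
    post_sd_mu: float
    post_mean_pi: np.ndarray
    post_mean_sigma2_e: float
    qtl_variance: float
    explained_variance: float
    k: int
    n_samples: int

    @property
    def statistic(self) -> float:
        """Detection statistic: posterior mean of the marker-predicted QTL
        variance Var_i(E(Q_i|M) mu), which stays calibrated under the null
        (the additive-variance functional 2 p_bar (1-p_bar) mu^2 is reported
        too but is unidentified when all pi elements coincide)."""
        return self.explained_variance


# ---------------------------------------------------------------------------
# Prior and conditional densities
# ---------------------------------------------------------------------------


def _norm_logpdf(x: float, var: float) -> float:
    return -0.5 * (_LOG_2PI + math.log(var) + x * x / var)


def _log_prior_x(x: np.ndarray, sigma2_x: float) -> float:
    """Normal log-density of x = logit(pi) — the prior on the logit scale.

    This is the density the MH ratio needs for a random walk proposed in x:
    the logit Jacobian of the pi-space prior cancels exactly against the
    proposal-density ratio of the transformed walk, leaving the x-space
    normal prior.
    """
    return float(-0.5 * np.sum(_LOG_2PI + math.log(sigma2_x) + x * x / sigma2_x))


def _log_prior_pi(pi: np.ndarray, sigma2_x: float) -> float:
    """Logit-normal log-density: normal on x = logit(pi) plus log-Jacobian."""
    pi = np.asarray(pi, dtype=float)
    if np.any(pi <= 0.0) or np.any(pi >= 1.0):
        return -np.inf
    x = logit(pi)
    lp = -0.5 * np.sum(_LOG_2PI + math.log(sigma2_x) + x * x / sigma2_x)
    return float(lp - np.sum(np.log(pi * (1.0 - pi))))


def _log_prior_sigma2e(s2e: float, nu_e: float, S2_e: float) -> float:
    """Scaled inverse chi-square(nu, S^2) == Inv-Gamma(nu/2, nu S^2 / 2)."""
    if s2e <= 0:
        return -np.inf
    a = nu_e / 2.0
    scale = nu_e * S2_e / 2.0
    return a * math.log(scale) - math.lgamma(a) - (a + 1.0) * math.log(s2e) - scale / s2e


def log_prior(state: BGFState, prior: PriorConfig, n_locations: int) -> float:
    """Joint log prior density at ``state`` (flat over beta)."""
    if n_locations < 1:
        raise ValueError("n_locations must be positive")
    lp = _log_prior_pi(state.pi, prior.sigma2_x)
    lp += _norm_logpdf(state.mu, prior.sigma2_mu)
    lp += -math.log(n_locations)
    lp += _log_prior_sigma2e(state.sigma2_e, prior.nu_e, prior.S2_e)
    return lp


class _ChainContext:
    """Precomputed per-location haplotype codes and fast likelihood kernel."""

    def __init__(self, study: StudyData, k: int):
        if study.y is None:
            raise ValueError("study has no phenotypes")
        self.k = k
        self.L = n_candidates(study.n_markers, k)
        if self.L < 1:
            raise ValueError("no candidate locations in the window")
        self.codes = [haplotype_codes(study, l, k) for l in range(self.L)]
        self.freqs = np.array(
            [haplotype_frequencies(study, l, k) for l in range(self.L)]
        )
        self.X = study.X
        self.y = study.y
        self.positions = candidate_positions(study.positions_cM, k)

    def log_lik(self, beta, pi, mu, location, s2e) -> float:
        m, p = self.codes[location]
        pim, pip = pi[m], pi[p]
        mean = self.X @ beta + (pim + pip) * mu
        var = s2e + (pim * (1.0 - pim) + pip * (1.0 - pip)) * (mu * mu)
        r = self.y - mean
        return float(-0.5 * np.sum(_LOG_2PI + np.log(var) + r * r / var))

    def log_lik_state(self, state: BGFState) -> float:
        return self.log_lik(
            state.beta, state.pi, state.mu, state.location, state.sigma2_e
        )

    def draw_beta(self, state: BGFState, rng: np.random.Generator) -> np.ndarray:
        """Gibbs draw of beta reusing the cached haplotype codes."""
        m, p = self.codes[state.location]
        pim, pip = state.pi[m], state.pi[p]
        var = state.sigma2_e + (pim * (1 - pim) + pip * (1 - pip)) * state.mu**2
        w = 1.0 / var
        Xw = self.X * w[:, None]
        A = Xw.T @ self.X
        rhs = Xw.T @ (self.y - (pim + pip) * state.mu)
        cov = np.linalg.inv(A)
        chol = np.linalg.cholesky(cov)
        return cov @ rhs + chol @ rng.standard_normal(len(rhs))


# ---------------------------------------------------------------------------
# Block updates
# ---------------------------------------------------------------------------


def beta_full_conditional(study: StudyData, state: BGFState):
    """Mean and covariance of the multivariate-normal full conditional of beta.

    The mean solves the weighted normal equations
    X' R*^-1 X beta = X' R*^-1 (y - Qhat mu); the covariance is
    (X' R*^-1 X)^-1 with R* the diagonal heterogeneous residual covariance.
    """
    m, p = haplotype_codes(study, state.location, state.k)
    pim, pip = state.pi[m], state.pi[p]
    qhat = pim + pip
    var = state.sigma2_e + (pim * (1 - pim) + pip * (1 - pip)) * state.mu**2
    w = 1.0 / var
    X = study.X
    A = (X * w[:, None]).T @ X
    rhs = (X * w[:, None]).T @ (study.y - qhat * state.mu)
    try:
        cov = np.linalg.inv(A)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError("X' R*^-1 X is singular") from err
    if not np.all(np.isfinite(cov)):
        raise np.linalg.LinAlgError("X' R*^-1 X is singular")
    return cov @ rhs, cov


def sample_beta(study: StudyData, state: BGFState, rng: np.random.Generator) -> np.ndarray:
    """Exact Gibbs draw of beta from its full conditional."""
    mean, cov = beta_full_conditional(study, state)
    chol = np.linalg.cholesky(cov)
    return mean + chol @ rng.standard_normal(len(mean))


def _mh_pi_mu_l(
    ctx: _ChainContext,
    state: BGFState,
    cur_loglik: float,
    prior: PriorConfig,
    proposal: ProposalConfig,
    rng: np.random.Generator,
    fix_mu: Optional[float] = None,
):
    """One MH move of the (pi, mu, l) block.

    Returns (state, loglik, accepted, same_location) where the last flag
    records whether the proposed location equalled the current one — the
    acceptance rate among those proposals is the step-size tuning signal,
    since the overall rate is capped near 1/L by the uniform location
    proposal whenever the posterior concentrates on one candidate.
    """
    x = logit(state.pi)
    x_new = x + rng.normal(0.0, math.sqrt(proposal.sigma2_x_prop), size=len(x))
    pi_new = expit(x_new)
    mu_new = (
        fix_mu
        if fix_mu is not None
        else state.mu + rng.normal(0.0, math.sqrt(proposal.sigma2_mu_prop))
    )
    l_new = int(rng.integers(0, ctx.L))
    same_l = l_new == state.location
    u = rng.random()

    if np.any(pi_new <= 0.0) or np.any(pi_new >= 1.0):
        # inverse logit saturated in floating point; zero posterior support
        return state, cur_loglik, False, same_l
    lp_new = _log_prior_x(x_new, prior.sigma2_x) + _norm_logpdf(
        mu_new, prior.sigma2_mu
    )
    lp_cur = _log_prior_x(x, prior.sigma2_x) + _norm_logpdf(
        state.mu, prior.sigma2_mu
    )
    ll_new = ctx.log_lik(state.beta, pi_new, mu_new, l_new, state.sigma2_e)
    log_alpha = (ll_new + lp_new) - (cur_loglik + lp_cur)
    if math.log(u) < log_alpha:
        new = BGFState(state.beta, pi_new, float(mu_new), l_new, state.sigma2_e)
        return new, ll_new, True, same_l
    return state, cur_loglik, False, same_l


def _mh_sigma2e(
    ctx: _ChainContext,
    state: BGFState,
    cur_loglik: float,
    prior: PriorConfig,
    proposal: ProposalConfig,
    rng: np.random.Generator,
):
    s2e_new = state.sigma2_e + rng.normal(0.0, np.sqrt(proposal.sigma2_e_prop))
    u = rng.random()
    if s2e_new <= 0:  # zero prior support
        return state, cur_loglik, False
    ll_new = ctx.log_lik(state.beta, state.pi, state.mu, state.location, s2e_new)
    log_alpha = (
        ll_new
        + _log_prior_sigma2e(s2e_new, prior.nu_e, prior.S2_e)
        - cur_loglik
        - _log_prior_sigma2e(state.sigma2_e, prior.nu_e, prior.S2_e)
    )
    if math.log(u) < log_alpha:
        new = BGFState(state.beta, state.pi, state.mu, state.location, float(s2e_new))
        return new, ll_new, True
    return state, cur_loglik, False


def mh_update_pi_mu_l(
    study: StudyData,
    state: BGFState,
    prior: PriorConfig,
    proposal: ProposalConfig,
    rng: np.random.Generator,
    fix_mu: Optional[float] = None,
):
    """Public single-step MH update of the (pi, mu, l) block.

    Returns (new_state, accepted).  ``run_chain`` uses an internally cached
    equivalent of this update.
    """
    ctx = _ChainContext(study, state.k)
    new, _, accepted, _ = _mh_pi_mu_l(
        ctx, state, ctx.log_lik_state(state), prior, proposal, rng, fix_mu
    )
    return new, accepted


def mh_update_sigma2e(
    study: StudyData,
    state: BGFState,
    prior: PriorConfig,
    proposal: ProposalConfig,
    rng: np.random.Generator,
):
    """Public single-step MH update of sigma_e^2; returns (new_state, accepted)."""
    ctx = _ChainContext(study, state.k)
    new, _, accepted = _mh_sigma2e(
        ctx, state, ctx.log_lik_state(state), prior, proposal, rng
    )
    return new, accepted


# ---------------------------------------------------------------------------
# The chain
# ---------------------------------------------------------------------------

_ADAPT_WINDOW = 200
_ADAPT_LOW, _ADAPT_HIGH = 0.2, 0.5
_ADAPT_BOUND = 16.0  # proposal variances stay within initial / and * this factor


def run_chain(
    study: StudyData,
    k: int = 1,
    prior: Optional[PriorConfig] = None,
    proposal: Optional[ProposalConfig] = None,
    chain: Optional[ChainConfig] = None,
    fix_mu: Optional[float] = None,
) -> PosteriorChain:
    """Run the three-block sampler and return the retained posterior sample.

    Fully reproducible given ``chain.seed``.  Proposal variances adapt only
    during burn-in (frozen afterwards, preserving the fixed-proposal MH
    ratios of the sampling phase).  ``fix_mu`` pins the QTL effect — a
    diagnostic mode in which the likelihood is flat in (pi, l).
    """
    prior = prior or PriorConfig()
    proposal = proposal or ProposalConfig()
    chain = chain or ChainConfig()
    rng = np.random.default_rng(chain.seed)
    ctx = _ChainContext(study, k)

    # initial state: intercept-level fit, equilibrium pi, null effect
    beta0, *_ = np.linalg.lstsq(study.X, study.y, rcond=None)
    s2e0 = max(float(np.var(study.y)), 1e-6)
    state = BGFState(
        beta=beta0,
        pi=np.full(2**k, 0.5),
        mu=0.0 if fix_mu is None else fix_mu,
        location=ctx.L // 2,
        sigma2_e=s2e0,
    )
    cur_ll = ctx.log_lik_state(state)

    prop = ProposalConfig(
        proposal.sigma2_x_prop,
        proposal.sigma2_mu_prop,
        proposal.sigma2_e_prop,
        proposal.adapt,
    )
    n_keep = (chain.n_iterations - chain.burn_in) // chain.thinning
    out_beta = np.empty((n_keep, study.X.shape[1]))
    out_pi = np.empty((n_keep, 2**k))
    out_mu = np.empty(n_keep)
    out_l = np.empty(n_keep, dtype=np.int64)
    out_s2e = np.empty(n_keep)
    out_qv = np.empty(n_keep)
    out_ev = np.empty(n_keep)

    acc2 = acc3 = 0  # post-burn-in acceptance counters
    # burn-in adaptation counters; block 2 tuned on same-location proposals
    win2_same = win2_acc = win3 = 0
    init_var = {
        "sigma2_x_prop": prop.sigma2_x_prop,
        "sigma2_mu_prop": prop.sigma2_mu_prop,
        "sigma2_e_prop": prop.sigma2_e_prop,
    }

    def _rescale(attr: str, rate: float) -> None:
        v = getattr(prop, attr)
        if rate < _ADAPT_LOW:
            v *= 0.64
        elif rate > _ADAPT_HIGH:
            v *= 1.56
        lo, hi = init_var[attr] / _ADAPT_BOUND, init_var[attr] * _ADAPT_BOUND
        setattr(prop, attr, min(max(v, lo), hi))

    kept = 0
    for it in range(chain.n_iterations):
        beta = ctx.draw_beta(state, rng)
        state = BGFState(beta, state.pi, state.mu, state.location, state.sigma2_e)
        cur_ll = ctx.log_lik_state(state)

        state, cur_ll, a2, same_l = _mh_pi_mu_l(
            ctx, state, cur_ll, prior, prop, rng, fix_mu
        )
        state, cur_ll, a3 = _mh_sigma2e(ctx, state, cur_ll, prior, prop, rng)

        if it < chain.burn_in:
            win2_same += same_l
            win2_acc += a2 and same_l
            win3 += a3
            if prop.adapt and (it + 1) % _ADAPT_WINDOW == 0:
                if win2_same >= 10:
                    rate2 = win2_acc / win2_same
                    _rescale("sigma2_x_prop", rate2)
                    _rescale("sigma2_mu_prop", rate2)
                _rescale("sigma2_e_prop", win3 / _ADAPT_WINDOW)
                win2_same = win2_acc = win3 = 0
        else:
            acc2 += a2
            acc3 += a3
            j = it - chain.burn_in
            if j % chain.thinning == 0 and kept < n_keep:
                out_beta[kept] = state.beta
                out_pi[kept] = state.pi
                out_mu[kept] = state.mu
                out_l[kept] = state.location
                out_s2e[kept] = state.sigma2_e
                out_qv[kept] = qtl_variance_statistic(
                    state.pi, ctx.freqs[state.location], state.mu
                )
                m_c, p_c = ctx.codes[state.location]
                qhat = state.pi[m_c] + state.pi[p_c]
                out_ev[kept] = float(np.var(qhat * state.mu))
                kept += 1

    n_post = chain.n_iterations - chain.burn_in
    return PosteriorChain(
        beta=out_beta[:kept],
        pi=out_pi[:kept],
        mu=out_mu[:kept],
        location=out_l[:kept],
        sigma2_e=out_s2e[:kept],
        qtl_variance=out_qv[:kept],
        explained_variance=out_ev[:kept],
        accept_rate_pi_mu_l=acc2 / n_post,
        accept_rate_sigma2e=acc3 / n_post,
        k=k,
        candidate_positions_cM=ctx.positions,
        hap_freqs=ctx.freqs,
        config=chain,
    )


def summarize(chain: PosteriorChain) -> BGFSummary:
    """Deterministic point summaries: modal location, posterior means.

    A tie between modal locations is broken toward the lower index.
    """
    if chain.n_samples == 0:
        raise ValueError("empty chain")
    counts = np.bincount(chain.location, minlength=len(chain.candidate_positions_cM))
    loc = int(np.argmax(counts))  # argmax takes the first (lowest) mode on ties
    return BGFSummary(
        estimated_location=loc,
        estimated_position_cM=float(chain.candidate_positions_cM[loc]),
        post_mean_mu=float(np.mean(chain.mu)),
        post_mean_abs_mu=float(np.mean(np.abs(chain.mu))),
        post_sd_mu=float(np.std(chain.mu, ddof=1)) if chain.n_samples > 1 else 0.0,
        post_mean_pi=chain.pi.mean(axis=0),
        post_mean_sigma2_e=float(np.mean(chain.sigma2_e)),
        qtl_variance=float(np.mean(chain.qtl_variance)),
        explained_variance=float(np.mean(chain.explained_variance)),
        k=chain.k,
        n_samples=chain.n_samples,
    )
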