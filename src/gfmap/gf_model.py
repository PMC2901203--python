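"""Gene-frequency model core for a biallelic QTL given marker haplotypes.

The model treats the unobserved QTL genotype of an unrelated individual as
the sum of two Bernoulli indicators, one per gamete.  The success
probability of each indicator is the conditional frequency pi_j of QTL
allele Q2 on the gamete's marker haplotype H_j — the disequilibrium
parameters.  Marker haplotypes are formed from k = 1 SNP (haplotypes 0/1,
pi of length 2) or k = 2 flanking SNPs (haplotypes 00/01/10/11, pi of
length 4; phase assumed known).

For unrelated individuals the polygenic background and the QTL's gametic
deviations merge into the residual, giving a diagonal residual covariance
with heterogeneous per-individual variances

    sigma*_i^2 = sigma_e^2 + pi_m (1 - pi_m) mu^2 + pi_p (1 - pi_p) mu^2,

where m/p index the maternal/paternal haplotypes of individual i.  The
phenotype likelihood is then an independent Gaussian per individual with
mean x_i' beta + (pi_m + pi_p) mu.

Candidate QTL locations: with k = 1 the location is restricted to the
window marker positions; with k = 2 to midpoints of adjacent markers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ld_simulator import StudyData

__all__ = [
    "BGFState",
    "candidate_positions",
    "n_candidates",
    "haplotype_codes",
    "haplotype_frequencies",
    "conditional_qtl_prob",
    "conditional_mean_q",
    "gametic_variance",
    "residual_variance",
    "phenotype_moments",
    "log_likelihood",
    "qtl_variance_statistic",
    "explained_qtl_variance",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class BGFState:
    """One point in the model's parameter space.

    ``location`` indexes the candidate grid (marker index for k=1, bracket
    index for k=2); ``pi`` is interpreted with respect to the SNP(s) at
    that location.
    """

    beta: np.ndarray
    pi: np.ndarray
    mu: float
    location: int
    sigma2_e: float

    def __post_init__(self) -> None:
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.pi = np.asarray(self.pi, dtype=float)
        if self.sigma2_e <= 0:
            raise ValueError("sigma2_e must be positive")
        if len(self.pi) not in (2, 4):
            raise ValueError("pi must have length 2 (k=1) or 4 (k=2)")
        if np.any(self.pi <= 0) or np.any(self.pi >= 1):
            raise ValueError("pi elements must lie strictly in (0, 1)")

    @property
    def k(self) -> int:
        return 1 if len(self.pi) == 2 else 2


def candidate_positions(positions_cM: np.ndarray, k: int) -> np.ndarray:
    """Candidate QTL positions: marker positions (k=1) or bracket midpoints (k=2)."""
    positions_cM = np.asarray(positions_cM, dtype=float)
    if k == 1:
        return positions_cM.copy()
    if k == 2:
        return 0.5 * (positions_cM[:-1] + positions_cM[1:])
    raise ValueError("k must be 1 or 2")


def n_candidates(n_markers: int, k: int) -> int:
    return n_markers if k == 1 else n_markers - 1


def haplotype_codes(study: StudyData, location: int, k: int):
    """Per-individual (maternal, paternal) haplotype codes at a candidate location.

    k=1: the allele of the SNP at ``location``.  k=2: code 2*left + right
    of the two SNPs flanking bracket ``location``.
    """
    mat, pat = study.maternal_haplotypes, study.paternal_haplotypes
    if k == 1:
        return mat[:, location].astype(np.int64), pat[:, location].astype(np.int64)
    if k == 2:
        m = 2 * mat[:, location].astype(np.int64) + mat[:, location + 1]
        p = 2 * pat[:, location].astype(np.int64) + pat[:, location + 1]
        return m, p
    raise ValueError("k must be 1 or 2")


def haplotype_frequencies(study: StudyData, location: int, k: int) -> np.ndarray:
    """Sample frequencies of the 2^k marker haplotypes at a candidate location."""
    m, p = haplotype_codes(study, location, k)
    counts = np.bincount(m, minlength=2**k) + np.bincount(p, minlength=2**k)
    return counts / (2.0 * study.n_individuals)


def conditional_qtl_prob(code, pi: np.ndarray):
    """P(gamete carries Q2 | marker haplotype) — a lookup of pi by haplotype code."""
    pi = np.asarray(pi, dtype=float)
    return pi[code]


def conditional_mean_q(maternal, paternal, pi: np.ndarray):
    """E(QTL genotype | marker data): sum of the two gametic Bernoulli means."""
    pi = np.asarray(pi, dtype=float)
    return pi[maternal] + pi[paternal]


def gametic_variance(code, pi: np.ndarray, mu: float):
    """Variance pi(1-pi) mu^2 of one gamete's QTL contribution given its haplotype."""
    p = np.asarray(pi, dtype=float)[code]
    return p * (1.0 - p) * mu * mu


def residual_variance(maternal, paternal, pi: np.ndarray, mu: float, sigma2_e: float):
    """Heterogeneous per-individual residual variance (diagonal of R*)."""
    if sigma2_e <= 0:
        raise ValueError("sigma2_e must be positive")
    return (
        sigma2_e
        + gametic_variance(maternal, pi, mu)
        + gametic_variance(paternal, pi, mu)
    )


def phenotype_moments(study: StudyData, state: BGFState):
    """Per-individual mean and variance of y under the model at ``state``."""
    m, p = haplotype_codes(study, state.location, state.k)
    mean = study.X @ state.beta + conditional_mean_q(m, p, state.pi) * state.mu
    var = residual_variance(m, p, state.pi, state.mu, state.sigma2_e)
    return mean, var


def log_likelihood(study: StudyData, state: BGFState) -> float:
    """Gaussian log-likelihood of the phenotypes; individuals independent."""
    if study.y is None:
        raise ValueError("study has no phenotypes")
    mean, var = phenotype_moments(study, state)
    if np.any(var <= 0):
        raise ValueError("non-positive residual variance")
    resid = study.y - mean
    return float(-0.5 * np.sum(_LOG_2PI + np.log(var) + resid * resid / var))


def qtl_variance_statistic(pi: np.ndarray, hap_freqs: np.ndarray, mu: float) -> float:
    """Additive QTL variance implied by (pi, mu) and marker-haplotype frequencies.

    The marginal Q2 frequency is p_bar = sum_j f_j pi_j; under random union
    of gametes the additive variance of the biallelic QTL is
    2 p_bar (1 - p_bar) mu^2.
    """
    pi = np.asarray(pi, dtype=float)
    hap_freqs = np.asarray(hap_freqs, dtype=float)
    if pi.shape != hap_freqs.shape:
        raise ValueError("pi and hap_freqs must have the same length")
    if not np.isclose(hap_freqs.sum(), 1.0):
        raise ValueError("hap_freqs must sum to 1")
    p_bar = float(hap_freqs @ pi)
    return 2.0 * p_bar * (1.0 - p_bar) * mu * mu


def explained_qtl_variance(maternal, paternal, pi: np.ndarray, mu: float) -> float:
    """Sample variance of the marker-predicted QTL genotypic values.

    Var_i of E(Q_i | M) mu over the individuals — the part of the QTL
    variance the marker haplotypes capture.  Unlike the additive variance
    2 p_bar (1-p_bar) mu^2, this functional is identified under the null:
    when the pi elements are equal the prediction is constant and the
    statistic collapses to zero regardless of mu, whereas the additive
    variance rides the flat (mu, sigma_e^2) likelihood ridge.
    """
    qhat = conditional_mean_q(maternal, paternal, np.asarray(pi, dtype=float))
    return float(np.var(qhat * mu))
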