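# Methods

## The mapping problem

`gfmap` fine-maps a single biallelic QTL inside a ~1 cM chromosomal
segment using dense, phased SNP haplotypes of unrelated individuals from a
purebred population.  With unrelated individuals only linkage
disequilibrium (LD) — the population-level association between marker and
QTL allele *states* — carries mapping information; cosegregation
(association of allele *origin* within families) contributes nothing and
is out of scope.

## The gene-frequency model

Phenotypes follow

    y_i = x_i' beta + q_i mu + u_i + e_i,

where `q_i ∈ {0,1,2}` counts copies of QTL allele Q2 and `mu` is the
additive substitution effect.  `q_i` is unobserved; its two gametic
indicators are Bernoulli with success probability `pi_j` — the conditional
frequency of Q2 on marker haplotype `H_j` of the corresponding gamete.
These `pi_j` are the disequilibrium parameters: under linkage equilibrium
all `pi_j` equal the QTL allele frequency and markers carry no positional
information; under complete LD they are 0/1 and the QTL genotype is read
directly off the markers.

Haplotypes are built from k = 1 SNP (`pi` of length 2) or k = 2 flanking
SNPs with known phase (`pi` of length 4, haplotypes 00/01/10/11).
Candidate QTL locations are the window's marker positions (k = 1) or the
midpoints of adjacent markers (k = 2).

For unrelated individuals the polygenic term `u_i` and the QTL's gametic
deviations merge into the residual.  Replacing `q_i` by its conditional
mean `qhat_i = pi_{m(i)} + pi_{p(i)}` leaves a heteroscedastic Gaussian
model with per-individual residual variance

    sigma*_i^2 = sigma_e^2 + pi_m(1-pi_m) mu^2 + pi_p(1-pi_p) mu^2.

This heterogeneous residual is the essential difference from the
least-squares comparator; when every `pi_j` is 0 or 1 the heterogeneity
vanishes and the two analyses coincide.

## Bayesian inference

Priors: flat on `beta`; scaled inverse chi-square (nu_e, S2_e) on
`sigma_e^2`; normal (0, sigma2_mu) on `mu`; discrete uniform over the L
candidate locations; logit-normal on `pi` (x = logit(pi) multivariate
normal with null mean and diagonal Sigma_x).

A blocked Gibbs sampler iterates three blocks per sweep: (1) `beta` drawn
exactly from its multivariate-normal full conditional (weighted normal
equations under the diagonal R*); (2) a joint Metropolis–Hastings move of
(`pi`, `mu`, `l`) — Gaussian random walks on logit(pi) and `mu`, and an
independent uniform draw of `l`; (3) a Gaussian random-walk MH move of
`sigma_e^2`, rejecting non-positive proposals outright.  Because the walk
on `pi` is proposed on the logit scale, the logit Jacobian of the pi-space
prior cancels against the transformed proposal density, so the acceptance
ratio uses the x-space normal prior directly.  The stationary distribution
was validated against a dense-grid numerical normalization of the
posterior on a small instance (the flat-prior intercept integrated out
analytically); this check caught — and now guards against — the classic
error of carrying the Jacobian into the ratio for a logit-scale walk.

Under a location move the current `pi` vector is re-interpreted with
respect to the SNP(s) at the proposed location; its dimension never
changes.  The sign of `mu` is unidentified jointly with the
`pi <-> 1-pi` relabelling, so summaries report |mu| alongside mu, and the
estimated location is the posterior mode of `l` (ties to the lower
index).

### Default hyperparameters

| parameter | default | role |
|---|---|---|
| sigma2_mu | 1.0 | prior variance of mu (phenotypes standardized to unit variance) |
| nu_e, S2_e | 4, 0.5 | weakly informative prior on sigma_e^2 (prior mean 1) |
| sigma2_x | 4.0 | prior variance of logit(pi) |
| sigma2_x_prop, sigma2_mu_prop, sigma2_e_prop | 0.25, 0.01, 0.01 | random-walk variances |
| chain | 20 000 sweeps, 5 000 burn-in, thinning 5 | full-length analysis chain |

`sigma2_x = 4` (logit-scale SD 2) keeps the prior 95% interval of each
`pi` near (0.02, 0.98).  A unit logit variance was tried first and proved
measurably informative against strong disequilibrium: with `pi` truth
(0.05, 0.95) the prior pulled the `pi` spread toward zero and inflated
`mu` along the weakly identified ridge where only the product
(pi-spread × mu) is pinned by the mean model, leaving the posterior mean
of `mu` more than 3 posterior SDs from truth in a third of pilot
replicates.

Proposal variances adapt only during burn-in (windowed rescaling toward
an acceptance rate of 0.2–0.5, bounded within a factor 16 of the
configured values) and are frozen for the sampling phase, whose MH ratios
therefore assume fixed symmetric proposals.  The adaptation signal for the
(`pi`, `mu`, `l`) block is the acceptance rate among proposals whose drawn
location equals the current one: the overall block acceptance is capped
near 1/L by the uniform location proposal whenever the posterior
concentrates on one candidate, and tuning on it would collapse the step
sizes.

### Detection statistic

The detection statistic of the Bayesian analysis is the posterior mean of
the *marker-predicted QTL variance*

    V_pred = Var_i( qhat_i * mu ),

the sample variance of the individuals' conditional QTL means times the
effect.  The additive QTL variance `2 p_bar (1-p_bar) mu^2`
(p_bar = sum_j f_j pi_j at the sampled location, f the sample haplotype
frequencies) is also computed and reported per sample, but it is not
identified under the null: when all `pi_j` coincide, the gametic-variance
heterogeneity is the same constant for every individual and the likelihood
is flat along a (mu, sigma_e^2) ridge, so its null posterior mean reflects
the prior scale rather than the data and the null-calibrated test loses
most of its power (0.45 instead of ~0.95 in a pilot of the 5% variance,
0.1 cM, n = 500 cell).  V_pred collapses to zero whenever `pi` is
constant, regardless of `mu`, which keeps the null distribution tight and
the calibrated test sharp.

## Least-squares comparator (LSR)

At each candidate position the phenotype is regressed on the copy numbers
of the 2^k marker haplotypes (one observed haplotype column dropped
against the intercept) and an F-test of equality of haplotype effects is
performed; df1 = observed haplotypes − 1, df2 = n − parameters.  The
estimated location minimizes the p-value; p-values below 1e-15 are treated
as numerically zero and the middle zero position is taken (the lower of
the two middles for an even count).  Haplotypes unobserved in the sample
are dropped with df1 reduced accordingly.

## LD simulator

2000 biallelic loci (scalable) spaced 0.01 / 0.005 / 0.002 cM apart evolve
from Bernoulli(0.5) independence (Hardy–Weinberg and linkage equilibrium)
through 1000 generations of random mating at effective size 500 followed
by 50 generations at size 100, with symmetric per-gamete mutation at
2.5e-5 per locus — approaching mutation–drift equilibrium while building
LD over short distances.  Random mating is discrete-generation with
parents drawn uniformly with replacement (selfing allowed).  Crossovers
are one Bernoulli(d/100) phase switch per adjacent-locus interval of d cM
(no interference; indistinguishable from any map function at these
distances).  The simulator was validated against the closed-form drift
decay E[H_t] = H_0 (1 − 1/(2N))^t and the martingale property of allele
frequencies.

Every tenth locus (the last of each 10-locus bin) is a QTL; the rest are
candidate markers.  In the final generation one marker per bin is selected
(allele frequency closest to 0.5, ties toward the lower index), and among
QTL loci whose bin admits the window geometry the one closest to 0.5 is
chosen.  The 1 cM analysis window consists of 11 / 21 / 51 selected
markers (marker spacing 0.1 / 0.05 / 0.02 cM) placed so the QTL lies
exactly 0.3 cM right of the first window marker *on the nominal bin grid*:
analysis coordinates are j × spacing for marker j, while the physical
locus positions drive recombination.  Monomorphic required bins or a
monomorphic QTL trigger resimulation of the whole history with a fresh
seed.

Study individuals are drawn from the final census of 100 by one additional
meiosis per gamete from a uniformly chosen final-generation parent, so
samples larger than the census preserve the population's
haplotype-frequency distribution.  Phenotypes are
`y_i = q_i mu_true + e_i` with `e_i ~ N(0, 1 − h2_qtl)` and
`mu_true = sqrt(h2_qtl / (2p(1−p)))` at the pool QTL frequency `p`, so the
QTL explains the prescribed fraction (2% or 5%) of unit phenotypic
variance; the null sets `mu_true = 0`.

`synthesize_ld_study` is a separate, synthetic shortcut generator that
prescribes the marker–QTL disequilibrium (`pi`) directly and fills the
flanking markers with a Markov-chain LD profile; it exists for fast
parameter-recovery experiments where the true `pi` must be known exactly,
and does not emulate the drift history.

### What the generator does and does not emulate

It reproduces the study conditions of the simulation protocol: neutral
two-phase demography, bin-based marker/QTL ascertainment toward allele
frequency 0.5, known phase, a single additive biallelic QTL and Gaussian
residuals.  It does not model genotyping error, phase uncertainty (real
2-SNP haplotypes must be inferred), multiple or multiallelic QTL,
selection, or population structure — so passing tests demonstrate
correctness of the methods under the model's own assumptions, not
robustness to these real-data complications.

## Power and precision harness

For each replicate a fresh LD history (or a draw from a shared history
pool, a configuration flag) is simulated, a panel and study sample built,
and phenotypes generated under the null (no QTL) or the alternative.  The
critical value is the empirical upper 10% quantile — the ceil(0.9 R)-th
order statistic — of the method's statistic over R null replicates; power
is the fraction of alternative statistics strictly above it; precision is
the mean absolute error (cM) of the estimated location on the nominal
grid, whose worst case is 0.7 cM given truth at 0.3 cM in a 1 cM window.

## Problem sizes used in the shipped tests and acceptance script

Full-scale cells (1500+ null replicates, each atop a 1050-generation
history, plus one MCMC chain per Bayesian replicate) are a
multi-CPU-day computation.  The shipped experiments therefore use a
scaled protocol chosen as this package's own reduced study conditions:
400 simulated loci (40 bins) instead of 2000 — identical local LD, fewer
ascertainment candidates — with the demography itself unchanged; fresh
histories per replicate in the scaled Table checks; 200 null + 200
alternative replicates per checked cell; and short per-replicate chains
(3000 sweeps, 800 burn-in) whose summaries pilot runs showed to be stable
for detection and location.  Statistical checks compare against the
published full-scale values using the binomial/normal uncertainty implied
by the reduced replicate counts.

## Known limitations

* Phase is assumed known for k = 2; unphased data are rejected, not
  phased.
* Related individuals (gametic covariance recursion, pedigree
  conditional probabilities) are out of scope.
* The `mu` sign is reported but unidentified; use |mu| or the variance
  functionals.
* The additive-variance functional `2 p_bar (1-p_bar) mu^2` should be read
  as an estimate of the QTL variance only when the data identify `pi`
  (detectable LD); under the null it reflects the prior.
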