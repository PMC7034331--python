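# Methods

## Scope

`voisyn` computes the expected value of perfect information (EVPI), of
partial perfect information (EVPPI) and of sample information (EVSI)
from a single Monte Carlo sample of a Bayesian model's joint posterior,
for decision problems whose optimal expected loss is a known function
h of the posterior mean of the decision-relevant outputs alpha:
finite-action choices (h = min of action-specific expected losses) and
point estimation of scalars or vectors under quadratic loss (h = the
variance, a weighted quadratic form c' cov c, or det(cov)).  EVSI curves
are monetized and traded against sampling costs to find an optimal
sample size (expected net benefit of sampling, ENBS).  The flagship
application is a multiparameter evidence synthesis estimating HIV
prevalence among men who have sex with men (MSM) in London, 2012.

## The regression estimators

For EVPPI of a parameter subset phi, the conditional mean
g(phi) = E(alpha | phi) is estimated by nonparametric regression of
posterior draws of alpha on draws of phi.  The expected loss after
learning phi is the Monte Carlo mean of h evaluated at the fitted
values; for quadratic loss this is the mean squared residual, and
equivalently EVPPI is the variance of the fitted values (the two agree
exactly for least-squares fits with an intercept; both use a K-1
denominator so the variance decomposition is an identity).  For vector
outputs, one regression per component yields the empirical covariance
of the residuals, to which the A-/D-optimal functional is applied.  For
EVSI, the same regression is applied with the sufficient statistic T(y)
of a posterior-predictive-simulated future dataset in place of phi.

Backends:

* `gam` (default): additive cubic B-spline bases at quantile knots
  (default 10 df per predictor), fitted by OLS.  Deterministic, exact
  coefficient covariance, supports up to 5 predictors.  A predictor
  with few distinct values (a count statistic y/n at small n) gets an
  indicator basis — the saturated per-level-mean fit, which is the
  exact conditional-mean estimator for a discrete statistic.
* `mars`: multivariate adaptive regression splines — greedy forward
  selection of reflected hinge pairs (quantile-knot candidates, up to
  21 terms, interaction degree 2) followed by backward pruning by
  generalized cross-validation (penalty 3), final model refitted by
  OLS.  Used when interactions between components of phi matter.

The spline backend is the default because, at the p <= 3 regimes this
package targets, it is deterministic, fast at K = 150,000 draws, and
carries an exact asymptotic coefficient covariance; the MARS backend is
retained for interaction-heavy conditioning sets.

Standard errors: coefficient vectors are simulated from their asymptotic
normal distribution (default 200 draws, seeded) and the VoI recomputed
from the perturbed fitted values; the SE is the standard deviation
across simulations.  The simulation is performed in the orthonormal
column space of the design (fitted + sigma Q z), which is the same
distribution as simulating the coefficients through sigma^2 (X'X)^+ but
immune to ill-conditioning.  This SE reflects regression-coefficient
uncertainty only; the Monte Carlo error of the draws themselves is
assessed in the test suite by draw-level bootstrap and seed panels.

Negative VoI estimates (possible from regression noise when the true
value is near zero) are reported as computed and flagged, never
truncated, since truncation would bias the standard errors.

## The HIV evidence-synthesis model

Founders and priors (all bounds strict):

| founder | prior | role |
|---|---|---|
| log mu_pop | N(0, 1000^2) | log male population of London |
| rho (4-simplex) | Dirichlet(1,1,1,1) | GMSM / NGMSM / PMSM / other fractions |
| a_S | exp(a_S) ~ N(1, 0.018^2) | register reporting bias (+-3%) |
| a_H | U(0,1) | P(new diagnosis \| diagnosed GUM attender) |
| a_delta_g, g=G,N,P | U(0,1) | diagnosed fraction scaling, delta_g = a_delta_g (1 - pibar_g) |
| gamma_1..gamma_3 | U(0,1) | clinic cascade: undiagnosed, offered, accepted |
| gamma_4 | U(0, 0.15) | test positivity |
| a_UN | U(log 0.5, log 1.5) | log odds-shift for unoffered-test prevalence |
| a_OP | U(0,1) | scales the opt-out excess prevalence a_EX = a_OP (0.15 - gamma_4) |
| p_G_GM, p_N_GM | U(0,1) | venue-survey prevalences |
| u_pibar_P | U(0,1) | pibar_P = u pibar_N (PMSM prevalence below NGMSM) |
| pibar_G_free | U(0,1) | variant (a) only |

Deterministic links: pi_UN = gamma1 (1-gamma2) p_UN with
logit(p_UN) = logit(gamma4) + a_UN; pi_OP = gamma1 gamma2 (1-gamma3)
(gamma4 + a_EX); pi_GD = gamma1 gamma2 gamma3 gamma4; base case
pibar_G = pi_UN + pi_OP; pi_GA = (pibar_G + pi_GD)/gamma1; the odds
ratio or_GM = odds(p_N_GM)/odds(p_G_GM) maps odds(pibar_G) to
odds(pibar_N); delta_g = a_delta_g (1 - pibar_g) guarantees
pi_g = pibar_g/(1 - delta_g) < 1.  Counts follow as
mu_Ug = pibar_g rho_g mu_pop etc.  Variant (a) replaces the pibar_G
construction by the free founder; variant (b) sets
pidelta_G = (1 - gamma1) + pi_GD directly from the cascade.

Likelihood: Poisson for the population count and the register count
(with log mu_M = a_S + log mu_D), multinomial for the survey subgroup
counts, binomials for the new-diagnoses count (p_H = a_H mu_DG / mu_D),
the four cascade steps, the anonymous-survey positives (pi_GA) and the
two venue-survey arms.  Every term can be toggled independently
(prior-only sampling and single-arm conjugate checks use this).

Two published quantities are exposed as distinct columns because the
source analyses use both: `mu_U_2grp` = mu_UG + mu_UN (the default for
EVSI/ENBS analyses of the undiagnosed total) and `mu_U_3grp` adding
mu_UP.  The PMSM submodel here (pibar_P ~ U(0, pibar_N), delta_P
mirroring the other groups) is a reconstruction — the original
description of that subgroup is one sentence — so three-group
quantities carry extra model risk, and the two-group total is preferred
wherever the published analyses define it that way.

### Input data

All observation counts ship in `src/voisyn/hiv/data/london_msm_2012.yaml`.
The one value not available as a printed observation is the ONS male
population count; the file uses 2,050,000, the mid-2012 estimate of men
aged 15-44 resident in London — the age range of this model lineage.
Case-count outputs scale linearly in this input, so analyses that
depend on it inherit its uncertainty; prevalences and EVPPI proportions
do not.  The NGMSM venue-survey denominator is 452 (a 492 appearing
once in the source material is treated as a typo).

### Posterior sampling

No Hamiltonian Monte Carlo backend is available in this stack, so the
posterior is sampled with the affine-invariant ensemble sampler
(emcee) on an unconstrained scale: log for mu_pop, stick-breaking for
the simplex, logit (plain, scaled, or affine) for the bounded founders,
with the corresponding Jacobians.  Defaults: 4 independent ensembles of
64 walkers, 5,000 burn-in + 3,000 retained steps, thinned to 5,000
draws per ensemble (K = 20,000; the published analyses used 150,000,
which this implementation reaches by thinning less).  Initialization is
two-stage: a 200-step exploration from data-informed overdispersed
starts, then all walkers restart in a tight ball around the best point
found — without this, a walker started far in the tails can take
thousands of stretch-move steps to reach the bulk.  A post-burn guard
drops any walker whose mean log-posterior sits more than 25 units below
the ensemble median (a stuck walker; the count is reported in the
diagnostics and is zero in routine runs).  Prior-only runs instead
start every walker at an exact prior draw (a stationary start) and skip
both stages.

Diagnostics: split-R-hat across ensembles (each chain ordered by step,
so drift is detected) with a 1.01 reporting threshold, and effective
sample sizes computed on per-walker chains, where autocorrelation is
estimated honestly — pooling walkers interleaves them and makes draws
look spuriously independent.  Ensemble coupling still makes even the
per-walker ESS optimistic, so distribution-level tests (KS) thin to
well below the nominal ESS.

### Desk-scale test conditions

The test suite fits the model with 2 ensembles at reduced lengths
(about 8,000-20,000 retained draws) and checks published values at
Monte Carlo tolerances: 10% for population-scale-free quantities, 15%
for case counts (population-input and PMSM sensitivity) and for the
venue-survey design.  One suite-level fit retains 150,000 draws to
verify that regression standard errors are below 1% of the EVPPI
estimates at the published sampling scale.

## Future-study simulation

* GUM Anon: y ~ Binomial(n, pi_GA) per draw; T = y/n.
* GMSHS: the number of the n participants who are clinic attenders is
  N_G ~ Binomial(n, q) with q resampled per draw from Beta(493.5,
  452.5), the Jeffreys posterior of the observed 493/945 venue split —
  the attendance predictive is not specified by the source analysis,
  and this choice is the main replication risk for venue-survey EVSI.
  Positives are binomial within group; T is the odds ratio of the
  Jeffreys-smoothed proportions (y + 0.5)/(N + 1), which is finite even
  when a group is empty.

Each sample size on an EVSI curve uses an independent generator seeded
from (seed, n), so curves are reproducible and independent across n.

## ENBS

Benefits: linear in variance reduction (lambda per unit) or per halving
(lambda log2(v0/v)).  Costs: fixed + unit cost per participant.  The
coarse EVSI curve is made monotone by isotonic regression (anchored at
EVSI(0) = 0, capped at the baseline variance) and interpolated onto the
dense integer grid with a monotone cubic (PCHIP) before locating the
net-benefit argmax (first index on ties); the raw coarse-grid argmax is
reported alongside.  Smoothing exists because independent per-n Monte
Carlo noise would otherwise jitter the argmax; it cannot repair a
mis-shaped curve, and optima at large n (shallow marginal EVSI) are
intrinsically less stable than optima at small n.

## Verification strategy

* Conjugate fixtures (normal-known-variance, beta-binomial, independent
  Gaussian sum, two-action Gaussian) with closed-form EVPPI/EVSI, exact
  enumeration over future datasets, and nested two-loop Monte Carlo —
  all independent of the regression path they check.
* The HIV joint density is verified against a second, deliberately
  literal scalar transcription built on scipy.stats (agreement 1e-8),
  and per-draw model identities (the undiagnosed decomposition,
  count additivity, the delta_g support construction) are asserted
  exactly on every posterior draw.
* Prior-only sampling is tested against the stated marginal priors by
  KS at alpha = 0.01, and a single-likelihood-arm run against its
  Beta conjugate posterior.

What the fixtures do not show: the synthetic fixtures are
low-dimensional with well-specified smooth conditional means, so they
validate the estimators, not the behaviour of nonparametric regression
under pathological posteriors (heavy tails, near-deterministic ridges).
The HIV model's own tails (e.g. diagnosed prevalence under a weakly
identified diagnosed fraction) are exercised only by the model checks
above.

## Known limitations

* The N(0, 1000^2) prior on log(mu_pop) is truncated at 700 in the
  implementation so that exp() stays inside floating-point range; the
  likelihood pins log(mu_pop) near 14.5 in every fit, so only
  prior-only runs see the truncation.

* EVSI requires a scalar (or low-dimensional) sufficient statistic;
  designs without one are out of scope.
* The default spline backend is additive; conditioning sets with strong
  interactions need `method="mars"` (p <= ~5 either way).
* Ensemble MCMC mixes slowly for weakly identified founders (a_H and
  the a_delta_g trade off along a ridge); the defaults are sized so the
  worst-case split-R-hat is ~1.01, but halving the burn-in degrades it.
* ENBS optima inherit the EVSI curve's Monte Carlo error; at shallow
  optima (large n) the argmax can move by tens of participants between
  seeds even after smoothing.
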