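# Methods

`fidlmm` implements three inferential treatments of the same two-level
linear mixed model, plus the preprocessing that produces its response
variable and a synthetic-data generator that serves as the test bed for all
of them.  This note records the model, the numerical choices, and what the
validation suite does and does not establish.

## The model

Repeated observations (12 task tertiles per wave, up to 2 waves) are nested
in subjects.  Level 1 regresses the response — systolic blood pressure
responsivity, SBP-R, in mmHg above resting baseline — on the within-person
time index (tertile, treated as a continuous 1–12 score so that a single
slope and its cross-level products are defined).  Level 2 models the
person-specific intercept and slope as linear functions of person-level
covariates (baseline SBP, a cognition composite, physical/mental-health
composites, log hair cortisol).  Substituting Level 2 into Level 1 gives
the marginal form used everywhere in the package:

    y = X beta + u + e,      u_i ~ N(0, tau00),  e ~ N(0, sigma2 I),
    V = Cov(y) = tau00 * S_a + sigma2 * I_n,

with `S_a` the same-subject indicator matrix.  `X` holds an intercept, the
main-effect columns and raw (uncentred) product columns for the cross-level
interactions; covariates enter on their supplied scale, so coefficients are
unstandardized and the ±1 SD simple-slope arithmetic works directly on
them.  Only a random intercept is supported: random slopes and crossed
designs are out of scope by design.

`V` is block diagonal by subject, each block `sigma2 I + tau00 11'`, so
solves, log-determinants and `S_a`-products are O(n) via Sherman–Morrison.
Every block-structured computation is property-tested against brute-force
dense linear algebra on random instances.

## Frequentist route

REML with the fixed effects profiled out:

    l_R = -1/2 [ (n-p) log 2pi + log|V| + log|X'V^{-1}X| + r'V^{-1}r ].

Optimization runs on log variances (Nelder–Mead from a method-of-moments
start plus two fixed jitters, because small-sample REML surfaces can be
nearly flat in tau00), and the tau00 = 0 boundary is profiled separately
and wins ties — a zero variance estimate is legitimate here.  Per-
coefficient t-tests use Satterthwaite degrees of freedom: the variance of
each contrast is differentiated numerically with respect to
(tau00, sigma2), and the variance-component covariance comes from the
inverse negative Hessian of `l_R` (central differences on the variance
scale).  When the Hessian is unusable, or the moment-matched df explodes on
a flat ridge (boundary tau00 = 0), the df falls back to (or is capped at)
the regression value n − p.  On a frozen benchmark dataset the estimates,
SEs, Satterthwaite df and p-values agree with R's lmerTest to at least
three significant figures, and beta/variance components match statsmodels
MixedLM at run time.

Simple slopes of a focal term at moderator mean ± 1 SD use the
between-person moderator distribution (one value per subject), the delta
method on the GLS coefficient covariance, and Satterthwaite df for the
contrast.  The unconditional variance partition reports
sigma2/(sigma2+tau00) and its complement as percentages.

Variance-component "SEs" printed by mixed-model software depend on an
undocumented convention; we report none for them in the side-by-side
report and treat them as not directly comparable across implementations.

## Fiducial route

The generalized fiducial distribution comes from inverting the
data-generating equation `Y = X beta + V^{1/2} U`, `U ~ N(0, I)`.  Its
unnormalized density is the likelihood times a Jacobian factor `D(M)`,

    M = [ X,  S_a V^{-1}(y - X beta),  V^{-1}(y - X beta) ],

an n × (p+2) matrix whose columns are the partial derivatives of the model
equation with respect to (beta, tau00, sigma2) evaluated at the inverse.
Two conventions for `D` circulate: `det(M'M)` and `sqrt(det(M'M))`.  The
package defaults to the square-root form, which is the one the general
theory it follows uses, and exposes `sqrt_jacobian=False` for the other;
the choice is validated behaviourally — with the square root, the
one-sample limit reproduces the classical Student-t fiducial distribution
exactly, and the simulated 95% intervals show near-nominal frequentist
coverage.  Theta-independent constant factors in the derivative columns
(the ½'s from differentiating with respect to variances) are omitted: they
shift the log density by a constant that cancels under normalization, a
fact the test suite checks numerically.

Sampling is adaptive Gaussian random-walk Metropolis on
(beta, log tau00, log sigma2); the log transform adds the usual
`+ log tau00 + log sigma2` term and makes the tau00 = 0 boundary
unreachable — a deliberate interior parameterization (the frequentist
route is the one that reports boundary estimates).  Chains initialize at
REML estimates with per-chain jitter.  The global step scale is tuned by
Robbins–Monro toward 30% acceptance during warmup only, and the proposal
covariance is re-estimated once from the first warmup half.  Defaults: 4
chains, 2 000 warmup iterations, 5 000 kept draws per chain with thinning
2; rank-normalized split R-hat and effective sample sizes come from arviz,
and R-hat > 1.05 is recorded as a warning, not an error.  Identical seeds
give identical draws.

Correctness of the sampler is defined by oracles, not by comparison with
any particular MCMC tooling: a 10 000-draw run matches the t(n−1)
confidence distribution in the one-sample configuration (KS < 0.05) and a
grid-normalized density in a two-parameter model (KS < 0.05), and 95%
fiducial intervals for the fixed effects cover the generating values in
[0.90, 0.99] of 300 replications at the study size (28 subjects, ~18
observations each).

Intervals are equal-tailed quantiles (not HPD), available for variance
components as well as fixed effects.  The equivalence-style null call
(`null` if the interval contains 0 and stays inside ±bound, `nonnull` if
it excludes 0, otherwise `inconclusive`) requires an analyst-supplied
bound; the package deliberately refuses to default it.

## Bayesian route

Candidate models are all subsets of the declared fixed-effect terms that
respect marginality — an interaction enters only when every lower-order
candidate term built from its factors is present — with the intercept and
the random intercept in every candidate, including the "intercept-only"
null.  On the two published term families this enumeration yields exactly
26 and 76 candidates.

Each candidate's marginal likelihood uses the Jeffreys–Zellner–Siow
construction: Jeffreys priors on the grand mean and sigma2, standardized
effect columns with conditionally Gaussian g-priors, and inverse-gamma(1/2,
r²/2) mixing on each g (so sqrt(g) is half-Cauchy with scale r).  Scales
follow the cited defaults: sqrt(2)/4 for continuous covariates, 0.5 for
binary/factor-like columns, 1 for the random-intercept block; all are
configurable.  By default columns share one g per scale class (continuous /
binary / random intercept), which matches the convention of the standard
Bayes-factor tooling and keeps the mixing integral at ≤ 3 dimensions;
`per_term_g=True` gives every term its own g.  Conditional on g the
marginal is closed-form; Woodbury identities reduce every evaluation to a
k × k Cholesky (k = number of effect + subject columns), and the g
integral is evaluated by adaptive quadrature in log g for ≤ 2 dimensions
(with wide windows, because the Cauchy-implied right tail decays only
exponentially in log g) or by importance sampling from a Laplace-fitted
product-t(4) proposal otherwise; both paths return error estimates and are
required to agree on models where both apply.  The engine reproduces the
closed-form one-sample JZS Bayes factor to better than 0.1% over a grid of
(n, t), and Bayes factors are invariant to covariate rescaling by
construction (standardization happens internally; this module never reports
coefficients).

Reported K values are Bayes factors against the intercept-only null;
pairwise evidence ratios carry the usual heuristic labels (strong ≥ 20,
substantial ≥ 10, anecdotal otherwise, symmetric under reciprocals).
Reproducing any particular published K magnitude requires the original
participant data and is not attempted; only the self-contained counts and
ratio arithmetic are validated.

## Preprocessing

Baseline SBP is the mean over the final 300 s of the rest window (a shorter
window is used whole, with a warning).  Each task level's 1 Hz samples are
split into three contiguous spans whose lengths differ by at most one
second; leftover seconds go to the earliest tertiles by default
(configurable — the convention is not dictated by anything and is logged).
Sample timestamps are 0-based and marker intervals are half-open
[start, end), so spans tile each level exactly.  SBP-R is tertile mean
minus baseline, which makes the whole pipeline invariant to adding a
constant to a trace.  Hair cortisol is natural-log transformed (log10
available by hand); non-positive concentrations become missing values with
a logged count.  Person-level composites are transparent z-score means of
their sign-oriented indicators, re-centred to mean 0.  This is an openly
documented substitution for latent factor scoring — the factor model behind
the published composites is not available — and it cannot and does not try
to reproduce factor-score variances; composite SDs are ≤ 1 by construction.

## Synthetic data

`simulate_dataset` draws person covariates from configurable normal
distributions (defaults are the published descriptive moments, e.g.
log-cortisol mean 2.35, SD 1.47), assembles the response exactly per the
two-level algebra, and applies completely-at-random missingness.  The
default configuration is the study condition: 28 subjects, 2 waves × 12
tertiles, 25% missingness (so ~504 of 672 rows survive; the real
missingness mechanism is unreported, and two rows per subject are exempted
so every subject remains estimable), generating variances tau00 = 125.97
and sigma2 = 131.22 (the published unconditional partition, recovered as
~49/51 by the fitted partition), and fixed effects equal to the published
Model 1 estimates.  Wave-2 covariates are generated as correlation-0.6
perturbations of wave 1 — a value chosen once as a plausible six-month
retest correlation for health composites — so the change-moderator models
are estimable.  `simulate_trace` produces 1 Hz traces whose within-tertile
mean follows a configurable engagement profile, exercising the
preprocessing end to end.

What the generator does *not* emulate: beat-to-beat cardiovascular
dynamics, informative missingness, non-normal covariates, and the factor
structure of the real composites.  Passing tests therefore establish
correctness of the algorithms under the stated model, not robustness to
violations of it.

## Problem sizes and numerical settings

The validation suite scales its simulations to what the checks need: the
coverage study runs 300 replications at the study size with a reduced
sampler schedule (2 chains, 1 000 warmup, 1 200 kept draws, thinning 2 —
enough mixing that interval quantiles are stable); parameter recovery uses
200 subjects; dense-matrix oracles use ≥ 100 random instances with n ≤ 24;
the closed-form and grid oracles use 10 000 draws.  Quadrature tolerances
(1e-10 absolute on the shifted integrand), the 0.02 log-scale error
ceiling with one quadrupled-budget retry for the g integral, the 1e-8
collinearity threshold in design construction, and the df cap at n − p are
the package's numerical guardrails; all are visible in the source next to
the code they protect.

## Known limitations

- Only random-intercept models; the three-level (wave-within-person)
  variance question is out of scope.
- Satterthwaite df (not Kenward–Roger), matching the default convention of
  the standard mixed-model testing tools.
- The fiducial sampler is a generic adaptive random-walk; long analyses of
  larger models may need longer schedules than the defaults.
- Whether baseline SBP should be forced into every Bayesian candidate
  model is unknowable from the published description; the default leaves
  it free (`always_include` forces it).
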