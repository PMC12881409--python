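# Methods

## Setting

The package analyzes *series of N-of-1 trials*: every participant runs a
personal 4-week crossover trial with weekly alternating intervention (A) and
control (B) phases in one of two sequences, ABAB or BABA, allocated
alternately by enrollment order (the first enrollee receives ABAB; the rule
is a deterministic parity so allocations are reproducible and balanced).
Two outcomes are self-reported daily on a 1–10 visual analog stress scale:
the stress level of the day and the stress level expected for the next day.
Missing daily entries are first-class data — a day without a report stays in
the dataset as an explicitly missing record and the analysis uses all
available observations regardless of completeness or adherence
(intention-to-treat).

## Individual-level model

For one participant with treatment indicator X_t (1 on A-days):

    y_t = alpha + tau * X_t + eps_t
    eps_t = rho * eps_{t-1} + eta_t,    eta_t ~ Normal(0, sigma^2)

tau is the individual intervention effect in scale points; negative tau
means stress reduction. The AR1 error process is stationary, so the
covariance between observations on days s and t is
`sigma^2/(1-rho^2) * rho^|t-s|`. Because AR1 is Markov, the likelihood of an
irregularly observed series factorizes into gap-aware conditionals — an
observation following a gap of g days has conditional correlation `rho^g`
and conditional variance `sigma^2/(1-rho^2) * (1 - rho^(2g))` — which the
implementation evaluates in O(n) and which a property test pins against the
dense multivariate-normal density on random instances to 1e-8.

### Priors ("non-informative", made concrete)

- alpha, tau: flat.
- sigma^2: Jeffreys, p(sigma^2) ∝ 1/sigma^2, giving the conjugate
  inverse-gamma conditional.
- rho: uniform over a fixed grid of 399 points spanning (-0.995, 0.995).

### Sampler

Metropolis-within-Gibbs with three blocks per sweep: (alpha, tau) jointly
from the conjugate generalized-least-squares normal (the AR1 whitening
transform turns the GLS problem into OLS); sigma^2 from its inverse-gamma
conditional; rho by griddy Gibbs — the full conditional is evaluated at
every grid point and sampled exactly. The griddy update was chosen over a
random-walk step because it has no tuning parameters and is reproducible
draw-for-draw given the seed. Per-series grid quantities that depend only on
the observation gaps are precomputed once, so the grid sweep costs three
matrix-vector products per iteration.

Defaults mirror the study protocol: 2 chains, 5,000 burn-in sweeps, 10,000
kept iterations per chain ("10,000 iterations" is read as kept draws per
chain, so pooled summaries use 20,000 draws). Chain seeds derive from the
master seed through a fixed SeedSequence splitting rule. Summaries always
pool chains.

### Degenerate inputs

A series with fewer than 4 observed outcomes, or with all observations in a
single phase type, raises an identifiability error rather than returning a
meaningless posterior. The bounded 1–10 outcome is modeled as an unbounded
Gaussian, exactly as the linear analysis it implements; no censoring
correction is applied (a known limitation: strong effects near the scale
ends are attenuated).

## Population-level model

    y_it = alpha + tau * X_it + a_i + b_i * X_it + eps_it
    a_i ~ Normal(0, sigma_a^2),   b_i ~ Normal(0, sigma_b^2)

with AR1(rho, sigma) errors within participant and rho, sigma shared across
participants. The random treatment slope b_i is on by default (the design
exists because individual effects are expected to be heterogeneous); a
random-intercept-only variant is available (`MCMCConfig.random_slope`).
Hierarchical SDs sigma_a, sigma_b get half-Cauchy(0, 5) priors — improper
priors on hierarchical variances risk improper posteriors — updated by
random-walk Metropolis on the log scale (step 0.3). Fixed effects and
random effects have conjugate normal updates; rho is sampled by griddy
Gibbs on the whole-data conditional. With sigma_a = sigma_b = 0 data the
posterior for tau collapses onto the pooled single-level fit, which is
regression-tested against a precision-weighted combination of individual
fits.

Note the population mean effect tau is identified jointly with the prior
mean 0 of the b_i; with few participants and high autocorrelation its
posterior is wide (SE around 0.2–0.3 points at 40 participants with ~50%
missingness), which is exactly the regime the recovery test exercises.

## Effect summaries

From pooled tau draws: posterior mean; equal-tailed 95% credible interval
(2.5/97.5 empirical quantiles — equal-tailed, not HPD); P(any reduction) =
P(tau < 0); P(clinically relevant reduction) = P(tau <= -0.5). The 0.5-point
threshold is the pre-specified clinically relevant stress reduction. A
participant is a *responder* when that probability, rounded to 2 decimals,
is at least 0.70 — the rounding-first rule is the only reading under which a
posterior probability of 69.75% counts as reaching the 70% threshold; raw
comparison is available by raising `probability_rounding`. Reduction curves
report P(-tau > x) over a grid, so positive values mean stress decrease and
the curve is non-increasing.

## Synthetic cohorts

The generator inverts the analysis model, adding what the analysis omits so
tests can probe misspecification: participant heterogeneity
(alpha_i ~ N(alpha0, sigma_a^2), tau_i ~ N(tau_bar, sigma_b^2)), a weekend
offset (default -0.5 points on days 6 and 7 of each study week; the anchor
is configurable since no calendar alignment is fixed), integer rounding
(half away from zero) and clipping to [1, 10], MCAR missingness, and
imperfect adherence flags (symmetric errors at rate 1 - adherence_prob).

Defaults are the study conditions: 28-day trials, rho = 0.8, innovation SD
derived from the design-stage marginal residual SD of 2.41 points
(sigma = 2.41 * sqrt(1 - rho^2) ≈ 1.45), missingness 0.47 (so the documented
fraction is ≈53%, matching the observed documentation rate), adherence
0.919. Where the study conditions fix no value the defaults are: baseline
mean 4.0 points and between-person intercept SD 1.0 (documented phase means
cluster near 4), mean effect -0.18 points with between-person effect SD 1.0
(population effects were small while individual posterior means spanned
roughly -3 to +3). A continuous mode (`integer_rounding=False,
clip_to_scale=False`) disables the response-scale discretization for exact
parameter-recovery tests; its latent-scale outcomes may leave [1, 10] and
are marked accordingly. The generator does **not** model informative
dropout, time-of-day effects, carryover, or learning — passing recovery
tests therefore show correctness of the estimator under MCAR Gaussian AR1
conditions, not robustness to those real-data features.

## Design power

Power is defined operationally: a replicate series (both sequences, equal
participants per sequence, `obs_per_phase` observed days per phase) is
analyzed by GLS with fixed participant intercepts, a shared treatment
effect and the known AR1 working correlation (residual scale estimated,
two-sided t test); power is the rejection fraction. The analytic companion
is the normal approximation `Phi(|delta|/SE - z_{1-alpha/2}) + Phi(-|delta|/SE
- z_{1-alpha/2})` with SE from the exact GLS variance of the treatment
contrast; simulation and closed form must agree within Monte-Carlo error,
which is the module's verifiable contract.

The AR1 correlation at the design stage acts on the *observation order* by
default — successive documented responses are correlated rho, the
convention of standard AR1 regression software applied to response
sequences. Under this convention the reference design (6 participants per
sequence, 4 observed PROs per weekly phase, residual SD 2.41, rho 0.8,
standardized effect 0.3, alpha 0.05) has analytic power 0.8035; under
calendar-day-gap correlation (`correlation_basis="calendar"`) the same
design has power ≈0.36. Both are offered because the two conventions answer
different questions about when information accrues between sparse
observations. `residual_sd` is the marginal SD of the error process (the
scale the standardized effect refers to), not the innovation SD.
Recruitment inflation divides by (1 - dropout) and rounds half to nearest
(24 analyzable at 30% dropout → 34 recruited).

## Adherence and linkage

A documented day is adherent when the exercise was performed in phase A or
not performed in phase B; fractions are reported per (arm × phase type)
cell and overall, computed from raw flags only. Longitudinal linkage uses a
self-generated identification code built from six prompts (first two
letters of mother's name and birthplace, sex symbol, older-sibling digit
capped at 9, last digits of parental house number and postal code) after
uppercasing and diacritic folding — 8 symbols by default; a 7-symbol
variant drops the sex symbol since the prompt list and the stated code
length disagree by one. Matching is two-stage: exact first, then optimal
string alignment distance ≤ 1 (substitutions, indels, adjacent
transpositions; Hamming available); a follow-up equidistant from several
baselines is flagged ambiguous and never auto-matched, because such matches
require confirmation against demographics the code deliberately omits.

## Questionnaire scoring

Each instrument is a data-only `ScaleDefinition`; scoring reverse-codes,
checks the instrument's missing-item rule (WPCS/CBI: at least 50% of items
answered; ERI: at most 1 missing overall; over-commitment: at most 2;
PSS/SWLS: at most 1), imputes missing items with the row-wise mean of the
answered reverse-coded items (imputation on the reverse-coded scale is a
package decision), and applies the transform (sum, mean, or 0–100
rescaling). The effort-reward imbalance ratio imputes within the effort and
reward blocks separately and corrects for unequal block sizes:
`sum(E) / (sum(R) * n_E/n_R)`. The SUS uses the classical odd/even scoring
to 0–100 and accepts no missing items. Shipped item counts and reversals
follow the standard German short forms of the cited instruments and are
assumptions correctable in config, not code.

## Problem sizes used by the shipped checks

The acceptance-style checks run reduced but honest problem sizes chosen as
the package's own verification budget: the power simulation uses 2,000
replicates (binomial MC SE ≈ 0.9 percentage points at power 0.8); the
likelihood property check uses 1,000 random instances of up to 12
observations; credible-interval coverage uses 200 replicate 28-day trials
at a reduced MCMC size (2 chains × 1,000 burn-in / 2,000 kept), which is
ample for a 4-parameter conjugate-dominated sampler; the population
recovery uses 40 participants at 2 × 500/1,500. Full-protocol MCMC sizes
remain the library defaults.

## Known limitations

- Gaussian likelihood on a bounded discrete response; no ordinal model.
- No covariate adjustment (e.g., weekday) in the fitted models; the
  generator's weekend effect therefore acts as structured residual noise.
- MCAR missingness only; informative dropout is out of scope.
- The population fit assumes a shared (rho, sigma) across participants.
- Griddy Gibbs discretizes rho to the grid resolution (~0.005 by default).
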