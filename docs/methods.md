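# Methods

## The censoring model

A ceiling (floor) effect is modelled as clipping: the observed score is
the latent true score unless the true score is at or beyond the scale
bound, in which case the bound itself is recorded.  An observation exactly
at a bound is therefore always treated as censored — the bound is a proxy,
not a measurement.  When ingesting user CSVs, equality to a bound (within
1e−12 absolute) marks a cell censored; values strictly outside the bounds
are rejected as a threshold misspecification rather than silently clipped.
All variables are assumed complete (no missing-data handling), and true
scores are assumed normal; both assumptions are inherited by every model
below.

## Paired t-test under censoring

True scores (y₁\*, y₂\*) are bivariate normal with free means (μ₁, μ₂) and
covariance [[v₁, c], [c, v₂]].  This is the moment-level form of a
single-common-factor model (two loadings, equal unique variances); the two
parameterisations imply the same censored-data likelihood, and the
(λ₁, λ₂, σₑ²) solution is recovered after fitting by solving
(v₁−s)(v₂−s) = c² for the smaller root s — a representation that avoids
the loadings' sign indeterminacy during optimisation.  The likelihood per
subject is:

- both scores interior — bivariate normal density;
- one censored — interior density × conditional (on the interior score)
  normal tail probability;
- both censored — the bivariate rectangle probability of the censored
  quadrant.

Rectangle probabilities use a closed-form bivariate-normal CDF built on
Owen's T function: deterministic, smooth in the parameters (which
quasi-Newton optimisation needs) and accurate to ~4e−14.

**ML estimation.**  BFGS on an unconstrained transform (means raw, log
variances, Fisher-z correlation), started at the observed-score moments.
Standard errors come from the inverse observed information (numerical
Hessian) mapped to the natural scale by the delta method.  Nonconvergence
is reported, never silently retried; an exit flagged "precision loss" with
a gradient already at the finite-difference noise floor (norm below
1e−4·(1+|loglik|)) and a positive-definite Hessian counts as converged,
because the nominal 1e−8 gradient tolerance is unattainable with numerical
gradients.

**Inference.**  t divides μ̂₂−μ̂₁ by its observed-information standard
error (default), against t(N−1); a standard-normal reference is available
(the convention of common SEM software output).  The algebraically neater
model-implied denominator √((v̂₁+v̂₂−2ĉ)/N) is kept as an option
(`se="model"`): the two coincide exactly without censoring, but under
censoring the clipped observations carry less information than the
implied difference-score variance suggests, so the model denominator
understates uncertainty and undercovers.  Cohen's d is the model-implied
standardised difference (μ̂₂−μ̂₁)/√(v̂₁+v̂₂−2ĉ) — identical to the
variance-based definition μ_D/√(σ_D²+2σₑ²) used on the Bayesian side,
since v₁+v₂−2c = σ_D²+2σₑ².

## Bayesian estimation (paired)

The latent-variable form y₁\* = η₁+ε₁, y₂\* = η₁+η₂+ε₂ with
η₁ ~ N(μ₁, σ₁²), η₂ ~ N(μ_D, σ_D²) and common error variance σₑ² implies
the same censored bivariate normal with v₁ = σ₁²+σₑ², v₂ = σ₁²+σ_D²+σₑ²,
c = σ₁².  Priors: N(0, 10⁶) on μ₁ and μ_D; Gamma(0.001, 0.001) on the
three precisions (equivalently inverse-gamma on the variances — the usual
BUGS/JAGS idiom; `PriorSpec` exposes the shape/rate for other choices).

The sampler is a **collapsed Gibbs scheme**: because the subject latents
enter the likelihood only through the implied covariance, they are
integrated out analytically.  Each sweep (i) augments each censored score
with a truncated-normal draw from its bivariate conditional given the
subject's other score, (ii) updates (μ₁, μ_D) from their joint conjugate
normal given the completed data, and (iii) slice-samples each variance
component (log scale, stepping-out and shrinkage) from its marginal
conditional, which depends on the completed data only through three sums
of squares.  The collapsed sampler targets exactly the posterior of the
latent formulation but removes the latent/variance coupling that gives
the naive sweep an integrated autocorrelation time of hundreds of
iterations; collapsed, it drops by an order of magnitude, so short chains
give trustworthy PSRF diagnostics.  The collapsed and naive sweeps target
the identical posterior; the test suite checks the posterior against the
ML estimates in the uncensored limit and on large censored samples.

Truncated-normal draws use inverse-CDF sampling, switching to an
exponential rejection sampler (Robert 1995) beyond 5 standardised units
where the CDF difference underflows.  Chains: the first starts at
moment-based estimates, later chains at overdispersed values (moments ± 2
rough standard errors, variances scaled correspondingly) — dispersed
starts are required for an honest Gelman–Rubin PSRF.  Convergence is
declared when every parameter's PSRF (classic pooled-variance form on
post-burn-in draws) is below 1.1.  Summaries are posterior means with 95%
equal-tailed percentile intervals (linear interpolation between order
statistics); Cohen's d is the per-draw transform μ_D/√(σ_D²+2σₑ²).

Default run length is desk-scale (2 chains, 1,000 burn-in, 4,000 kept);
a reference long-run configuration is 2 × 30,000 / 60,000.

## Moderated regression under censoring

Model: y\* = β₀+β₁x\*+β₂z\*+β₃x\*z\*+e, e ~ N(0, σₑ²), (x\*, z\*)
bivariate normal with free means, variances and covariance.  The free
exogenous covariance matters: with correlated predictors, forcing
independence biases the interaction under censoring.  With censoring only
in y the exogenous part factors out and the fit reduces to the classical
Tobit regression likelihood (density for interior y, tail probability at
a bound) — this closed-form path is selected automatically.

With censored x\* and/or z\*, each censored dimension is integrated out of
the joint likelihood over its censored region.  The five computational
branches — all interior; y only; one exogenous; one exogenous plus y;
both exogenous (tensor product) — cover all 27 floor/interior/ceiling
patterns.  Integrals are Gauss–Legendre (default 40 nodes per dimension)
on the censored interval truncated at 8.5 conditional SDs beyond the
bound or the conditional mean, where the integrand is ~1e−17 of its peak;
integrating in the original coordinate keeps the integrand analytic, so
doubling the node count changes the log-likelihood by less than 1e−9 on
typical data (a probability-transform rule was tried first and converged
only polynomially).  Optimisation, SEs and convergence assessment follow
the paired ML fit; starting values are OLS coefficients and observed
moments.  Wald tests use the standard-normal reference by default.
Simple slopes β₁+β₃z carry delta-method SEs from the coefficient
covariance block.

A documented option (`measurement_inflation`) adds a small constant to
the error variances, mimicking the single-indicator identification device
(loading 1, intercept 0, error variance .01) that general SEM software
needs to express this model; the default 0 is the exact formulation.

**Bayesian estimation.**  Gibbs sampling augments every censored y\*,
x\*, z\* cell.  Censored x\* combines its marginal normal prior with the
outcome term — linear in x\* with slope β₁+β₃z\* — into a conjugate
normal, truncated to the censored region (symmetrically for z\*); the
interaction column is rebuilt from the current x\*, z\* each sweep, so
censoring propagates into the product term.  β then gets a conjugate
multivariate-normal update, variances precision-gamma updates, exogenous
means normal updates.  By default x\* and z\* carry independent marginal
normals (their correlation is absorbed only through the regression term in
censored-cell conditionals); `bivariate_exo=True` models them jointly with
an inverse-Wishart(3, 0.001·I) prior on the covariance.  Exogenous means
take diffuse N(0, 10⁶) priors, matching the other location parameters.
Defaults are again desk-scale (2 × 1,000 / 5,000; reference configuration
2 × 30,000 / 100,000).

## Conventional comparators

The censoring-ignoring baselines: the classical paired t-test on observed
scores (sample moments with the n−1 divisor by default; a 1/N option
exists because the no-censoring Tobit ML t equals the conventional t
exactly under that convention) and OLS moderated regression via
statsmodels with classical SEs, t(n−4) inference and the interaction
column formed from observed scores.

## Synthetic data and the simulation engine

The generators reproduce two factorial study designs and serve as the test
fixture factory:

- **Paired**: y₁\* ~ N(0,1), y₂\* ~ N(μ₂, SDR²) with correlation ρ and
  μ₂ = d√(1+SDR²−2ρ·SDR).  The ceiling threshold is Φ⁻¹(1−CP) on the
  pre-test N(0,1) marginal and is applied to both occasions, so the
  post-test ceiling proportion varies with μ₂ and SDR by construction.
  Grid: d ∈ {0, .5}, SDR ∈ {1, 1.5}, ρ ∈ {0, .5}, CP ∈ {0,.1,.2,.3},
  N ∈ {50,100,200,500}.
- **Moderated regression**: (x\*, z\*) bivariate normal, unit marginals,
  correlation ρ; y\* = x\* + z\* + β₃x\*z\* + e, e ~ N(0,1) (β₀ = 0,
  β₁ = β₂ = 1, σₑ² = 1).  Scenario 1 censors x and y at the shared
  threshold Φ⁻¹(1−CP) from X's marginal; Scenario 2 censors z only.
  Grid: β₃ ∈ {0, .39} (f² ≈ 0 and .15), ρ ∈ {0, .3}, same CP and N.

These generators emulate the ceiling mechanism exactly but none of the
features of real scales — discreteness (sum scores are integers), skewed
or non-normal true scores, measurement error, or missing data.  Passing
Monte-Carlo tests therefore demonstrates correctness of the estimators
under the assumed normal-true-score model, not robustness beyond it.

The engine runs one method over one factorial cell: per replication it
draws data (one independent substream per replication spawned from the
master seed, kept below 2³¹), fits, and records the target estimate, 95%
interval, rejection at α = .05 (for Bayesian fits: the 95% percentile
interval excluding the null) and a convergence flag.  Metrics — empirical
bias, relative bias (non-null truths only), Type-I/power, coverage — are
computed over converged replications, with nonconvergence counted and
reported.  Verdict bands: |relative bias| ≤ 10%, Type-I in [2.5%, 7.5%],
coverage in [91%, 98%], convergence ≥ 90%.

### Problem sizes used in the test suite

Monte-Carlo checks run at 1000 replications for the conventional and
Tobit-ML paired cells, 500 for Tobit-ML moderated regression, and 200
(with the desk-scale 2 × 1,000/4,000 chains) for the Bayesian paired
cells; deterministic oracle checks (Gauss–Hermite, 10⁷-draw Monte-Carlo
integration, factor-solution reconstruction, limit identities) are exact
to the stated tolerances.  These counts make binomial error a few
percentage points, which the test bands accommodate.

## Known limitations

- Normal true scores only; heavy tails or floor-and-ceiling-skewed
  populations will bias all three estimators.
- The Bayesian paired model's posterior mean shows a small upward
  finite-sample bias in μ_D (a few percent relative at N = 100 with heavy
  post-test censoring) under the diffuse priors — a property of the
  posterior itself, visible in the Monte-Carlo bias checks, not of the
  sampler.
- The Bayesian moderated-regression default treats x\* and z\* as
  independent; with strongly correlated, heavily censored predictors the
  joint option is preferable.
- ML moderated regression with two censored exogenous variables uses a
  tensor-product rule whose cost grows quadratically in the node count.
- No missing data, no measurement-error models, no more than one
  moderator.
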