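# Methods

## Outcome models

Two foraging outcomes are modelled in parallel so that age and trait
effects are comparable across resources:

* **Shellfish.** Kilograms of unprocessed shellfish collected by one
  person on one trip, strictly positive by construction (participants
  always collect something, so only the positive part of a hurdle model
  is needed): `R ~ lognormal(mu, sigma)` with
  `mu = log(alpha * phi_i * psi_f)`, i.e. `alpha * phi * psi` is the
  median return.
* **Traps.** The number of prey captured by one snare over its
  deployment: `S ~ Poisson(lambda)`.  Only the count part is modelled;
  prey weight varies mainly with species and season, not with the
  installer's traits.

The default Poisson link is the product `lambda = alpha * phi * psi`,
the exact mirror of the lognormal median parameterisation.  An
alternative exponential link `lambda = exp(alpha * phi * psi)` is kept
behind `link_choice="printed_exp"` for comparison, but it constrains
`lambda >= 1` whenever `alpha, phi, psi >= 0`, which is incompatible
with snare data in which roughly 31 of 724 traps succeed
(`lambda ~ 0.04`); a property test documents this.  The product link is
therefore the default and the generator simulates from it.

## The production function

```
phi_i = exp(iota_i) * (1 - exp(-beta * a_i))**gamma * k_i**zeta * h_i**eta * g_i**theta
psi_f = d_f**xi * exp(t_f * tau)
```

* The age term rises from exactly 0 at age 0 toward 1, with `beta`
  (per year) setting the rate and `gamma` bending the approach into a
  sigmoid.  Cobb–Douglas exponents encode the biological assumption
  that production is impossible in the complete absence of a positively
  exponentiated trait.
* The individual random effect enters as `exp(iota_i)` with
  `iota_i ~ normal(0, 1)`.  A multiplicative effect with a normal prior
  directly on the factor would admit negative `phi` and an undefined
  log-median; the exponential form preserves the prior while keeping
  `phi > 0`.
* **Scaling conventions.**  Heights and grips are divided by the
  participant sample mean; durations/exposures are divided by their
  sample mean; tide heights are centred at their sample mean.  The
  average individual on an average trip therefore contributes
  `phi * psi = 1`, which makes `alpha` interpretable as the median
  outcome of a reference person-trip and fixes the scale that the
  likelihood alone cannot (multiplying `alpha` by `c` and dividing
  `psi` by `c` leaves every likelihood term unchanged — a property
  test asserts this coherence).  Knowledge enters as
  `k = exp(kappa)` mean-scaled, `kappa` being the latent ability on
  the standardised IRT scale.

Priors (as used throughout): `alpha ~ half-normal(0, 1)`;
`beta, gamma, sigma ~ exponential(1)`;
`iota, zeta, eta, theta, xi, tau ~ normal(0, 1)`.

## Knowledge measurement (2PL)

A single latent ability per individual is estimated from pooled binary
responses (50 knowledge questions, 27 picture identifications, plus
itemised freelist indicators when present) under the two-parameter
logistic model `P(correct) = logistic(a_j (kappa_i - b_j))` with priors
`a_j ~ lognormal(0, 0.5)` (sign-identified) and `b_j ~ normal(0, 1)`.

Fitting is marginal maximum a-posteriori EM (Bock–Aitkin quadrature
over the standard-normal ability prior), followed by a dense grid
posterior for each individual's ability given the fitted items — the
standard empirical-Bayes route for this model class.  A joint MCMC over
all ~250 item-and-ability parameters adds little for the downstream
use (a per-individual mean and sd) and mixes poorly with ensemble
samplers, so the empirical-Bayes EM route is the package default.  Abilities are
standardised across individuals within each posterior draw; this
identifies the latent scale.  Degenerate all-0/all-1 items are flagged
and retained (the priors keep their parameters finite).

Knowledge uncertainty propagates to the foraging model in two stages by
default: the per-individual ability mean and sd act as a
measurement-error likelihood `m_i ~ normal(kappa_i, s_i)` on the latent
`kappa_i` inside the foraging model, alongside its age-and-sex
imputation prior.

## Missing traits

Heights, grips and the knowledge latent are modelled as normal around
sex-specific linear functions of age on their mean-scaled scales
(intercept priors `normal(1, 0.5)` for somatic traits, `normal(0, 1)`
for knowledge; slope priors `normal(0, 0.1)` per year; residual sds
`exponential`).  Observed values contribute likelihood; missing values
are latent parameters, so `phi` always receives a value and every
observation row informs the remaining parameters.  The exact functional
form is a package choice — a linear-in-age regression per sex with a
shared residual sd per trait — selected for being the simplest model
the generator can mirror exactly, which keeps recovery experiments
well posed.  Latent scaled traits proposed at non-positive values get
zero posterior mass.

## Synthetic data

The generator draws from exactly the model above, so every downstream
stage is testable without any field data.  Defaults encode the study
conditions:

* design sizes 39 collectors x 35 trips / 156 person-trips and 24
  installers x 335 trips / 724 snares, plus a recovery preset of 30
  individuals x 500 person-trips;
* right-skewed ages (8–39, mean ~16 for collectors; 7–26, mean ~15 for
  installers) drawn from scaled Beta distributions;
* shellfish age curve calibrated so a 10-year-old sits at ~80% of the
  curve maximum (`beta = 0.161, gamma = 1`), the trap curve at ~29%
  (`beta = 0.07, gamma = 2`);
* `alpha_trap = 0.094`, giving an expected success fraction of
  ~31/724 at the default exposure distribution;
* `alpha_shellfish = 2.0 kg`, `tau = -0.6`, `sigma = 0.7`, which give a
  mean of ~2.6 kg per person-trip and an expected catch above 3 kg for
  a three-hour trip at the lowest observed tide;
* trip durations lognormal around 180 min (sd 0.3 on the log scale),
  tides normal (sd 0.4 m) and centred downstream, snare exposures
  lognormal around 7 days; none of these distributions is asserted by
  the source data — they are explicit package choices;
* trait growth linear in age per sex with Gaussian noise (truncated
  positive), missingness fractions 10% (height), 20% (grip), 40%
  (knowledge survey).

What the generator does **not** emulate: group-level correlation in
returns (foragers share patches and information), seasonality of prey,
age-dependent trip self-selection, and measurement error in heights and
grips.  Passing recovery tests therefore show the estimator is correct
for its own data-generating process, not that these field complications
are harmless.

## Inference

Sampling uses an affine-invariant ensemble (emcee) with
differential-evolution moves (80% `DEMove`, 20% `DESnookerMove`),
which mix far better than stretch moves in this ~40-dimensional
correlated posterior.  The model log-density is evaluated in batch over
all walkers (pure numpy), so a full shellfish fit takes seconds.
`chains` independent seeded ensembles (default 4; 2 in the heavier
validation loops) play the role of chains for split-R-hat and bulk-ESS
diagnostics (arviz); walkers within an ensemble are flattened into its
draw axis.  Defaults: 1000–3000 adaptation steps discarded, thinned
retention of 400–500 draws per chain.  R-hat above 1.01 warns, above
1.05 attaches an explicit convergence warning to the result.  All
randomness derives from integer seeds; identical (seed, config, data)
reproduce draws bit-for-bit.

Positive parameters (`alpha, beta, gamma, sigma`, imputation sds) are
sampled on the log scale with the corresponding Jacobian; the age term
is computed through `expm1` with clipping at 1e-300 to guard underflow
at extreme adaptation-phase values.

## Validation harness

`recover()` draws true core parameters from the model's own priors
(including `iota ~ normal(0, 1)`), simulates the 30 x 500 design,
refits, and scores 89% central-interval coverage plus the normalised
rank of the truth in the posterior.  Over 20 replicates the core
shellfish parameters (`beta, gamma, xi, tau, sigma`) cover at the
nominal rate within binomial error and the rank distribution is
uniform (chi-square).  Fixed-effects least squares on log-returns
serves as an independent oracle for `xi` and `tau` in tests.

## Information content of rare-success trap data

Two findings from the validation experiments are worth stating
explicitly because they bound what trap-style data can teach:

* Even with only ~31 successes, the 724 zero counts pin each
  installer's total log-effect to sd ~1.3, and regressing ~24 such
  installer-level values on a trait with large relative spread
  (knowledge on the exp-ability scale, grip across ages 7–26) halves
  the prior sd of its exponent.  Only small-spread traits (height,
  ~10% relative spread) remain fully prior-dominated.  Trait-exponent
  "learning" from such data is thus a between-individual regression
  with n = number of installers, not n = number of traps.
* Because each individual has one age, the age curve is identified only
  through the same ~24–30 installer-level points against the
  `normal(0, 1)` random-effect prior, and the `beta`–`gamma` marginals
  are dominated by a curve-shape ridge (many pairs produce
  near-identical curves over the observed 7–26 age span).  Raising the
  per-trap success rate sharpens per-installer estimates but not this
  ridge, so the marginal posteriors of `beta` and `gamma` stay wide at
  any realistic rate for this design.

## Counterfactual reporting

* **Age curves** evaluate `phi` on an age grid with traits at unit
  (average) values and zero random effect, normalised by the grid
  maximum (`alpha` cancels); summarised by the median and 30/60/89
  percentile bands.  Normalising by the asymptote instead of the grid
  maximum differs negligibly for saturating curves; the grid maximum is
  the documented default.
* **Trait contrasts** on the `phi` scale compare hypothetical
  individuals average in all traits but one; with the Cobb–Douglas form
  this is `high**e - low**e`, so the contrast sign equals the exponent
  sign draw by draw.
* **Outcome contrasts** move one predictor from its observed minimum to
  maximum with everything else at means (the individual factor is the
  dataset-average `phi`); shellfish expectations include the lognormal
  mean correction `exp(sigma**2 / 2)`.  Observed min/max is the default
  range; percentile ranges are available via the `low`/`high`
  arguments.
* **Posterior prediction** simulates outcomes for every observed
  covariate row per draw, with imputed latents taken from their own
  posterior draws.

## Problem sizes and runtimes

The test suite and the acceptance script run study-sized fits (156 and
724 observations), a 20-replicate recovery loop at 30 x 500, and a
93 x 77 knowledge-model fit; together these take a few minutes on one
CPU.  These sizes are the package's chosen validation scales: large
enough to exercise every code path at the study's own designs, small
enough to iterate on.

## Known limitations

* The trap model's trait exponents and age curve are weakly identified
  at the study design (see the information-content notes above);
  reported trap counterfactuals are correspondingly prior-sensitive.
* The two-stage knowledge flow ignores correlation between item
  parameters and foraging parameters; the joint single-model fit
  is structurally supported (the measurement term is one likelihood
  component) but not the default.
* Ensemble MCMC struggles in the extreme prior tails (e.g. true
  `sigma < 0.02`), which shows up as occasional near-miss coverage in
  recovery replicates.
* The imputation regressions are linear in age; real growth curves
  saturate, so extrapolation beyond the observed age span is not
  meaningful.
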