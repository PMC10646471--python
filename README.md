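# forager

Bayesian analysis of age-specific foraging returns for a population of
part-time child and teenage foragers: shellfish collection along a
mangrove coast and snare-trap hunting in forest and farmland.  The
package is aimed at human behavioural ecologists who want to separate
the contribution of cognitive embodied capital (ecological knowledge)
from somatic traits (height, grip strength) in observational foraging
data, with principled treatment of missing measurements.

## The model

Person-trip shellfish returns and per-snare capture counts are modelled
in parallel:

```
R ~ lognormal(mu, sigma),        mu     = log(alpha * phi_i * psi_f)
S ~ Poisson(lambda),             lambda = alpha * phi_i * psi_f
```

`phi_i` is an individual production factor built as a Cobb–Douglas
composite of a saturating age term and mean-scaled traits,

```
phi_i = exp(iota_i) * (1 - exp(-beta * a_i))^gamma * k_i^zeta * h_i^eta * g_i^theta
```

so production is impossible at age zero or in the complete absence of
knowledge `k`, height `h` or grip strength `g` (for positive
exponents).  The trip factor is `psi_f = d_f^xi * exp(t_f * tau)` with
mean-scaled trip duration (or snare exposure days) `d` and mean-centred
tide height `t`.  Priors: `alpha ~ half-normal(0,1)`;
`beta, gamma, sigma ~ exponential(1)`;
`iota, zeta, eta, theta, xi, tau ~ normal(0,1)`.

Ecological knowledge is a latent ability estimated from a 77-item
survey (knowledge questions plus picture identifications) with a
two-parameter logistic IRT model; missing heights, grips and knowledge
scores are imputed inside the foraging model through sex-specific
linear-in-age regressions, so every individual contributes to the fit.

Results are reported as counterfactuals: normalised age curves of
`phi`, trait contrasts on the `phi` scale, and outcome-scale max–min
contrasts for each predictor.

## Worked example

```python
import numpy as np
import forager

# study-sized synthetic dataset: 39 collectors x 35 trips / 156
# person-trips, 24 trappers x 335 trips / 724 snares
ds, truth = forager.simulate_dataset("table1", seed=1)
print(forager.summarize_dataset(ds)["shellfish"])
# {'n_participants': 39, 'n_trips': 35, 'n_outcomes': 156,
#  'mean_age': 16.2, 'min_age': 8.1, 'max_age': 28.0}

model = forager.ShellfishReturnsModel(chains=2, warmup=2000,
                                      samples=400, thin=5, seed=5)
model.fit(ds)
print(model.draws_.summary(["alpha", "xi", "tau", "sigma"]).round(3))
#   parameter   mean  median     sd     q5    q95
#   alpha      2.032   2.023  0.243  1.649  2.428
#   xi         0.863   0.886  0.197  0.524  1.151
#   tau       -0.417  -0.420  0.138 -0.635 -0.194
#   sigma      0.754   0.754  0.032  0.702  0.811
```

The fitted `tau < 0` says lower tides mean higher returns; `xi ~ 0.8`
says returns scale a little less than linearly with trip duration.
Counterfactual post-processing turns the draws into reported
quantities:

```python
from forager.counterfactuals import age_curve, outcome_contrast

curve = age_curve(model.draws_, np.linspace(0.01, 40, 200))
contrast = outcome_contrast(model.draws_, "tide")
print(contrast.summary())
# {'name': 'tide', 'median': -1.99, 'lo': -3.12, 'hi': -1.00,
#  'p_negative': 1.0}  -> kg lost moving from the lowest to highest tide
```

A thin CLI wraps the same functions: `forager simulate`,
`forager fit-irt`, `forager fit`, `forager recover`,
`forager counterfactual`.

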