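"""Counterfactual post-processing of posterior draws.

Turns posterior samples into the analysis's reported quantities:

* normalised age curves of the production factor phi (the age component
  of foraging variation, stripped of other predictors, scaled by its
  maximum over the age grid so curves are comparable across resources);
* trait contrasts on the phi scale for hypothetical individuals that
  are average in every trait but one;
* outcome-scale max-min contrasts for each predictor (kg of shellfish,
  including the lognormal mean correction exp(sigma^2/2), or expected
  trap captures);
* posterior-predictive outcome tables for every observed covariate row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from forager.model import age_component
from forager.inference import PosteriorDraws

TRAIT_EXPONENT = {"knowledge": "zeta", "height": "eta", "grip": "theta"}
PERCENTILE_BANDS = (0.30, 0.60, 0.89)


@dataclass
class AgeCurve:
    """Normalised age curves of phi with percentile band summaries."""

    ages: np.ndarray
    normalized: np.ndarray  # (n_draws, n_ages), each row max-normalised
    summary: pd.DataFrame

    def at_age(self, age: float) -> np.ndarray:
        """Per-draw normalised curve value at one age (grid interpolation)."""
        return np.array(
            [np.interp(age, self.ages, row) for row in self.normalized]
        )


@dataclass
class ContrastResult:
    """Per-draw counterfactual contrast for one trait or trip covariate."""

    name: str
    values: np.ndarray
    scale: str  # "phi" or "outcome"
    units: str = "dimensionless"

    def summary(self, prob: float = 0.89) -> dict:
        lo, hi = np.quantile(self.values, [(1 - prob) / 2, 1 - (1 - prob) / 2])
        return {
            "name": self.name,
            "median": float(np.median(self.values)),
            "lo": float(lo),
            "hi": float(hi),
            "p_negative": float(np.mean(self.values < 0)),
        }


def age_curve(
    draws: PosteriorDraws, age_grid: np.ndarray | None = None, resource: str | None = None
) -> AgeCurve:
    """Average phi by age with traits at reference (unit) values.

    Per draw the curve is (1 - exp(-beta a))**gamma on the grid,
    normalised by its grid maximum so it lies in [0, 1] and attains 1
    at the maximising age; alpha and the random effects cancel in the
    ratio.  Summarised by the median and 30/60/89 percentile bands.
    """
    if age_grid is None:
        age_grid = np.linspace(0.0, 60.0, 121)
    age_grid = np.asarray(age_grid, dtype=float)
    if age_grid.size == 0:
        raise ValueError("age grid must be non-empty")
    beta = draws.flat("beta")
    gamma = draws.flat("gamma")
    curves = (1.0 - np.exp(-beta[:, None] * age_grid[None, :])) ** gamma[:, None]
    peak = curves.max(axis=1, keepdims=True)
    normalized = np.where(peak > 0, curves / np.where(peak > 0, peak, 1.0), 0.0)

    rows = {"age": age_grid, "median": np.median(normalized, axis=0)}
    for band in PERCENTILE_BANDS:
        lo, hi = (1 - band) / 2, 1 - (1 - band) / 2
        rows[f"lo{int(band * 100)}"] = np.quantile(normalized, lo, axis=0)
        rows[f"hi{int(band * 100)}"] = np.quantile(normalized, hi, axis=0)
    return AgeCurve(ages=age_grid, normalized=normalized, summary=pd.DataFrame(rows))


def trait_contrast(
    draws: PosteriorDraws, trait: str, low: float, high: float
) -> ContrastResult:
    """phi(high) - phi(low) per draw, all other traits at unit values.

    With the Cobb-Douglas form and the reference individual (unit age
    factor, unit other traits, zero random effect) this is
    high**e - low**e for the trait's exponent e, so the contrast's sign
    equals the exponent's sign draw by draw.
    """
    if trait not in TRAIT_EXPONENT:
        raise ValueError(f"unknown trait {trait!r}")
    exponent = TRAIT_EXPONENT[trait]
    if exponent not in draws.draws:
        raise ValueError(
            f"trait {trait!r} is not in the fitted model (exponent {exponent!r} absent)"
        )
    if low <= 0 or high <= 0:
        raise ValueError("trait values must be positive on the mean-scaled scale")
    e = draws.flat(exponent)
    return ContrastResult(name=trait, values=high**e - low**e, scale="phi")


def phi_draws(draws: PosteriorDraws) -> np.ndarray:
    """(n_total_draws, n_individuals) production factors of the fitted
    individuals, using each draw's random effects and latent traits."""
    model = draws.model
    if model is None:
        raise ValueError("draws carry no model metadata")
    n = model.n_individuals
    beta = draws.flat("beta")
    gamma = draws.flat("gamma")
    iota = np.column_stack([draws.flat(f"iota[{i}]") for i in range(n)])
    age_term = (1.0 - np.exp(-beta[:, None] * model.age[None, :])) ** gamma[:, None]
    out = np.exp(iota) * age_term
    if model.include_traits:
        zeta = draws.flat("zeta")[:, None]
        eta = draws.flat("eta")[:, None]
        theta = draws.flat("theta")[:, None]
        S = beta.size
        h = np.broadcast_to(model.h_scaled, (S, n)).copy()
        for j, i in enumerate(model.h_missing):
            h[:, i] = draws.flat(f"height_latent[{i}]")
        g = np.broadcast_to(model.g_scaled, (S, n)).copy()
        for j, i in enumerate(model.g_missing):
            g[:, i] = draws.flat(f"grip_latent[{i}]")
        kappa = np.column_stack([draws.flat(f"kappa[{i}]") for i in range(n)])
        k = np.exp(kappa) / model.knowledge_scale
        out = out * k**zeta * h**eta * g**theta
    return out


def _phi_bar(draws: PosteriorDraws, strip_trait: str | None = None) -> np.ndarray:
    """Per-draw dataset-average phi; optionally with one trait's factor
    removed (set to its unit reference) for trait contrasts."""
    model = draws.model
    phis = phi_draws(draws)
    if strip_trait is not None and model.include_traits:
        e = draws.flat(TRAIT_EXPONENT[strip_trait])[:, None]
        n = model.n_individuals
        S = e.shape[0]
        if strip_trait == "height":
            v = np.broadcast_to(model.h_scaled, (S, n)).copy()
            for i in model.h_missing:
                v[:, i] = draws.flat(f"height_latent[{i}]")
        elif strip_trait == "grip":
            v = np.broadcast_to(model.g_scaled, (S, n)).copy()
            for i in model.g_missing:
                v[:, i] = draws.flat(f"grip_latent[{i}]")
        else:
            kappa = np.column_stack(
                [draws.flat(f"kappa[{i}]") for i in range(n)]
            )
            v = np.exp(kappa) / model.knowledge_scale
        phis = phis / v**e
    return phis.mean(axis=1)


def _mean_correction(draws: PosteriorDraws) -> np.ndarray:
    """exp(sigma^2 / 2) for shellfish (lognormal mean), 1 for traps."""
    if draws.model.resource == "shellfish":
        return np.exp(draws.flat("sigma") ** 2 / 2.0)
    return np.ones(draws.n_draws)


def _trait_observed_range(draws: PosteriorDraws, trait: str) -> tuple[float, float]:
    model = draws.model
    if trait == "height":
        v = model.h_scaled[np.isfinite(model.h_scaled)]
    elif trait == "grip":
        v = model.g_scaled[np.isfinite(model.g_scaled)]
    else:
        m = model.k_meas_mean[np.isfinite(model.k_meas_mean)]
        v = np.exp(m) / model.knowledge_scale
    if not len(v):
        raise ValueError(f"no observed values for trait {trait!r}")
    return float(v.min()), float(v.max())


def outcome_contrast(
    draws: PosteriorDraws,
    predictor: str,
    low: float | None = None,
    high: float | None = None,
) -> ContrastResult:
    """Expected-outcome difference between predictor at max vs min.

    All other variables are held at their means: mean-scaled traits and
    durations are 1 and the centred tide is 0, the individual factor is
    the dataset-average phi.  Shellfish expectations include the
    lognormal mean correction exp(sigma^2/2); trap expectations are the
    Poisson rate.  Default ranges are the observed min/max of the
    predictor in the fitted data.
    """
    model = draws.model
    if model is None:
        raise ValueError("draws carry no model metadata")
    resource = model.resource
    trip_predictors = (
        ("duration", "tide") if resource == "shellfish" else ("exposure",)
    )
    alpha = draws.flat("alpha")
    corr = _mean_correction(draws)
    units = "kg" if resource == "shellfish" else "expected captures"

    if predictor in trip_predictors:
        phi_bar = _phi_bar(draws)
        xi = draws.flat("xi")
        if predictor in ("duration", "exposure"):
            if low is None or high is None:
                low = float(model.d_scaled.min())
                high = float(model.d_scaled.max())
            values = alpha * phi_bar * corr * (high**xi - low**xi)
        else:  # tide
            tau = draws.flat("tau")
            if low is None or high is None:
                low = float(model.t_centred.min())
                high = float(model.t_centred.max())
            values = alpha * phi_bar * corr * (np.exp(high * tau) - np.exp(low * tau))
        return ContrastResult(predictor, values, scale="outcome", units=units)

    if predictor in TRAIT_EXPONENT:
        if not model.include_traits:
            raise ValueError(f"predictor {predictor!r} absent from the age-only model")
        e = draws.flat(TRAIT_EXPONENT[predictor])
        base = _phi_bar(draws, strip_trait=predictor)
        if low is None or high is None:
            low, high = _trait_observed_range(draws, predictor)
        values = alpha * base * corr * (high**e - low**e)
        return ContrastResult(predictor, values, scale="outcome", units=units)

    raise ValueError(
        f"predictor {predictor!r} not available for resource {resource!r}"
    )


def expected_outcome_rows(draws: PosteriorDraws) -> np.ndarray:
    """(n_draws, n_obs) expected outcome for every observed covariate row."""
    model = draws.model
    phis = phi_draws(draws)[:, model.obs_idx]
    alpha = draws.flat("alpha")[:, None]
    xi = draws.flat("xi")[:, None]
    psi = model.d_scaled[None, :] ** xi
    if model.resource == "shellfish":
        tau = draws.flat("tau")[:, None]
        sigma = draws.flat("sigma")[:, None]
        psi = psi * np.exp(model.t_centred[None, :] * tau)
        return alpha * phis * psi * np.exp(sigma**2 / 2.0)
    core = alpha * phis * psi
    if model.config.link_choice == "printed_exp":
        return np.exp(core)
    return core


@dataclass
class PosteriorPredictive:
    """Simulated outcomes per (retained draw, observation row)."""

    values: np.ndarray  # (n_draws_used, n_obs)
    resource: str

    def interval_coverage(self, observed: np.ndarray, prob: float = 0.89) -> float:
        lo, hi = np.quantile(
            self.values, [(1 - prob) / 2, 1 - (1 - prob) / 2], axis=0
        )
        observed = np.asarray(observed, dtype=float)
        return float(np.mean((observed >= lo) & (observed <= hi)))

    def summary_by_age(self, ages: np.ndarray, bins: int = 8) -> pd.DataFrame:
        edges = np.quantile(ages, np.linspace(0, 1, bins + 1))
        idx = np.clip(np.searchsorted(edges, ages, side="right") - 1, 0, bins - 1)
        rows = []
        for b in range(bins):
            sel = idx == b
            if not sel.any():
                continue
            v = self.values[:, sel]
            rows.append(
                {
                    "age_lo": edges[b],
                    "age_hi": edges[b + 1],
                    "mean": float(v.mean()),
                    "q5": float(np.quantile(v, 0.055)),
                    "q94": float(np.quantile(v, 0.945)),
                }
            )
        return pd.DataFrame(rows)


def posterior_predict(
    draws: PosteriorDraws,
    seed: int = 0,
    n_draws: int | None = None,
) -> PosteriorPredictive:
    """Simulate outcomes for every observed covariate row, draw by draw.

    Imputed latent traits are taken from their own posterior draws, so
    prediction uncertainty includes the missing-data uncertainty.
    """
    model = draws.model
    rng = np.random.default_rng(seed)
    mu_like = expected_outcome_rows(draws)
    total = mu_like.shape[0]
    use = np.arange(total) if n_draws is None or n_draws >= total else rng.choice(
        total, n_draws, replace=False
    )
    if model.resource == "shellfish":
        sigma = draws.flat("sigma")[use, None]
        # expected_outcome_rows includes exp(sigma^2/2); invert to the median
        med = mu_like[use] / np.exp(sigma**2 / 2.0)
        values = np.exp(rng.normal(np.log(med), sigma))
    else:
        values = rng.poisson(mu_like[use]).astype(float)
    return PosteriorPredictive(values=values, resource=model.resource)
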