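"""The foraging-returns probability model as an evaluable log-density.

Outcome models, fitted separately per resource:

* shellfish person-trip returns  R ~ lognormal(mu, sigma) with
  mu = log(alpha * phi_i * psi_f);
* snare captures  S ~ Poisson(lambda) with, by default,
  lambda = alpha * phi_i * psi_f (an optional exponential link
  lambda = exp(alpha * phi_i * psi_f) is kept behind
  ``link_choice="printed_exp"``; it forces lambda >= 1 for non-negative
  inputs and cannot reproduce rare-success trap data — see docs).

The individual production factor is a Cobb-Douglas composite

    phi_i = exp(iota_i) * (1 - exp(-beta * a_i))**gamma
            * k_i**zeta * h_i**eta * g_i**theta

so that production is zero at age zero or when a positively
exponentiated trait is absent, and the trip factor is

    psi_f = d_f**xi * exp(t_f * tau)        (tide term shellfish only).

Traits enter mean-scaled (the average individual contributes factor
one); durations/exposures are mean-scaled and tides mean-centred, which
fixes the scale of alpha.  Missing heights/grips and the latent
knowledge score are parameters with a sex-specific linear-in-age normal
imputation submodel.  Priors follow the study defaults: alpha ~
half-normal(0,1); beta, gamma, sigma ~ exponential(1); iota, zeta, eta,
theta, xi, tau ~ normal(0,1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from forager.config import RunConfig
from forager.data import ForagingDataset

_LOG_2PI = math.log(2.0 * math.pi)


# -- deterministic building blocks -----------------------------------------


def age_component(a, beta, gamma):
    """Saturating age factor (1 - exp(-beta*a))**gamma in [0, 1).

    Zero at age zero ("foraging cannot happen"), strictly increasing,
    approaching one as age grows; gamma bends the approach into a
    sigmoid.  ``beta`` and ``gamma`` must be strictly positive.
    """
    a = np.asarray(a, dtype=float)
    if np.any(np.asarray(beta) <= 0) or np.any(np.asarray(gamma) <= 0):
        raise ValueError("age_component requires beta > 0 and gamma > 0")
    if np.any(a < 0):
        raise ValueError("age must be non-negative")
    return (1.0 - np.exp(-np.asarray(beta) * a)) ** np.asarray(gamma)


def _trait_power(x, exponent, name):
    x = np.asarray(x, dtype=float)
    e = np.asarray(exponent, dtype=float)
    if np.any(x < 0):
        raise ValueError(f"trait {name!r} must be non-negative")
    if np.any((x == 0) & (e < 0)):
        raise ValueError(f"trait {name!r} is zero with a negative exponent")
    return np.where((x == 0) & (e == 0), 1.0, x**e)


def phi(age, knowledge, height, grip, iota, beta, gamma, zeta, eta, theta):
    """Individual production factor exp(iota) * age term * k^zeta * h^eta * g^theta."""
    return (
        np.exp(np.asarray(iota, dtype=float))
        * age_component(age, beta, gamma)
        * _trait_power(knowledge, zeta, "knowledge")
        * _trait_power(height, eta, "height")
        * _trait_power(grip, theta, "grip")
    )


def psi_shellfish(duration, tide, xi, tau):
    """Trip factor d**xi * exp(t * tau); duration pre-scaled, tide pre-centred."""
    d = np.asarray(duration, dtype=float)
    if np.any(d <= 0):
        raise ValueError("duration must be strictly positive")
    return d ** np.asarray(xi) * np.exp(np.asarray(tide, dtype=float) * np.asarray(tau))


def psi_trap(exposure, xi):
    """Trap factor d**xi for mean-scaled exposure days."""
    d = np.asarray(exposure, dtype=float)
    if np.any(d <= 0):
        raise ValueError("exposure must be strictly positive")
    return d ** np.asarray(xi)


# -- elementary log-densities ------------------------------------------------


def _normal_logpdf(x, loc, scale):
    z = (np.asarray(x, dtype=float) - loc) / scale
    return -0.5 * z**2 - np.log(scale) - 0.5 * _LOG_2PI


def shellfish_logdensity(returns_kg, alpha, phi_i, psi_f, sigma):
    """Lognormal log-pdf of positive returns with location log(alpha*phi*psi)."""
    r = np.asarray(returns_kg, dtype=float)
    if np.any(r <= 0):
        raise ValueError("returns_kg must be strictly positive")
    med = np.asarray(alpha) * np.asarray(phi_i) * np.asarray(psi_f)
    if np.any(med <= 0) or np.any(np.asarray(sigma) <= 0):
        raise ValueError("alpha*phi*psi and sigma must be strictly positive")
    return _normal_logpdf(np.log(r), np.log(med), sigma) - np.log(r)


def trap_logdensity(captures, alpha, phi_i, psi_f, link="product"):
    """Poisson log-pmf of capture counts under the configured rate link."""
    s = np.asarray(captures)
    if np.any(s < 0) or not np.issubdtype(np.asarray(s).dtype, np.integer):
        s = np.asarray(s, dtype=float)
        if np.any(s < 0) or np.any(s != np.floor(s)):
            raise ValueError("captures must be non-negative integers")
    s = np.asarray(s, dtype=float)
    core = np.asarray(alpha) * np.asarray(phi_i) * np.asarray(psi_f)
    if link == "product":
        lam = core
        if np.any(lam <= 0):
            raise ValueError("rate alpha*phi*psi must be strictly positive")
    elif link == "printed_exp":
        lam = np.exp(core)
    else:
        raise ValueError(f"unknown link {link!r}")
    from scipy.special import gammaln

    return s * np.log(lam) - lam - gammaln(s + 1.0)


def imputation_logdensity(value, age, sex, intercept_female, slope_female,
                          intercept_male, slope_male, sd):
    """Normal log-pdf of a trait value around its sex-specific age regression.

    Applies identically to observed values (a likelihood term) and to
    latent imputed values (their prior), so phi always receives a value.
    """
    male = np.asarray(sex) == "male"
    mean = np.where(male, intercept_male, intercept_female) + np.where(
        male, slope_male, slope_female
    ) * np.asarray(age, dtype=float)
    if np.any(np.asarray(sd) <= 0):
        raise ValueError("imputation sd must be strictly positive")
    return _normal_logpdf(value, mean, sd)


def _prior_logpdf(x, spec):
    x = np.asarray(x, dtype=float)
    dist = spec["dist"]
    scale = spec.get("scale", 1.0)
    if dist == "half_normal":
        if np.any(x < 0):
            return -np.inf * np.ones(np.shape(x)) if np.ndim(x) else -np.inf
        return (
            0.5 * math.log(2.0 / math.pi) - math.log(scale) - 0.5 * (x / scale) ** 2
        )
    if dist == "exponential":
        if np.any(x < 0):
            return -np.inf * np.ones(np.shape(x)) if np.ndim(x) else -np.inf
        return -math.log(scale) - x / scale
    if dist == "normal":
        return _normal_logpdf(x, spec.get("loc", 0.0), scale)
    raise ValueError(f"unknown prior family {dist!r}")


# -- assembled model ---------------------------------------------------------

TRAITS = ("knowledge", "height", "grip")
TRAIT_EXPONENTS = {"knowledge": "zeta", "height": "eta", "grip": "theta"}


@dataclass
class KnowledgeSummary:
    """Per-individual ability posterior summary passed from the IRT stage
    as a measurement-error model: measured mean ~ normal(kappa_i, sd)."""

    mean: dict[str, float]
    sd: dict[str, float]


class ForagingLogPosterior:
    """Joint log-posterior of one resource model over a dataset.

    Builds the design arrays (participants, outcomes, mean-scalings),
    owns the packed parameter layout used by the sampler, and evaluates
    the posterior for single parameter vectors, batches of vectors, or
    named-parameter dictionaries.

    Parameters
    ----------
    dataset : validated :class:`ForagingDataset`
    resource : ``"shellfish"`` or ``"trap"``
    config : :class:`RunConfig` (priors, link, trait inclusion)
    knowledge : optional :class:`KnowledgeSummary` from the IRT stage;
        only used when ``config.include_traits`` is set.
    """

    def __init__(
        self,
        dataset: ForagingDataset,
        resource: str,
        config: RunConfig | None = None,
        knowledge: KnowledgeSummary | None = None,
    ):
        if resource not in ("shellfish", "trap"):
            raise ValueError("resource must be 'shellfish' or 'trap'")
        self.resource = resource
        self.config = config or RunConfig()
        self.knowledge = knowledge

        ind = dataset.individuals
        if resource == "shellfish":
            obs = dataset.shellfish
            part_ids = pd.unique(obs["individual_id"])
            id_col = "individual_id"
        else:
            obs = dataset.traps
            part_ids = pd.unique(obs["installer_id"])
            id_col = "installer_id"
        if not len(obs):
            part_ids = np.asarray([], dtype=object)
        self.individual_ids = list(part_ids)
        self.n_individuals = len(self.individual_ids)
        sub = ind.set_index("individual_id").loc[self.individual_ids]
        self.age = sub["age"].to_numpy(float)
        self.sex = sub["sex"].to_numpy()

        idx_of = {iid: i for i, iid in enumerate(self.individual_ids)}
        self.obs_idx = np.asarray([idx_of[i] for i in obs[id_col]], dtype=int)

        if resource == "shellfish":
            self.y = obs["returns_kg"].to_numpy(float)
            d = obs["duration_min"].to_numpy(float)
            t = obs["tide_height"].to_numpy(float)
            self.duration_scale = d.mean() if len(d) else 1.0
            self.tide_centre = t.mean() if len(t) else 0.0
            self.d_scaled = d / self.duration_scale if len(d) else d
            self.t_centred = t - self.tide_centre
        else:
            self.y = obs["captures"].to_numpy(float)
            d = obs["exposure_days"].to_numpy(float)
            self.duration_scale = d.mean() if len(d) else 1.0
            self.d_scaled = d / self.duration_scale if len(d) else d
            self.t_centred = np.zeros_like(self.d_scaled)

        self.include_traits = self.config.include_traits
        if self.include_traits:
            self._build_traits(sub)
        self._build_layout()

    # -- trait scaffolding -------------------------------------------

    def _build_traits(self, sub: pd.DataFrame) -> None:
        h = sub["height_obs"].to_numpy(float)
        g = sub["grip_obs"].to_numpy(float)
        self.height_scale = np.nanmean(h) if np.isfinite(h).any() else 1.0
        self.grip_scale = np.nanmean(g) if np.isfinite(g).any() else 1.0
        self.h_scaled = h / self.height_scale
        self.g_scaled = g / self.grip_scale
        self.h_missing = np.flatnonzero(np.isnan(self.h_scaled))
        self.g_missing = np.flatnonzero(np.isnan(self.g_scaled))

        if self.knowledge is not None:
            self.k_meas_mean = np.asarray(
                [self.knowledge.mean.get(i, np.nan) for i in self.individual_ids]
            )
            self.k_meas_sd = np.asarray(
                [self.knowledge.sd.get(i, np.nan) for i in self.individual_ids]
            )
        else:
            self.k_meas_mean = np.full(self.n_individuals, np.nan)
            self.k_meas_sd = np.full(self.n_individuals, np.nan)
        self.k_measured = np.flatnonzero(np.isfinite(self.k_meas_mean))
        measured = self.k_meas_mean[self.k_measured]
        # unit-mean scale for k = exp(kappa): fixed from measured abilities
        self.knowledge_scale = (
            float(np.mean(np.exp(measured))) if len(measured) else 1.0
        )

    # -- packed layout ------------------------------------------------

    def _build_layout(self) -> None:
        names: list[str] = ["log_alpha", "log_beta", "log_gamma", "xi"]
        if self.resource == "shellfish":
            names += ["tau", "log_sigma"]
        if self.include_traits:
            names += ["zeta", "eta", "theta"]
        self._core_names = list(names)
        names += [f"iota[{i}]" for i in range(self.n_individuals)]
        if self.include_traits:
            for trait in ("height", "grip", "knowledge"):
                names += [
                    f"imp_{trait}_{p}"
                    for p in ("icpt_f", "slope_f", "icpt_m", "slope_m", "log_sd")
                ]
            names += [f"height_latent[{i}]" for i in self.h_missing]
            names += [f"grip_latent[{i}]" for i in self.g_missing]
            names += [f"kappa[{i}]" for i in range(self.n_individuals)]
        self.parameter_names = names
        self.n_dim = len(names)
        self._slices = {}
        pos = 0
        for block, size in self._blocks():
            self._slices[block] = slice(pos, pos + size)
            pos += size
        assert pos == self.n_dim

    def _blocks(self):
        yield "core", len(self._core_names)
        yield "iota", self.n_individuals
        if self.include_traits:
            yield "imp", 15
            yield "height_latent", len(self.h_missing)
            yield "grip_latent", len(self.g_missing)
            yield "kappa", self.n_individuals

    # -- evaluation ----------------------------------------------------

    def unpack(self, x: np.ndarray) -> dict:
        """Named natural-scale parameters from one packed vector."""
        x = np.asarray(x, dtype=float)
        core = x[self._slices["core"]]
        d = dict(zip(self._core_names, core))
        out = {
            "alpha": math.exp(d["log_alpha"]),
            "beta": math.exp(d["log_beta"]),
            "gamma": math.exp(d["log_gamma"]),
            "xi": d["xi"],
            "iota": x[self._slices["iota"]].copy(),
        }
        if self.resource == "shellfish":
            out["tau"] = d["tau"]
            out["sigma"] = math.exp(d["log_sigma"])
        if self.include_traits:
            out.update(zeta=d["zeta"], eta=d["eta"], theta=d["theta"])
            imp = x[self._slices["imp"]]
            for ti, trait in enumerate(("height", "grip", "knowledge")):
                block = imp[5 * ti : 5 * ti + 5]
                out[f"imp_{trait}"] = {
                    "intercept_female": block[0],
                    "slope_female": block[1],
                    "intercept_male": block[2],
                    "slope_male": block[3],
                    "sd": math.exp(block[4]),
                }
            out["height_latent"] = x[self._slices["height_latent"]].copy()
            out["grip_latent"] = x[self._slices["grip_latent"]].copy()
            out["kappa"] = x[self._slices["kappa"]].copy()
        return out

    def pack(self, params: dict) -> np.ndarray:
        """Packed sampling vector from named natural-scale parameters."""
        x = np.zeros(self.n_dim)
        core = {
            "log_alpha": math.log(params["alpha"]),
            "log_beta": math.log(params["beta"]),
            "log_gamma": math.log(params["gamma"]),
            "xi": params["xi"],
        }
        if self.resource == "shellfish":
            core["tau"] = params["tau"]
            core["log_sigma"] = math.log(params["sigma"])
        if self.include_traits:
            core.update(
                zeta=params["zeta"], eta=params["eta"], theta=params["theta"]
            )
        x[self._slices["core"]] = [core[n] for n in self._core_names]
        x[self._slices["iota"]] = params["iota"]
        if self.include_traits:
            imp = []
            for trait in ("height", "grip", "knowledge"):
                b = params[f"imp_{trait}"]
                imp += [
                    b["intercept_female"],
                    b["slope_female"],
                    b["intercept_male"],
                    b["slope_male"],
                    math.log(b["sd"]),
                ]
            x[self._slices["imp"]] = imp
            x[self._slices["height_latent"]] = params.get("height_latent", [])
            x[self._slices["grip_latent"]] = params.get("grip_latent", [])
            x[self._slices["kappa"]] = params["kappa"]
        return x

    def _trait_arrays(self, params: dict, W: int | None = None):
        """(k, h, g) mean-scaled trait arrays, batched if W given."""
        n = self.n_individuals
        if not self.include_traits:
            shape = (W, n) if W else (n,)
            one = np.ones(shape)
            return one, one, one

        def fill(base, missing, latent):
            if W is None:
                v = base.copy()
                if len(missing):
                    v[missing] = latent
                return v
            v = np.broadcast_to(base, (W, n)).copy()
            if len(missing):
                v[:, missing] = latent
            return v

        h = fill(self.h_scaled, self.h_missing, params.get("height_latent", ()))
        g = fill(self.g_scaled, self.g_missing, params.get("grip_latent", ()))
        k = np.exp(params["kappa"]) / self.knowledge_scale
        return k, h, g

    def log_posterior(self, params: dict) -> float:
        """Natural-scale log-posterior (no sampling-coordinate Jacobians).

        The sum of the outcome log-likelihood, the trait imputation /
        measurement terms, and the printed log-priors; raises on
        parameter-domain violations instead of returning -inf from
        coding faults.
        """
        ll = self._log_likelihood(params)
        lp = self._log_prior(params)
        return float(ll + lp)

    def _log_likelihood(self, params: dict) -> float:
        if not len(self.y):
            return 0.0
        k, h, g = self._trait_arrays(params)
        zeta = params.get("zeta", 0.0)
        eta = params.get("eta", 0.0)
        theta = params.get("theta", 0.0)
        phi_i = phi(
            self.age, k, h, g, params["iota"],
            params["beta"], params["gamma"], zeta, eta, theta,
        )
        if self.resource == "shellfish":
            psi = psi_shellfish(self.d_scaled, self.t_centred, params["xi"], params["tau"])
            ll = shellfish_logdensity(
                self.y, params["alpha"], phi_i[self.obs_idx], psi, params["sigma"]
            ).sum()
        else:
            psi = psi_trap(self.d_scaled, params["xi"])
            ll = trap_logdensity(
                self.y.astype(int), params["alpha"], phi_i[self.obs_idx], psi,
                link=self.config.link_choice,
            ).sum()
        ll += self._imputation_terms(params)
        return float(ll)

    def _imputation_terms(self, params: dict) -> float:
        if not self.include_traits:
            return 0.0
        total = 0.0
        k, h, g = self._trait_arrays(params)
        for trait, values in (("height", h), ("grip", g)):
            b = params[f"imp_{trait}"]
            total += imputation_logdensity(
                values, self.age, self.sex,
                b["intercept_female"], b["slope_female"],
                b["intercept_male"], b["slope_male"], b["sd"],
            ).sum()
        b = params["imp_knowledge"]
        total += imputation_logdensity(
            params["kappa"], self.age, self.sex,
            b["intercept_female"], b["slope_female"],
            b["intercept_male"], b["slope_male"], b["sd"],
        ).sum()
        if len(self.k_measured):
            m = self.k_measured
            total += _normal_logpdf(
                self.k_meas_mean[m], params["kappa"][m], self.k_meas_sd[m]
            ).sum()
        return float(total)

    def _log_prior(self, params: dict) -> float:
        pr = self.config.priors
        total = _prior_logpdf(params["alpha"], pr["alpha"])
        total += _prior_logpdf(params["beta"], pr["beta"])
        total += _prior_logpdf(params["gamma"], pr["gamma"])
        total += _prior_logpdf(params["xi"], pr["xi"])
        if self.resource == "shellfish":
            total += _prior_logpdf(params["tau"], pr["tau"])
            total += _prior_logpdf(params["sigma"], pr["sigma"])
        total += _prior_logpdf(params["iota"], pr["iota"]).sum()
        if self.include_traits:
            total += _prior_logpdf(params["zeta"], pr["zeta"])
            total += _prior_logpdf(params["eta"], pr["eta"])
            total += _prior_logpdf(params["theta"], pr["theta"])
            for trait in ("height", "grip"):
                b = params[f"imp_{trait}"]
                for key in ("intercept_female", "intercept_male"):
                    total += _prior_logpdf(b[key], pr["imp_intercept"])
                for key in ("slope_female", "slope_male"):
                    total += _prior_logpdf(b[key], pr["imp_slope"])
                total += _prior_logpdf(b["sd"], pr["imp_sigma"])
            b = params["imp_knowledge"]
            for key in ("intercept_female", "intercept_male"):
                total += _prior_logpdf(b[key], pr["imp_intercept_knowledge"])
            for key in ("slope_female", "slope_male"):
                total += _prior_logpdf(b[key], pr["imp_slope_knowledge"])
            total += _prior_logpdf(b["sd"], pr["imp_sigma_knowledge"])
        return float(total)

    # -- batched sampler interface ------------------------------------

    def __call__(self, x: np.ndarray) -> np.ndarray:
        """Log-posterior in sampling coordinates for a (W, n_dim) batch.

        Adds the log-Jacobians of the log-transformed positive
        parameters; invalid latents (non-positive imputed traits) get
        -inf so the sampler rejects them.
        """
        X = np.atleast_2d(np.asarray(x, dtype=float))
        W = X.shape[0]
        core = X[:, self._slices["core"]]
        cn = {n: i for i, n in enumerate(self._core_names)}
        log_alpha = core[:, cn["log_alpha"]]
        log_beta = core[:, cn["log_beta"]]
        log_gamma = core[:, cn["log_gamma"]]
        alpha = np.exp(log_alpha)
        beta = np.exp(log_beta)
        gamma = np.exp(log_gamma)
        xi = core[:, cn["xi"]]
        iota = X[:, self._slices["iota"]]
        pr = self.config.priors

        jac = log_alpha + log_beta + log_gamma
        logp = (
            _prior_logpdf(alpha, pr["alpha"])
            + _prior_logpdf(beta, pr["beta"])
            + _prior_logpdf(gamma, pr["gamma"])
            + _prior_logpdf(xi, pr["xi"])
            + _prior_logpdf(iota, pr["iota"]).sum(axis=1)
            + jac
        )

        if self.resource == "shellfish":
            tau = core[:, cn["tau"]]
            log_sigma = core[:, cn["log_sigma"]]
            sigma = np.exp(log_sigma)
            logp += (
                _prior_logpdf(tau, pr["tau"])
                + _prior_logpdf(sigma, pr["sigma"])
                + log_sigma
            )
        valid = np.ones(W, dtype=bool)

        if self.include_traits:
            zeta = core[:, cn["zeta"]]
            eta = core[:, cn["eta"]]
            theta = core[:, cn["theta"]]
            logp += (
                _prior_logpdf(zeta, pr["zeta"])
                + _prior_logpdf(eta, pr["eta"])
                + _prior_logpdf(theta, pr["theta"])
            )
            imp = X[:, self._slices["imp"]]
            h_lat = X[:, self._slices["height_latent"]]
            g_lat = X[:, self._slices["grip_latent"]]
            kappa = X[:, self._slices["kappa"]]
            valid &= np.all(h_lat > 0, axis=1) & np.all(g_lat > 0, axis=1)

            prior_keys = {
                "height": ("imp_intercept", "imp_slope", "imp_sigma"),
                "grip": ("imp_intercept", "imp_slope", "imp_sigma"),
                "knowledge": (
                    "imp_intercept_knowledge",
                    "imp_slope_knowledge",
                    "imp_sigma_knowledge",
                ),
            }
            male = self.sex == "male"
            trait_values = {}
            for ti, trait in enumerate(("height", "grip", "knowledge")):
                icpt_f, slope_f, icpt_m, slope_m, log_sd = (
                    imp[:, 5 * ti + j] for j in range(5)
                )
                sd = np.exp(log_sd)
                ik, sk, dk = prior_keys[trait]
                logp += (
                    _prior_logpdf(icpt_f, pr[ik])
                    + _prior_logpdf(icpt_m, pr[ik])
                    + _prior_logpdf(slope_f, pr[sk])
                    + _prior_logpdf(slope_m, pr[sk])
                    + _prior_logpdf(sd, pr[dk])
                    + log_sd
                )
                if trait == "height":
                    v = np.broadcast_to(self.h_scaled, (W, self.n_individuals)).copy()
                    if len(self.h_missing):
                        v[:, self.h_missing] = h_lat
                elif trait == "grip":
                    v = np.broadcast_to(self.g_scaled, (W, self.n_individuals)).copy()
                    if len(self.g_missing):
                        v[:, self.g_missing] = g_lat
                else:
                    v = kappa
                mean = (
                    np.where(male, icpt_m[:, None], icpt_f[:, None])
                    + np.where(male, slope_m[:, None], slope_f[:, None])
                    * self.age[None, :]
                )
                logp += _normal_logpdf(v, mean, sd[:, None]).sum(axis=1)
                trait_values[trait] = v
            if len(self.k_measured):
                m = self.k_measured
                logp += _normal_logpdf(
                    self.k_meas_mean[None, m], kappa[:, m], self.k_meas_sd[None, m]
                ).sum(axis=1)
            k_arr = np.exp(kappa) / self.knowledge_scale
            h_arr = trait_values["height"]
            g_arr = trait_values["grip"]
            trait_log = (
                zeta[:, None] * np.log(k_arr)
                + eta[:, None] * np.log(np.clip(h_arr, 1e-300, None))
                + theta[:, None] * np.log(np.clip(g_arr, 1e-300, None))
            )
        else:
            trait_log = 0.0

        if len(self.y):
            # log (1 - exp(-beta a))**gamma, guarded against underflow at
            # extreme beta values visited during warmup
            one_m = -np.expm1(-beta[:, None] * self.age[None, :])
            log_age_term = gamma[:, None] * np.log(np.clip(one_m, 1e-300, None))
            log_phi = iota + log_age_term + (
                trait_log if np.ndim(trait_log) else 0.0
            )
            log_psi = xi[:, None] * np.log(self.d_scaled[None, :])
            if self.resource == "shellfish":
                log_psi = log_psi + tau[:, None] * self.t_centred[None, :]
                mu = log_alpha[:, None] + log_phi[:, self.obs_idx] + log_psi
                logy = np.log(self.y)[None, :]
                z = (logy - mu) / sigma[:, None]
                logp += (
                    -0.5 * (z**2).sum(axis=1)
                    - self.y.size * (0.5 * _LOG_2PI)
                    - self.y.size * log_sigma
                    - np.log(self.y).sum()
                )
            else:
                log_core = log_alpha[:, None] + log_phi[:, self.obs_idx] + log_psi
                from scipy.special import gammaln

                with np.errstate(over="ignore", invalid="ignore"):
                    if self.config.link_choice == "product":
                        lam = np.exp(log_core)
                        log_lam = log_core
                    else:
                        lam = np.exp(np.exp(log_core))
                        log_lam = np.exp(log_core)
                    logp += (
                        self.y[None, :] * log_lam - lam
                    ).sum(axis=1) - gammaln(self.y + 1.0).sum()

        logp = np.where(valid & np.isfinite(logp), logp, -np.inf)
        return logp if np.ndim(x) == 2 else float(logp[0])

    # -- initialisation -------------------------------------------------

    def initial_vector(self, rng: np.random.Generator) -> np.ndarray:
        """A random overdispersed but valid starting point."""
        x = np.zeros(self.n_dim)
        x[self._slices["core"]] = rng.normal(0.0, 0.3, len(self._core_names))
        # keep log_alpha near the empirical outcome scale
        if len(self.y):
            if self.resource == "shellfish":
                x[self._core_names.index("log_alpha")] = math.log(
                    max(np.median(self.y), 1e-3)
                ) + rng.normal(0, 0.3)
            else:
                x[self._core_names.index("log_alpha")] = math.log(
                    max(self.y.mean(), 1e-3)
                ) + rng.normal(0, 0.3)
        x[self._slices["iota"]] = rng.normal(0.0, 0.3, self.n_individuals)
        if self.include_traits:
            imp = []
            for trait in ("height", "grip", "knowledge"):
                icpt = 1.0 if trait != "knowledge" else 0.0
                imp += [
                    icpt + rng.normal(0, 0.05),
                    rng.normal(0, 0.01),
                    icpt + rng.normal(0, 0.05),
                    rng.normal(0, 0.01),
                    math.log(0.2) + rng.normal(0, 0.1),
                ]
            x[self._slices["imp"]] = imp
            x[self._slices["height_latent"]] = 1.0 + rng.normal(
                0, 0.05, len(self.h_missing)
            )
            x[self._slices["grip_latent"]] = 1.0 + rng.normal(
                0, 0.05, len(self.g_missing)
            )
            kap = np.where(
                np.isfinite(self.k_meas_mean), np.nan_to_num(self.k_meas_mean), 0.0
            )
            x[self._slices["kappa"]] = kap + rng.normal(0, 0.1, self.n_individuals)
        return x


def total_logposterior(
    dataset: ForagingDataset,
    params: dict,
    config: RunConfig | None = None,
    resource: str = "shellfish",
    knowledge: KnowledgeSummary | None = None,
) -> float:
    """Scalar log-posterior of one resource model at named parameter values.

    Sums the outcome log-densities over all observations, the trait
    imputation terms (when the configuration includes traits), and the
    log-priors, all on the natural parameter scale.
    """
    lp = ForagingLogPosterior(dataset, resource, config, knowledge)
    return lp.log_posterior(params)
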