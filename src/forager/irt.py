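"""Two-parameter logistic (2PL) item response model for ecological knowledge.

A single latent ability per individual is estimated from the pooled
binary responses of the three survey components (knowledge questions,
picture identifications, itemised freelist answers).  Item parameters
are fitted by marginal maximum a-posteriori EM (Bock-Aitkin quadrature
over a standard-normal ability prior); each individual's ability
posterior is then evaluated on a dense grid given the fitted items
(empirical Bayes), drawn from, and standardised across individuals so
that the latent scale is identified (mean 0, sd 1 within each draw).

Priors: discrimination ~ lognormal(0, 0.5) (sign-identified, weakly
informative), difficulty ~ normal(0, 1).  Degenerate items with all-0
or all-1 observed responses are flagged and retained: the priors keep
their parameters finite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from sklearn.base import BaseEstimator, TransformerMixin


def response_probability(kappa, discrimination, difficulty):
    """2PL probability of a correct response: logistic(a * (kappa - b)).

    Strictly increasing in ``kappa`` when ``discrimination`` > 0; equals
    0.5 at ``kappa == difficulty`` (and everywhere when discrimination
    is zero).  Broadcasts over array inputs.
    """
    kappa = np.asarray(kappa, dtype=float)
    a = np.asarray(discrimination, dtype=float)
    b = np.asarray(difficulty, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("item parameters must be finite")
    return expit(a * (kappa - b))


def _response_loglik(X: np.ndarray, grid: np.ndarray, disc, diff) -> np.ndarray:
    """Log-likelihood of each individual's responses at each grid ability.

    X is (n_individuals, n_items) with NaN for unobserved responses;
    returns (n_individuals, n_grid).
    """
    p = response_probability(grid[None, :, None], disc[None, None, :], diff[None, None, :])
    p = np.clip(p, 1e-12, 1 - 1e-12)
    Xb = X[:, None, :]
    obs = ~np.isnan(Xb)
    terms = np.where(obs, np.where(Xb == 1, np.log(p), np.log1p(-p)), 0.0)
    return terms.sum(axis=2)


def ability_posterior(
    X: np.ndarray,
    discrimination: np.ndarray,
    difficulty: np.ndarray,
    grid: np.ndarray | None = None,
    prior_mean: float = 0.0,
    prior_sd: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Grid posterior of ability for each response row, item parameters fixed.

    Returns ``(grid, weights)`` where ``weights[i]`` sums to one and is
    proportional to the normal prior times the 2PL likelihood of row i.
    Rows with no observed responses get the prior itself.
    """
    if grid is None:
        grid = np.linspace(-5.0, 5.0, 201)
    X = np.asarray(X, dtype=float)
    disc = np.asarray(discrimination, dtype=float)
    diff = np.asarray(difficulty, dtype=float)
    log_prior = -0.5 * ((grid - prior_mean) / prior_sd) ** 2
    log_post = _response_loglik(X, grid, disc, diff) + log_prior[None, :]
    log_post -= logsumexp(log_post, axis=1, keepdims=True)
    return grid, np.exp(log_post)


class TwoParameterLogisticIRT(BaseEstimator, TransformerMixin):
    """Scikit-learn style 2PL estimator over a binary response matrix.

    Parameters
    ----------
    n_grid : int
        Number of equally spaced quadrature/posterior grid points.
    grid_limit : float
        Grid spans ``[-grid_limit, grid_limit]`` on the latent scale.
    max_iter, tol : EM stopping rule (max |item-parameter change|).
    disc_prior_sd : float
        Scale of the lognormal(0, sd) discrimination prior.
    diff_prior_sd : float
        Scale of the normal(0, sd) difficulty prior.
    n_draws : int
        Posterior ability draws retained per individual.
    standardize : bool
        Standardise abilities across individuals within each draw
        (identification of the latent scale).
    random_state : int
        Seed for the posterior draws.

    Attributes
    ----------
    discrimination_, difficulty_ : (n_items,) fitted item parameters.
    ability_mean_, ability_sd_ : (n_individuals,) posterior summaries.
    ability_draws_ : (n_draws, n_individuals) posterior draws.
    degenerate_items_ : indices of all-0 / all-1 items.
    n_iter_ : EM iterations used.
    """

    def __init__(
        self,
        n_grid: int = 121,
        grid_limit: float = 5.0,
        max_iter: int = 200,
        tol: float = 1e-4,
        disc_prior_sd: float = 0.5,
        diff_prior_sd: float = 1.0,
        n_draws: int = 500,
        standardize: bool = True,
        random_state: int = 0,
    ):
        self.n_grid = n_grid
        self.grid_limit = grid_limit
        self.max_iter = max_iter
        self.tol = tol
        self.disc_prior_sd = disc_prior_sd
        self.diff_prior_sd = diff_prior_sd
        self.n_draws = n_draws
        self.standardize = standardize
        self.random_state = random_state

    # -- EM fitting ---------------------------------------------------

    def _m_step_item(self, theta, n_q, r_q, la0, b0):
        """Maximise the expected item log-likelihood plus log-priors for
        one item over (log discrimination, difficulty)."""

        def negobj(x):
            la, b = x
            a = np.exp(la)
            p = np.clip(expit(a * (theta - b)), 1e-12, 1 - 1e-12)
            ll = np.sum(r_q * np.log(p) + (n_q - r_q) * np.log1p(-p))
            lp = -0.5 * (la / self.disc_prior_sd) ** 2 - 0.5 * (b / self.diff_prior_sd) ** 2
            resid = r_q - n_q * p
            ga = np.sum(resid * (theta - b)) * a - la / self.disc_prior_sd**2
            gb = -np.sum(resid) * a - b / self.diff_prior_sd**2
            return -(ll + lp), -np.array([ga, gb])

        res = minimize(negobj, np.array([la0, b0]), jac=True, method="L-BFGS-B")
        return res.x

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be (n_individuals, n_items)")
        n, m = X.shape
        if n < 2 or m < 2:
            raise ValueError("need at least 2 individuals and 2 items")
        vals = X[~np.isnan(X)]
        if not np.isin(vals, [0.0, 1.0]).all():
            raise ValueError("responses must be binary (0/1) or missing")

        obs = ~np.isnan(X)
        col_means = np.nanmean(np.where(obs, X, np.nan), axis=0)
        self.degenerate_items_ = np.flatnonzero(
            (col_means == 0.0) | (col_means == 1.0) | ~obs.any(axis=0)
        )

        theta = np.linspace(-self.grid_limit, self.grid_limit, self.n_grid)
        log_prior = -0.5 * theta**2
        la = np.zeros(m)  # log discrimination
        b = np.zeros(m)

        for it in range(self.max_iter):
            log_post = _response_loglik(X, theta, np.exp(la), b) + log_prior[None, :]
            log_post -= logsumexp(log_post, axis=1, keepdims=True)
            W = np.exp(log_post)  # (n, Q)
            Xo = np.where(obs, X, 0.0)
            # expected per-item counts at each node
            n_q = obs.T.astype(float) @ W  # (m, Q)
            r_q = Xo.T @ W
            la_new, b_new = la.copy(), b.copy()
            for j in range(m):
                la_new[j], b_new[j] = self._m_step_item(theta, n_q[j], r_q[j], la[j], b[j])
            delta = max(np.max(np.abs(la_new - la)), np.max(np.abs(b_new - b)))
            la, b = la_new, b_new
            if delta < self.tol:
                break
        self.n_iter_ = it + 1
        self.discrimination_ = np.exp(la)
        self.difficulty_ = b

        grid, W = ability_posterior(X, self.discrimination_, self.difficulty_)
        self.ability_grid_ = grid
        self.ability_weights_ = W
        rng = np.random.default_rng(self.random_state)
        # inverse-CDF sampling on the grid, with within-cell jitter
        cdf = np.cumsum(W, axis=1)
        u = rng.random((self.n_draws, n))
        idx = np.empty((self.n_draws, n), dtype=int)
        for i in range(n):
            idx[:, i] = np.searchsorted(cdf[i], u[:, i])
        step = grid[1] - grid[0]
        draws = grid[idx] + rng.uniform(-step / 2, step / 2, idx.shape)
        if self.standardize:
            draws = (draws - draws.mean(axis=1, keepdims=True)) / draws.std(
                axis=1, keepdims=True
            )
        self.ability_draws_ = draws
        self.ability_mean_ = draws.mean(axis=0)
        self.ability_sd_ = draws.std(axis=0)
        return self

    def transform(self, X):
        """Posterior-mean abilities for new response rows, items fixed."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "discrimination_")
        grid, W = ability_posterior(
            np.asarray(X, dtype=float), self.discrimination_, self.difficulty_
        )
        return (W @ grid)[:, None]


def responses_to_matrix(responses: pd.DataFrame) -> tuple[np.ndarray, list, list]:
    """Pivot a long response table into (matrix, individual_ids, item_ids)."""
    wide = responses.pivot(index="individual_id", columns="item_id", values="response")
    return wide.to_numpy(dtype=float), list(wide.index), list(wide.columns)


def fit_irt(
    responses: pd.DataFrame, **settings
) -> tuple[pd.DataFrame, pd.DataFrame, TwoParameterLogisticIRT]:
    """Fit the 2PL to a long-format response table.

    Returns ``(item_params, ability_tidy, estimator)`` where
    ``ability_tidy`` has one row per (individual_id, draw).
    """
    X, ind_ids, item_ids = responses_to_matrix(responses)
    est = TwoParameterLogisticIRT(**settings).fit(X)
    comp = (
        responses.drop_duplicates("item_id").set_index("item_id")["component"]
        if "component" in responses.columns
        else pd.Series(index=item_ids, dtype=object)
    )
    item_params = pd.DataFrame(
        {
            "item_id": item_ids,
            "component": [comp.get(i) for i in item_ids],
            "discrimination": est.discrimination_,
            "difficulty": est.difficulty_,
        }
    )
    n_draws, n = est.ability_draws_.shape
    ability = pd.DataFrame(
        {
            "individual_id": np.tile(ind_ids, n_draws),
            "draw": np.repeat(np.arange(n_draws), n),
            "ability": est.ability_draws_.ravel(),
        }
    )
    return item_params, ability, est
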