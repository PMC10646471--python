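"""Counterfactual reports: closed-form checks and sign/shape invariants."""

import math

import numpy as np
import pandas as pd
import pytest

from forager.config import RunConfig
from forager.counterfactuals import (
    age_curve,
    outcome_contrast,
    posterior_predict,
    trait_contrast,
)
from forager.data import ForagingDataset
from forager.inference import PosteriorDraws
from forager.model import ForagingLogPosterior


def _draws_from(values: dict, model=None) -> PosteriorDraws:
    """Wrap explicit per-parameter arrays as (1, n) chain draws."""
    d = {k: np.atleast_2d(np.asarray(v, dtype=float)) for k, v in values.items()}
    return PosteriorDraws(draws=d, model=model)


def _reference_model(include_traits=False):
    ind = pd.DataFrame(
        {
            "individual_id": ["a", "b"],
            "sex": ["female", "male"],
            "age": [10.0, 20.0],
            "height_obs": [120.0, 160.0],
            "grip_obs": [10.0, 30.0],
        }
    )
    sf = pd.DataFrame(
        {
            "individual_id": ["a", "b", "b"],
            "trip_id": ["t0", "t0", "t1"],
            "returns_kg": [1.0, 2.0, 3.0],
            "duration_min": [100.0, 100.0, 200.0],
            "tide_height": [0.5, 0.5, 1.5],
        }
    )
    ds = ForagingDataset(individuals=ind, shellfish=sf).validate()
    return ForagingLogPosterior(ds, "shellfish", RunConfig(include_traits=include_traits))


class TestAgeCurve:
    def test_single_draw_closed_form(self):
        draws = _draws_from({"beta": [0.1], "gamma": [1.0]})
        curve = age_curve(draws, np.linspace(0, 100, 1001))
        got = curve.at_age(10.0)[0]
        expected = (1 - math.exp(-1.0)) / (1 - math.exp(-10.0))
        assert got == pytest.approx(expected, abs=1e-4)
        assert got == pytest.approx(0.632, abs=1e-3)

    def test_tiny_gamma_flattens_the_curve(self):
        draws = _draws_from({"beta": [0.5], "gamma": [1e-9]})
        curve = age_curve(draws, np.linspace(1, 60, 60))
        assert np.all(curve.normalized[0] > 0.999)

    def test_curve_attains_one_and_is_nondecreasing(self):
        rng = np.random.default_rng(0)
        draws = _draws_from(
            {"beta": rng.exponential(1, 50) + 0.01, "gamma": rng.exponential(1, 50) + 0.01}
        )
        curve = age_curve(draws, np.linspace(0.5, 60, 120))
        assert np.allclose(curve.normalized.max(axis=1), 1.0)
        assert np.all(np.diff(curve.normalized, axis=1) >= -1e-12)

    def test_alpha_cancels_out(self):
        # the ratio involves only beta and gamma: alpha draws are unused
        draws = _draws_from({"beta": [0.2], "gamma": [1.5]})
        curve = age_curve(draws, np.linspace(1, 40, 40))
        assert curve.normalized.shape == (1, 40)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            age_curve(_draws_from({"beta": [0.1], "gamma": [1.0]}), np.array([]))


class TestTraitContrast:
    def test_zero_exponent_gives_zero_contrast(self):
        draws = _draws_from({"zeta": np.zeros(20)})
        res = trait_contrast(draws, "knowledge", 0.5, 2.0)
        assert np.all(res.values == 0.0)

    def test_closed_form_height_contrast(self):
        draws = _draws_from({"eta": [0.5]})
        res = trait_contrast(draws, "height", 0.5, 2.0)
        assert res.values[0] == pytest.approx(math.sqrt(2) - math.sqrt(0.5), abs=1e-9)
        assert res.values[0] == pytest.approx(0.70711, abs=1e-5)

    def test_sign_matches_exponent_draw_by_draw(self):
        rng = np.random.default_rng(2)
        e = rng.normal(size=200)
        draws = _draws_from({"theta": e})
        res = trait_contrast(draws, "grip", 0.5, 2.0)
        assert np.all(np.sign(res.values) == np.sign(e))

    def test_unknown_or_absent_trait_errors(self):
        draws = _draws_from({"eta": [0.5]})
        with pytest.raises(ValueError):
            trait_contrast(draws, "speed", 0.5, 2.0)
        with pytest.raises(ValueError):
            trait_contrast(draws, "grip", 0.5, 2.0)


class TestOutcomeContrast:
    def _age_only_draws(self, **over):
        model = _reference_model()
        n = model.n_individuals
        base = {
            "alpha": [1.2],
            "beta": [0.3],
            "gamma": [1.0],
            "xi": [1.0],
            "tau": [-0.5],
            "sigma": [1e-9],
        }
        base.update({f"iota[{i}]": [0.0] for i in range(n)})
        base.update(over)
        return _draws_from(base, model=model), model

    def test_degenerate_range_gives_zero(self):
        draws, _ = self._age_only_draws()
        res = outcome_contrast(draws, "duration", low=1.0, high=1.0)
        assert np.allclose(res.values, 0.0)

    def test_duration_doubling_equals_alpha_phi_bar(self):
        """xi=1, sigma->0: doubling the scaled duration from 1 to 2 adds one
        reference-trip expected catch, alpha * mean phi."""
        draws, model = self._age_only_draws()
        res = outcome_contrast(draws, "duration", low=1.0, high=2.0)
        phi_bar = np.mean(
            (1 - np.exp(-0.3 * model.age)) ** 1.0
        )
        assert res.values[0] == pytest.approx(1.2 * phi_bar, rel=1e-6)

    def test_negative_tide_coefficient_gives_negative_contrast(self):
        rng = np.random.default_rng(3)
        n = 2
        tau = -np.abs(rng.normal(0.5, 0.2, 30))
        model = _reference_model()
        base = {
            "alpha": np.full(30, 1.0),
            "beta": np.full(30, 0.3),
            "gamma": np.full(30, 1.0),
            "xi": np.full(30, 0.5),
            "tau": tau,
            "sigma": np.full(30, 0.3),
        }
        base.update({f"iota[{i}]": np.zeros(30) for i in range(n)})
        draws = _draws_from(base, model=model)
        res = outcome_contrast(draws, "tide")
        assert np.all(res.values < 0)

    def test_trait_predictor_requires_trait_model(self):
        draws, _ = self._age_only_draws()
        with pytest.raises(ValueError):
            outcome_contrast(draws, "height")

    def test_tide_absent_for_traps_errors(self):
        ind = pd.DataFrame(
            {
                "individual_id": ["a"],
                "sex": ["male"],
                "age": [15.0],
                "height_obs": [150.0],
                "grip_obs": [20.0],
            }
        )
        tr = pd.DataFrame(
            {
                "trap_id": ["x0", "x1"],
                "installer_id": ["a", "a"],
                "exposure_days": [2.0, 8.0],
                "captures": [0, 1],
            }
        )
        ds = ForagingDataset(individuals=ind, traps=tr).validate()
        model = ForagingLogPosterior(ds, "trap", RunConfig())
        draws = _draws_from(
            {"alpha": [0.1], "beta": [0.1], "gamma": [1.0], "xi": [1.0],
             "iota[0]": [0.0]},
            model=model,
        )
        with pytest.raises(ValueError):
            outcome_contrast(draws, "tide")


class TestPosteriorPredict:
    def test_zero_sigma_collapses_to_mean_surface(self):
        model = _reference_model()
        draws = _draws_from(
            {
                "alpha": [1.2], "beta": [0.3], "gamma": [1.0],
                "xi": [0.8], "tau": [-0.4], "sigma": [1e-12],
                "iota[0]": [0.1], "iota[1]": [-0.2],
            },
            model=model,
        )
        from forager.counterfactuals import expected_outcome_rows

        pp = posterior_predict(draws, seed=0)
        np.testing.assert_allclose(pp.values, expected_outcome_rows(draws), rtol=1e-6)

    def test_trap_predictive_reproduces_success_rate(self):
        """Poisson predictions at the fitted rate match the simulated
        success fraction within Monte-Carlo error."""
        rng = np.random.default_rng(8)
        ind = pd.DataFrame(
            {
                "individual_id": [f"i{k}" for k in range(10)],
                "sex": ["male"] * 10,
                "age": rng.uniform(8, 25, 10),
                "height_obs": rng.normal(150, 8, 10),
                "grip_obs": rng.normal(20, 4, 10),
            }
        )
        lam_true = 0.05
        tr = pd.DataFrame(
            {
                "trap_id": [f"x{k}" for k in range(600)],
                "installer_id": rng.choice(ind["individual_id"], 600),
                "exposure_days": np.full(600, 5.0),
                "captures": rng.poisson(lam_true, 600),
            }
        )
        ds = ForagingDataset(individuals=ind, traps=tr).validate()
        model = ForagingLogPosterior(ds, "trap", RunConfig())
        base = {
            "alpha": np.full(50, lam_true), "beta": np.full(50, 5.0),
            "gamma": np.full(50, 1.0), "xi": np.full(50, 0.0),
        }
        base.update({f"iota[{i}]": np.zeros(50) for i in range(10)})
        draws = _draws_from(base, model=model)
        pp = posterior_predict(draws, seed=1)
        pred_frac = (pp.values > 0).mean()
        # closed form: P(S > 0) = 1 - exp(-lambda)
        assert pred_frac == pytest.approx(1 - math.exp(-lam_true), abs=0.01)
        # and the simulated data's own success fraction sits inside the
        # predictive binomial band
        obs_frac = (tr["captures"] > 0).mean()
        band = 3 * math.sqrt(pred_frac * (1 - pred_frac) / len(tr))
        assert abs(obs_frac - pred_frac) < band + 0.01
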