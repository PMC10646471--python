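"""Deterministic model components against closed-form oracles, plus
algebraic invariants of the Cobb-Douglas production structure."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from forager.config import RunConfig
from forager.data import ForagingDataset
from forager.model import (
    ForagingLogPosterior,
    age_component,
    imputation_logdensity,
    phi,
    psi_shellfish,
    psi_trap,
    shellfish_logdensity,
    total_logposterior,
    trap_logdensity,
)


class TestAgeComponent:
    def test_zero_age_gives_zero(self):
        assert age_component(0.0, 0.5, 2.0) == 0.0

    def test_saturates_at_one(self):
        assert age_component(1e4, 0.5, 1.0) == pytest.approx(1.0)

    def test_closed_form_value(self):
        # (1 - e^{-1})^2
        assert age_component(10.0, 0.1, 2.0) == pytest.approx(
            (1 - math.exp(-1)) ** 2, abs=1e-12
        )
        assert age_component(10.0, 0.1, 2.0) == pytest.approx(0.39958, abs=1e-5)

    @pytest.mark.parametrize("beta,gamma", [(0.0, 1.0), (-0.1, 1.0), (0.1, 0.0)])
    def test_domain_errors(self, beta, gamma):
        with pytest.raises(ValueError):
            age_component(5.0, beta, gamma)

    def test_strictly_increasing_in_age(self):
        a = np.linspace(0.1, 80, 200)
        v = age_component(a, 0.12, 1.7)
        assert np.all(np.diff(v) > 0)


class TestPhi:
    def test_unit_traits_reduce_to_age_component(self):
        val = phi(12.0, 1.0, 1.0, 1.0, 0.0, 0.2, 1.5, -0.3, 0.6, 0.1)
        assert val == pytest.approx(age_component(12.0, 0.2, 1.5))

    def test_zero_trait_with_positive_exponent_kills_production(self):
        assert phi(12.0, 0.0, 1.0, 1.0, 0.0, 0.2, 1.5, 0.5, 0.6, 0.1) == 0.0

    def test_closed_form_value(self):
        # age term 0.25 via beta/gamma, k=2 with zeta=1/2 -> 0.25 * sqrt(2)
        beta, a = 0.5, 10.0
        gamma = math.log(0.25) / math.log(1 - math.exp(-beta * a))
        val = phi(a, 2.0, 1.0, 1.0, 0.0, beta, gamma, 0.5, 0.0, 0.0)
        assert val == pytest.approx(0.25 * math.sqrt(2), abs=1e-9)
        assert val == pytest.approx(0.35355, abs=1e-5)

    def test_zero_trait_with_negative_exponent_is_an_error(self):
        with pytest.raises(ValueError, match="grip"):
            phi(12.0, 1.0, 1.0, 0.0, 0.0, 0.2, 1.5, 0.0, 0.0, -0.5)

    @settings(derandomize=True, max_examples=50)
    @given(
        e=st.floats(-1.5, 1.5).filter(lambda v: v == 0.0 or abs(v) > 1e-3),
        lo=st.floats(0.2, 0.9),
        hi=st.floats(1.1, 4.0),
    )
    def test_monotone_in_trait_according_to_exponent_sign(self, e, lo, hi):
        f_lo = phi(10.0, lo, 1.0, 1.0, 0.0, 0.2, 1.0, e, 0.0, 0.0)
        f_hi = phi(10.0, hi, 1.0, 1.0, 0.0, 0.2, 1.0, e, 0.0, 0.0)
        if e > 0:
            assert f_hi > f_lo
        elif e < 0:
            assert f_hi < f_lo
        else:
            assert f_hi == pytest.approx(f_lo)


class TestPsi:
    def test_reference_trip_is_one(self):
        assert psi_shellfish(1.0, 0.0, 0.8, -0.5) == 1.0
        assert psi_trap(1.0, -2.3) == 1.0

    def test_closed_forms(self):
        assert psi_shellfish(4.0, 0.0, 0.5, 1.0) == pytest.approx(2.0)
        assert psi_shellfish(1.0, 0.5, 1.0, -1.0) == pytest.approx(
            math.exp(-0.5), abs=1e-9
        )
        assert psi_trap(3.0, 1.0) == pytest.approx(3.0)
        assert psi_trap(5.0, 0.7) == pytest.approx(5.0**0.7, abs=1e-9)
        assert psi_trap(5.0, 0.7) == pytest.approx(3.08517, abs=1e-5)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            psi_shellfish(0.0, 0.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            psi_trap(-1.0, 1.0)


class TestOutcomeDensities:
    def test_lognormal_at_median_matches_closed_form(self):
        r, sigma = 1.7, 0.4
        val = shellfish_logdensity(r, 1.0, 1.7, 1.0, sigma)
        assert val == pytest.approx(
            -math.log(r) - math.log(sigma * math.sqrt(2 * math.pi)), abs=1e-12
        )

    def test_lognormal_matches_scipy_oracle(self):
        # R = 2 with alpha*phi*psi = 1, sigma = 1
        oracle = stats.lognorm(s=1.0, scale=1.0).logpdf(2.0)
        assert shellfish_logdensity(2.0, 1.0, 1.0, 1.0, 1.0) == pytest.approx(
            oracle, abs=1e-12
        )

    def test_flatness_limit_in_sigma(self):
        vals = [shellfish_logdensity(2.0, 1.0, 1.0, 1.0, s) for s in (1, 5, 25, 125)]
        assert np.all(np.diff(vals) < 0)

    def test_poisson_closed_forms(self):
        assert trap_logdensity(0, 1.0, 0.06, 1.0) == pytest.approx(-0.06)
        assert trap_logdensity(1, 1.0, 1.0, 1.0) == pytest.approx(-1.0)

    def test_printed_exp_link_forces_rate_at_least_one(self):
        # alpha*phi*psi = 0  =>  lambda = exp(0) = 1
        val = trap_logdensity(0, 0.0, 1.0, 1.0, link="printed_exp")
        assert val == pytest.approx(stats.poisson(1.0).logpmf(0), abs=1e-12)
        # so a zero count can never be more likely than e^{-1}
        grids = np.linspace(0.0, 3.0, 31)
        for core in grids:
            assert trap_logdensity(0, core, 1.0, 1.0, link="printed_exp") <= -1.0

    def test_default_link_permits_rare_successes(self):
        # expected successes per trap far below one, as in the observed data
        lam = 31 / 724
        assert math.exp(trap_logdensity(0, lam, 1.0, 1.0)) > 0.95

    def test_scale_coherence_alpha_vs_psi(self):
        c = 3.7
        a = shellfish_logdensity(2.4, 1.2, 0.8, 0.9, 0.5)
        b = shellfish_logdensity(2.4, 1.2 * c, 0.8, 0.9 / c, 0.5)
        assert a == pytest.approx(b, abs=1e-12)

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            shellfish_logdensity(-1.0, 1.0, 1.0, 1.0, 0.5)
        with pytest.raises(ValueError):
            trap_logdensity(-1, 1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            trap_logdensity(2, 1.0, 1.0, 1.0, link="other")


class TestImputation:
    def test_observed_traits_match_scipy_normal(self):
        val = imputation_logdensity(
            1.1, 12.0, "female", 1.0, 0.01, 0.9, 0.02, 0.2
        )
        assert val == pytest.approx(
            stats.norm(1.0 + 0.01 * 12.0, 0.2).logpdf(1.1), abs=1e-12
        )

    def test_small_sd_pins_value_to_regression_line(self):
        grid = np.linspace(0.5, 1.5, 1001)
        dens = imputation_logdensity(grid, 10.0, "male", 1.0, 0.0, 0.8, 0.02, 1e-4)
        assert grid[np.argmax(dens)] == pytest.approx(0.8 + 0.02 * 10.0, abs=1e-3)

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            imputation_logdensity(1.0, 10.0, "male", 1.0, 0.0, 1.0, 0.0, 0.0)


def _toy_dataset():
    ind = pd.DataFrame(
        {
            "individual_id": ["a", "b", "c"],
            "sex": ["female", "male", "female"],
            "age": [10.0, 16.0, 25.0],
            "height_obs": [130.0, 150.0, np.nan],
            "grip_obs": [10.0, 20.0, 28.0],
        }
    )
    sf = pd.DataFrame(
        {
            "individual_id": ["a", "a", "b", "c", "c"],
            "trip_id": ["t0", "t1", "t0", "t1", "t2"],
            "returns_kg": [0.5, 1.2, 2.0, 3.1, 1.8],
            "duration_min": [120.0, 200.0, 120.0, 200.0, 150.0],
            "tide_height": [0.8, 1.4, 0.8, 1.4, 1.0],
        }
    )
    return ForagingDataset(individuals=ind, shellfish=sf).validate()


def test_empty_dataset_logposterior_is_prior_only():
    ind = pd.DataFrame(
        {c: [] for c in ("individual_id", "sex", "age", "height_obs", "grip_obs")}
    )
    ds = ForagingDataset(individuals=ind)
    params = dict(alpha=0.8, beta=0.3, gamma=1.2, xi=0.5, tau=-0.2, sigma=0.6,
                  iota=np.array([]))
    got = total_logposterior(ds, params, RunConfig(), "shellfish")
    expected = (
        stats.halfnorm(scale=1.0).logpdf(0.8)
        + stats.expon(scale=1.0).logpdf(0.3)
        + stats.expon(scale=1.0).logpdf(1.2)
        + stats.norm(0, 1).logpdf(0.5)
        + stats.norm(0, 1).logpdf(-0.2)
        + stats.expon(scale=1.0).logpdf(0.6)
    )
    assert got == pytest.approx(expected, abs=1e-10)


def test_widening_a_prior_lowers_its_density_at_an_interior_point():
    cfg_narrow = RunConfig()
    cfg_wide = RunConfig()
    cfg_wide.priors["tau"] = {"dist": "normal", "loc": 0.0, "scale": 3.0}
    ind = pd.DataFrame(
        {c: [] for c in ("individual_id", "sex", "age", "height_obs", "grip_obs")}
    )
    ds = ForagingDataset(individuals=ind)
    params = dict(alpha=0.8, beta=0.3, gamma=1.2, xi=0.5, tau=0.1, sigma=0.6,
                  iota=np.array([]))
    assert total_logposterior(ds, params, cfg_wide, "shellfish") < total_logposterior(
        ds, params, cfg_narrow, "shellfish"
    )


def test_packed_vector_matches_dict_evaluation_plus_jacobian():
    """Sampling-coordinate density = natural density + log|J| of the
    log-transformed positive parameters."""
    ds = _toy_dataset()
    cfg = RunConfig(include_traits=True)
    lp = ForagingLogPosterior(ds, "shellfish", cfg)
    rng = np.random.default_rng(0)
    for _ in range(5):
        x = lp.initial_vector(rng)
        params = lp.unpack(x)
        jac = (
            math.log(params["alpha"]) + math.log(params["beta"])
            + math.log(params["gamma"]) + math.log(params["sigma"])
            + sum(math.log(params[f"imp_{t}"]["sd"]) for t in ("height", "grip", "knowledge"))
        )
        assert lp(x[None, :])[0] == pytest.approx(lp.log_posterior(params) + jac, abs=1e-8)


def test_pack_unpack_round_trip():
    ds = _toy_dataset()
    lp = ForagingLogPosterior(ds, "shellfish", RunConfig(include_traits=True))
    x = lp.initial_vector(np.random.default_rng(3))
    np.testing.assert_allclose(lp.pack(lp.unpack(x)), x, atol=1e-12)
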