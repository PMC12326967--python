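"""Structural model, covariate equations and residual-error model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from amikapk.model import (
    CovariateSet,
    DoseEvent,
    IndividualParameters,
    PopulationModel,
    apply_residual_error,
    concentration,
    final_model,
    individual_params,
    model_from_dict,
    model_to_dict,
    typical_cl,
    typical_v,
)

from conftest import ode_concentration


class TestTypicalValues:
    def test_reference_neonate_matches_published_typical_values(
        self, model, reference_covariates
    ):
        # 1 kg, 30-week-PMA neonate sits exactly at the model's reference
        assert typical_cl(reference_covariates, model) == pytest.approx(
            0.0487, abs=1e-12
        )
        assert typical_v(reference_covariates, model) == pytest.approx(
            0.497, abs=1e-12
        )

    def test_zero_exponents_collapse_to_theta(self, model, reference_covariates):
        flat = model.replace(exp_wt_cl=0.0, exp_pma_cl=0.0, exp_wt_v=0.0)
        cov = CovariateSet(wt=2345.0, pma=41.0, ga=30.0, pna=77.0, scr=50.0)
        assert typical_cl(cov, flat) == model.theta_cl
        assert typical_v(cov, flat) == model.theta_v

    @pytest.mark.parametrize(
        "wt, pma, expected_cl",
        [
            (2000.0, 30.0, 0.0487 * 2**0.919),
            (1500.0, 30.0, 0.0487 * 1.5**0.919),
            (1000.0, 45.0, 0.0487 * 1.5**1.53),
        ],
    )
    def test_power_scaling_of_clearance(self, model, wt, pma, expected_cl):
        cov = CovariateSet(wt=wt, pma=pma, ga=28.0, pna=7 * (pma - 28), scr=43.0)
        assert typical_cl(cov, model) == pytest.approx(expected_cl, rel=1e-12)

    def test_volume_power_scaling_and_linear_case(self, model):
        cov = CovariateSet(wt=1500.0, pma=32.0)
        assert typical_v(cov, model) == pytest.approx(0.497 * 1.5**0.851, rel=1e-12)
        linear = model.replace(exp_wt_v=1.0)
        cov2 = CovariateSet(wt=2000.0, pma=32.0)
        assert typical_v(cov2, linear) == pytest.approx(2 * model.theta_v, rel=1e-12)

    def test_monotone_in_weight_and_maturation(self, model):
        cls = [
            typical_cl(CovariateSet(wt=w, pma=30.0), model)
            for w in (600, 1000, 2000, 3000)
        ]
        assert np.all(np.diff(cls) > 0)
        cls = [
            typical_cl(CovariateSet(wt=1000.0, pma=p), model)
            for p in (26, 30, 38, 45)
        ]
        assert np.all(np.diff(cls) > 0)

    def test_nonpositive_covariates_rejected(self, model):
        with pytest.raises(ValueError):
            CovariateSet(wt=-5.0, pma=30.0)
        cov = CovariateSet(wt=1000.0, pma=30.0)
        object.__setattr__(cov, "pma", -1.0)
        with pytest.raises(ValueError):
            typical_cl(cov, model)


class TestIndividualParameters:
    def test_zero_etas_give_typical_values(self, model, reference_covariates):
        ind = individual_params(reference_covariates, model, 0.0, 0.0)
        assert ind.cl == typical_cl(reference_covariates, model)
        assert ind.v == typical_v(reference_covariates, model)

    def test_exponential_link(self, model, reference_covariates):
        ind = individual_params(reference_covariates, model, np.log(2.0), 0.0)
        assert ind.cl == pytest.approx(
            2 * typical_cl(reference_covariates, model), rel=1e-12
        )

    def test_bsv_variance_reproduced_in_monte_carlo(
        self, model, reference_covariates, rng
    ):
        etas = rng.normal(0.0, np.sqrt(model.omega2_cl), size=100_000)
        tcl = typical_cl(reference_covariates, model)
        cls = np.array(
            [individual_params(reference_covariates, model, e).cl for e in etas[:500]]
        )
        # exact identity on the sampled subset, variance on the full draw
        assert np.allclose(np.log(cls / tcl), etas[:500])
        assert np.var(etas) == pytest.approx(0.0188, rel=0.05)


class TestConcentration:
    def test_no_doses_is_zero(self, model, reference_covariates):
        ind = individual_params(reference_covariates, model)
        assert concentration(ind, [], 5.0, model) == 0.0

    def test_zero_before_first_dose(self, model, reference_covariates):
        ind = individual_params(reference_covariates, model)
        doses = [DoseEvent(time=10.0, amount=11.0, route="IV", duration=0.5)]
        assert concentration(ind, doses, 9.9, model) == 0.0

    def test_steady_state_trough_matches_accumulation_formula(self, model):
        cov = CovariateSet(wt=1500.0, pma=34.0)
        ind = individual_params(cov, model)
        k = ind.k
        tau, dur, amt = 24.0, 0.5, 16.5
        doses = [
            DoseEvent(time=i * tau, amount=amt, route="IV", duration=dur)
            for i in range(200)
        ]
        t = 199 * tau  # trough immediately before the 200th dose
        rate = amt / dur
        expected = (
            (rate / ind.cl)
            * (1 - np.exp(-k * dur))
            * np.exp(-k * (tau - dur))
            / (1 - np.exp(-k * tau))
        )
        assert concentration(ind, doses, t - 1e-12, model) == pytest.approx(
            expected, rel=1e-9
        )

    def test_matches_ode_integration_on_random_histories(self, model, rng):
        """Closed-form superposition against an independent ODE solve."""
        for _ in range(100):
            wt = rng.uniform(600, 3500)
            cov = CovariateSet(wt=wt, pma=rng.uniform(26, 55))
            ind = individual_params(
                cov, model, rng.normal(0, 0.2), rng.normal(0, 0.2)
            )
            n_doses = rng.integers(1, 6)
            t0 = 0.0
            doses = []
            for _ in range(n_doses):
                route = "IV" if rng.random() < 0.5 else "IM"
                doses.append(
                    DoseEvent(
                        time=t0,
                        amount=rng.uniform(5, 40),
                        route=route,
                        duration=rng.uniform(0.25, 1.0) if route == "IV" else 0.0,
                    )
                )
                t0 += rng.uniform(6, 48)
            times = np.sort(rng.uniform(0.1, t0 + 24, size=4))
            got = concentration(ind, doses, times, model)
            want = ode_concentration(ind, doses, times)
            assert np.allclose(got, want, rtol=1e-6, atol=1e-10)

    def test_linear_in_dose_and_shift_invariant(self, model):
        cov = CovariateSet(wt=900.0, pma=28.0)
        ind = individual_params(cov, model)
        doses = [
            DoseEvent(time=0.0, amount=10.0, route="IV", duration=0.5),
            DoseEvent(time=36.0, amount=10.0, route="IM", duration=0.0),
        ]
        t = np.array([1.0, 12.0, 37.0, 50.0])
        base = concentration(ind, doses, t, model)
        doubled = [
            DoseEvent(time=d.time, amount=2 * d.amount, route=d.route,
                      duration=d.duration)
            for d in doses
        ]
        assert np.allclose(concentration(ind, doubled, t, model), 2 * base)
        shifted = [
            DoseEvent(time=d.time + 7.0, amount=d.amount, route=d.route,
                      duration=d.duration)
            for d in doses
        ]
        assert np.allclose(concentration(ind, shifted, t + 7.0, model), base)

    def test_strictly_decreasing_between_doses(self, model):
        cov = CovariateSet(wt=1200.0, pma=31.0)
        ind = individual_params(cov, model)
        doses = [DoseEvent(time=0.0, amount=13.0, route="IV", duration=0.5)]
        t = np.linspace(0.6, 24.0, 200)
        c = concentration(ind, doses, t, model)
        assert np.all(np.diff(c) < 0)

    def test_im_first_order_absorption_and_limit(self, model):
        cov = CovariateSet(wt=1000.0, pma=30.0)
        ind = individual_params(cov, model)
        doses = [DoseEvent(time=0.0, amount=11.0, route="IM", duration=0.0)]
        times = np.array([0.5, 1.5, 4.0, 12.0])
        m_ka = model.replace(ka_im=1.2, f_im=0.9)
        got = concentration(ind, doses, times, m_ka)
        want = ode_concentration(ind, doses, times, f_im=0.9, ka_im=1.2)
        assert np.allclose(got, want, rtol=1e-6)
        # ka -> k limiting form stays finite and continuous
        k = ind.k
        m_lim = model.replace(ka_im=k)
        m_near = model.replace(ka_im=k * (1 + 1e-9))
        assert concentration(ind, doses, 4.0, m_lim) == pytest.approx(
            concentration(ind, doses, 4.0, m_near), rel=1e-5
        )

    def test_invalid_elimination_rejected(self, model):
        with pytest.raises(ValueError):
            IndividualParameters(cl=-1.0, v=0.5)


class TestResidualError:
    def test_noiseless_limit_is_identity(self, model):
        pred = np.array([0.0, 1.0, 20.0])
        y = apply_residual_error(pred, model, (np.zeros(3), np.zeros(3)))
        assert np.array_equal(y, pred)

    def test_zero_prediction_leaves_additive_noise_only(self, model):
        y = apply_residual_error(0.0, model, (0.77, 0.31))
        assert y == pytest.approx(0.31)

    def test_variance_composition(self, rng):
        m = final_model().replace(sigma_prop=0.2, sigma_add=0.5)
        n = 100_000
        pred = np.full(n, 20.0)
        y = apply_residual_error(
            pred, m, (rng.normal(0, 0.2, n), rng.normal(0, 0.5, n))
        )
        assert y.std() == pytest.approx(np.sqrt((20 * 0.2) ** 2 + 0.5**2), rel=0.02)

    def test_negative_draws_truncated_to_zero(self, model):
        y = apply_residual_error(np.array([1.0]), model, (np.array([-2.0]), np.array([0.0])))
        assert y[0] == 0.0


class TestSerialisation:
    def test_final_model_round_trips_through_dict(self, model):
        assert model_from_dict(model_to_dict(model)) == model

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            PopulationModel(theta_cl=-1.0, theta_v=0.5)
        with pytest.raises(ValueError):
            PopulationModel(theta_cl=0.05, theta_v=0.5, f_im=1.5)
        with pytest.raises(ValueError):
            DoseEvent(time=0.0, amount=11.0, route="IV", duration=0.0)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    wt=st.floats(min_value=400.0, max_value=4500.0),
    pma=st.floats(min_value=24.0, max_value=80.0),
)
def test_typical_values_positive_and_finite(wt, pma):
    m = final_model()
    cov = CovariateSet(wt=wt, pma=pma)
    assert 0 < typical_cl(cov, m) < 10
    assert 0 < typical_v(cov, m) < 20
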