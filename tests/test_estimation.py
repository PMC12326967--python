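"""Laplace objective, population fitting, EBEs, stepwise selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from amikapk import (
    CohortSpec,
    CovariateCandidate,
    Dataset,
    concentration,
    empirical_bayes,
    fit_population,
    individual_params,
    objective_function,
    simulate_dataset,
    stepwise_selection,
    typical_cl,
    typical_v,
)
from amikapk.estimation import FitResult

from conftest import make_dataset, make_subject


class TestObjectiveFunction:
    def test_matches_exact_gaussian_without_random_effects(self, model):
        m = model.replace(omega2_cl=0.0, sigma_prop=0.1, sigma_add=0.3)
        sub = make_subject(obs_times=(1.0,), obs_values=(20.0,))
        ind = individual_params(sub.covariates, m)
        pred = concentration(ind, sub.doses, 1.0, m)
        sig2 = (0.1 * pred) ** 2 + 0.3**2
        exact = -2 * stats.norm.logpdf(20.0, pred, np.sqrt(sig2))
        assert objective_function(make_dataset([sub]), m) == pytest.approx(
            exact, rel=1e-10
        )

    def test_matches_adaptive_quadrature_with_one_random_effect(self, model):
        """Laplace approximation against the exact 1-D marginal integral."""
        m = model.replace(sigma_prop=0.1, sigma_add=0.3)
        for obs_val in (12.0, 20.0, 28.0):
            sub = make_subject(obs_times=(1.0,), obs_values=(obs_val,))

            def integrand(eta):
                ind = individual_params(sub.covariates, m, eta_cl=eta)
                p = concentration(ind, sub.doses, 1.0, m)
                s2 = (0.1 * p) ** 2 + 0.3**2
                return stats.norm.pdf(obs_val, p, np.sqrt(s2)) * stats.norm.pdf(
                    eta, 0, np.sqrt(m.omega2_cl)
                )

            L, _ = integrate.quad(integrand, -2.0, 2.0, epsabs=1e-14, epsrel=1e-12)
            exact = -2 * np.log(L)
            assert objective_function(make_dataset([sub]), m) == pytest.approx(
                exact, rel=1e-3
            )

    def test_matches_double_quadrature_with_two_random_effects(self, model):
        m = model.replace(omega2_v=0.01, sigma_prop=0.1, sigma_add=0.3)
        sub = make_subject(obs_times=(1.0,), obs_values=(20.0,))

        def integrand(ev, ec):
            ind = individual_params(sub.covariates, m, eta_cl=ec, eta_v=ev)
            p = concentration(ind, sub.doses, 1.0, m)
            s2 = (0.1 * p) ** 2 + 0.3**2
            return (
                stats.norm.pdf(20.0, p, np.sqrt(s2))
                * stats.norm.pdf(ec, 0, np.sqrt(m.omega2_cl))
                * stats.norm.pdf(ev, 0, np.sqrt(m.omega2_v))
            )

        L, _ = integrate.dblquad(integrand, -1, 1, -1, 1, epsabs=1e-12)
        got = objective_function(make_dataset([sub]), m)
        assert got == pytest.approx(-2 * np.log(L), rel=1e-3)

    def test_additive_over_subjects(self, model):
        m = model.replace(sigma_prop=0.1, sigma_add=0.3)
        sub1 = make_subject(sid="A")
        sub2 = make_subject(sid="B")
        one = objective_function(make_dataset([sub1]), m)
        two = objective_function(make_dataset([sub1, sub2]), m)
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_degenerate_error_model_raises(self, model):
        m = model.replace(omega2_cl=0.0, sigma_prop=0.0, sigma_add=0.0)
        from amikapk.estimation import NumericalLikelihoodError

        with pytest.raises(NumericalLikelihoodError):
            objective_function(make_dataset([make_subject()]), m)


class TestFitPopulation:
    def test_noiseless_truth_is_a_fixed_point(self, model):
        quiet = model.replace(sigma_prop=0.0, sigma_add=1e-4, omega2_cl=1e-6)
        ds = simulate_dataset(
            CohortSpec(n_subjects=40, seed=5),
            model.replace(sigma_prop=0.0, sigma_add=0.0, omega2_cl=0.0),
        )
        fit = fit_population(ds, quiet, init=quiet, maxiter=5, compute_se=False)
        # starting at the generating values, estimates stay there
        assert fit.estimates.theta_cl == pytest.approx(quiet.theta_cl, rel=0.02)
        assert fit.estimates.exp_wt_cl == pytest.approx(quiet.exp_wt_cl, abs=0.05)

    def test_recovers_generating_parameters(self, model):
        ds = simulate_dataset(CohortSpec(n_subjects=200, seed=1), model)
        fit = fit_population(ds, model)
        assert fit.converged
        p = fit.params()
        assert p["exp_wt_cl"] == pytest.approx(0.919, rel=0.15)
        assert p["exp_pma_cl"] == pytest.approx(1.53, rel=0.15)
        assert p["exp_wt_v"] == pytest.approx(0.851, rel=0.15)
        assert p["theta_cl"] == pytest.approx(0.0487, rel=0.15)
        ses = fit.standard_errors
        assert all(np.isfinite(ses[k]) and ses[k] >= 0 for k in p)

    def test_warns_on_small_cohort(self, model):
        ds = simulate_dataset(CohortSpec(n_subjects=5, seed=2), model)
        with pytest.warns(UserWarning, match="subjects"):
            fit_population(ds, model, maxiter=3, compute_se=False)

    def test_subject_without_observations_rejected(self, model, small_dataset):
        from amikapk.dataset import SubjectRecord

        bare = SubjectRecord(
            id="EMPTY", covariates=small_dataset[0].covariates,
            doses=list(small_dataset[0].doses), observations=[],
        )
        ds = Dataset(list(small_dataset.subjects) + [bare])
        with pytest.raises(ValueError):
            fit_population(ds, model)


class TestEmpiricalBayes:
    def test_no_observations_gives_prior_mode(self, model, small_dataset):
        from amikapk.dataset import SubjectRecord

        bare = SubjectRecord(
            id="X", covariates=small_dataset[0].covariates,
            doses=list(small_dataset[0].doses), observations=[],
        )
        assert empirical_bayes(bare, model) == {"eta_cl": 0.0, "eta_v": 0.0}

    def test_vanishing_noise_interpolates_the_observation(self, model):
        m = model.replace(sigma_prop=0.0, sigma_add=1e-6)
        sub = make_subject(obs_times=(2.0,), obs_values=(15.0,))
        eta = empirical_bayes(sub, m)["eta_cl"]
        ind = individual_params(sub.covariates, m, eta_cl=eta)
        assert concentration(ind, sub.doses, 2.0, m) == pytest.approx(15.0, rel=1e-3)

    def test_ebes_track_true_etas(self, model):
        # BSV is small (omega^2 = 0.0188) so shrinkage is heavy at sparse
        # sampling; correlation strengthens as sampling gets richer
        sparse = simulate_dataset(CohortSpec(n_subjects=150, seed=4), model)
        rich = simulate_dataset(
            CohortSpec(n_subjects=150, seed=4, n_random_obs=3), model
        )
        corr = {}
        for name, ds in (("sparse", sparse), ("rich", rich)):
            est = [empirical_bayes(s, model)["eta_cl"] for s in ds]
            true = [s.true_params.eta_cl for s in ds]
            corr[name] = np.corrcoef(est, true)[0, 1]
        assert corr["sparse"] > 0.5
        assert corr["rich"] > 0.7
        assert corr["rich"] > corr["sparse"]

    def test_shrinkage_grows_as_data_vanish(self, model):
        rich = simulate_dataset(
            CohortSpec(n_subjects=80, seed=6, n_random_obs=3), model
        )
        poor = Dataset(
            [
                type(s)(
                    id=s.id, covariates=s.covariates, doses=list(s.doses),
                    observations=[s.observations[0]], true_params=s.true_params,
                )
                for s in rich
            ]
        )
        mean_rich = np.mean([abs(empirical_bayes(s, model)["eta_cl"]) for s in rich])
        mean_poor = np.mean([abs(empirical_bayes(s, model)["eta_cl"]) for s in poor])
        assert mean_poor < mean_rich


class _StubFit:
    """Deterministic OFV table standing in for the inner fitter."""

    def __init__(self, table):
        self.table = table

    def __call__(self, dataset, template):
        key = (
            tuple(t.covariate for t in template.extra_cl_terms),
            tuple(t.covariate for t in template.extra_v_terms),
        )
        ofv = self.table[key]
        return FitResult(
            estimates=template, ofv=ofv, standard_errors={},
            ebes=pd.DataFrame(), converged=True, n_function_evals=1,
            n_iterations=1,
        )


class TestStepwiseSelection:
    def test_empty_candidate_list_returns_base(self, model, small_dataset):
        base = model.replace(exp_wt_cl=None, exp_pma_cl=None, exp_wt_v=None)
        sel = stepwise_selection(
            small_dataset, base, [],
            fit_fn=lambda ds, t: fit_population(ds, t, compute_se=False, maxiter=20),
        )
        assert sel.included == []
        assert sel.trace.empty

    def test_boundary_drop_exactly_at_threshold_not_added(self):
        cands = [CovariateCandidate("CL", "WT")]
        stub = _StubFit({((), ()): 100.0, (("WT",), ()): 100.0 - 3.84})
        sel = stepwise_selection(None, _base_model(), cands, fit_fn=stub)
        assert sel.included == []

    def test_drop_just_above_threshold_added_and_survives_backward(self):
        cands = [CovariateCandidate("CL", "WT")]
        stub = _StubFit({((), ()): 100.0, (("WT",), ()): 100.0 - 12.0})
        sel = stepwise_selection(None, _base_model(), cands, fit_fn=stub)
        assert [c.covariate for c in sel.included] == ["WT"]

    def test_forward_keeps_but_backward_removes_marginal_covariate(self):
        # drops 5 in forward (>3.84) but removal costs only 5 (<=10.83)
        cands = [CovariateCandidate("CL", "SCR")]
        stub = _StubFit({((), ()): 100.0, (("SCR",), ()): 95.0})
        sel = stepwise_selection(None, _base_model(), cands, fit_fn=stub)
        assert sel.included == []
        assert (sel.trace["action"] == "removed").any()

    def test_recovers_planted_weight_effect_and_rejects_null_scr(self, model):
        truth = model.replace(exp_pma_cl=None, exp_wt_v=None)
        ds = simulate_dataset(CohortSpec(n_subjects=120, seed=8), truth)
        base = model.replace(exp_wt_cl=None, exp_pma_cl=None, exp_wt_v=None)
        sel = stepwise_selection(
            ds, base,
            [CovariateCandidate("CL", "WT"), CovariateCandidate("CL", "SCR")],
            fit_fn=lambda d, t: fit_population(d, t, compute_se=False),
        )
        assert [c.covariate for c in sel.included] == ["WT"]
        trace = sel.trace
        assert set(trace.columns) >= {"stage", "candidate", "delta_ofv", "action"}


def _base_model():
    from amikapk import final_model

    return final_model().replace(
        exp_wt_cl=None, exp_pma_cl=None, exp_wt_v=None
    )
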