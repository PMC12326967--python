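"""Nonlinear mixed-effects estimation and stepwise covariate selection.

The marginal likelihood of each subject's observations is approximated
by the Laplace method with interaction: the per-subject random effects
``eta`` are profiled by an inner Newton maximisation of the joint
log-density (with the residual variance evaluated at the conditional
prediction), and the curvature at the mode supplies the Gaussian
integral correction.  The reported objective function value (OFV) is
-2 times the approximate marginal log-likelihood, including all 2*pi
constants, so that with no random effects it reduces exactly to the
Gaussian -2 log-likelihood.

The outer maximisation runs L-BFGS-B on transformed parameters
(log for positivity-constrained thetas, variances and error SDs;
untransformed covariate exponents).  Standard errors come from the
finite-difference Hessian of the OFV at the optimum (cov = 2 H^-1),
delta-transformed back to the natural scale.

Covariate model building follows a stepwise procedure: forward
addition accepts the candidate with the largest OFV drop while the
drop strictly exceeds 3.84 (chi-square, p < 0.05, df = 1); backward
elimination then removes covariates whose deletion raises the OFV by
10.83 or less (retention requires an increase strictly above 10.83,
p < 0.001).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize

from .dataset import Dataset, SubjectRecord
from .engine import PackedDesign
from .model import COVARIATE_REFERENCES, CovariateTerm, PopulationModel

__all__ = [
    "FitResult",
    "CovariateCandidate",
    "SelectionResult",
    "objective_function",
    "fit_population",
    "empirical_bayes",
    "stepwise_selection",
]

logger = logging.getLogger(__name__)

_LOG2PI = math.log(2.0 * math.pi)
_VAR_FLOOR = 1e-12
_ETA_STEP = 1e-4  # finite-difference step for the inner Newton solver
_INNER_TOL = 1e-9
_INNER_MAXIT = 60

FORWARD_DELTA_OFV = 3.84
BACKWARD_DELTA_OFV = 10.83


class NumericalLikelihoodError(RuntimeError):
    """The likelihood is not finite under the requested configuration."""


# ---------------------------------------------------------------------------
# parameter layout


@dataclass(frozen=True)
class _Entry:
    name: str
    path: tuple  # ('field', attr) | ('cl_term'|'v_term', index, attr)
    log: bool


def _term_entries(side: str, terms) -> List[_Entry]:
    out = []
    for i, t in enumerate(terms):
        if t.form == "power":
            out.append(_Entry(f"{side}_{t.covariate}_{t.form}_exp", (f"{side}_term", i, "exponent"), False))
        elif t.form == "sigmoid_emax":
            out.append(_Entry(f"{side}_{t.covariate}_emax_gamma", (f"{side}_term", i, "gamma"), True))
            out.append(_Entry(f"{side}_{t.covariate}_emax_tm50", (f"{side}_term", i, "tm50"), True))
        # allometric: exponent fixed, nothing estimated
    return out


class ParameterLayout:
    """Maps a population-model template onto a flat optimisation vector.

    A named exponent is estimated when it is present (not None); a
    variance or error SD is estimated when its template value is
    strictly positive (zero means structurally absent and fixed).
    """

    def __init__(self, template: PopulationModel):
        entries = [
            _Entry("theta_cl", ("field", "theta_cl"), True),
            _Entry("theta_v", ("field", "theta_v"), True),
        ]
        for attr in ("exp_wt_cl", "exp_pma_cl", "exp_wt_v"):
            if getattr(template, attr) is not None:
                entries.append(_Entry(attr, ("field", attr), False))
        entries += _term_entries("cl", template.extra_cl_terms)
        entries += _term_entries("v", template.extra_v_terms)
        for attr in ("omega2_cl", "omega2_v", "sigma_prop", "sigma_add"):
            if getattr(template, attr) > 0:
                entries.append(_Entry(attr, ("field", attr), True))
        self.entries = entries
        self.template = template

    @property
    def names(self) -> List[str]:
        return [e.name for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def _get(self, model: PopulationModel, path) -> float:
        if path[0] == "field":
            return getattr(model, path[1])
        terms = model.extra_cl_terms if path[0] == "cl_term" else model.extra_v_terms
        return getattr(terms[path[1]], path[2])

    def pack(self, model: PopulationModel) -> np.ndarray:
        x = np.empty(len(self.entries))
        for i, e in enumerate(self.entries):
            v = self._get(model, e.path)
            x[i] = math.log(v) if e.log else v
        return x

    def unpack(self, x: np.ndarray) -> PopulationModel:
        fields: Dict[str, float] = {}
        cl_terms = {}
        v_terms = {}
        for e, xi in zip(self.entries, x):
            v = math.exp(xi) if e.log else float(xi)
            if e.path[0] == "field":
                fields[e.path[1]] = v
            elif e.path[0] == "cl_term":
                cl_terms.setdefault(e.path[1], {})[e.path[2]] = v
            else:
                v_terms.setdefault(e.path[1], {})[e.path[2]] = v
        model = self.template
        if cl_terms:
            fields["extra_cl_terms"] = tuple(
                replace(t, **cl_terms.get(i, {}))
                for i, t in enumerate(model.extra_cl_terms)
            )
        if v_terms:
            fields["extra_v_terms"] = tuple(
                replace(t, **v_terms.get(i, {}))
                for i, t in enumerate(model.extra_v_terms)
            )
        return model.replace(**fields)


# ---------------------------------------------------------------------------
# Laplace objective


class _LaplaceObjective:
    """OFV evaluator over a packed design with warm-started inner modes."""

    def __init__(self, design: PackedDesign, template: PopulationModel):
        self.design = design
        self.use_eta_cl = template.omega2_cl > 0
        self.use_eta_v = template.omega2_v > 0
        self.n_eta = int(self.use_eta_cl) + int(self.use_eta_v)
        S = design.n_subjects
        self.eta_warm = np.zeros((S, max(self.n_eta, 1)))

    # -- residual pieces ----------------------------------------------------

    def _data_terms(self, model, pred):
        """Masked per-subject sums of ln sigma^2 + r^2/sigma^2."""
        d = self.design
        sig2 = np.maximum(
            (model.sigma_prop * pred) ** 2 + model.sigma_add**2, _VAR_FLOOR
        )
        r = d.y - pred
        contrib = np.log(sig2) + (r * r) / sig2
        return np.sum(np.where(d.obs_mask, contrib, 0.0), axis=-1)

    def _q(self, model, tcl, tv, eta):
        """Joint -2 log density (up to 2*pi constants), per subject."""
        e_cl = eta[:, 0] if self.use_eta_cl else 0.0
        e_v = eta[:, 1] if (self.use_eta_cl and self.use_eta_v) else (
            eta[:, 0] if self.use_eta_v else 0.0
        )
        pred = self.design.pred(
            tcl * np.exp(e_cl), tv * np.exp(e_v), model.f_im, model.ka_im
        )
        q = self._data_terms(model, pred)
        if self.use_eta_cl:
            q = q + np.asarray(e_cl) ** 2 / model.omega2_cl
        if self.use_eta_v:
            q = q + np.asarray(e_v) ** 2 / model.omega2_v
        return q

    # -- inner Newton -------------------------------------------------------

    def _newton(self, model, tcl, tv, eta0):
        """Vectorised Newton minimisation of q over per-subject etas.

        Returns (eta_hat, q_hat, log-det of half the q-Hessian)."""
        d = self.n_eta
        eta = eta0.copy()
        h = _ETA_STEP
        qfun = lambda e: self._q(model, tcl, tv, e)
        q0 = qfun(eta)
        for _ in range(_INNER_MAXIT):
            if d == 1:
                ep = eta + h
                em = eta - h
                qp = qfun(ep)
                qm = qfun(em)
                g = (qp - qm) / (2 * h)
                H = (qp - 2 * q0 + qm) / h**2
                H = np.where(H > _VAR_FLOOR, H, np.abs(H) + 1.0)
                step = (-g / H)[:, None]
            else:
                offs = np.array(
                    [[h, 0], [-h, 0], [0, h], [0, -h], [h, h], [h, -h], [-h, h], [-h, -h]]
                )
                qs = [qfun(eta + o) for o in offs]
                gx = (qs[0] - qs[1]) / (2 * h)
                gy = (qs[2] - qs[3]) / (2 * h)
                hxx = (qs[0] - 2 * q0 + qs[1]) / h**2
                hyy = (qs[2] - 2 * q0 + qs[3]) / h**2
                hxy = (qs[4] - qs[5] - qs[6] + qs[7]) / (4 * h**2)
                det = hxx * hyy - hxy * hxy
                bad = (det <= _VAR_FLOOR) | (hxx <= 0)
                reg = np.where(bad, np.abs(hxx) + np.abs(hyy) + 1.0, 0.0)
                hxx = hxx + reg
                hyy = hyy + reg
                det = hxx * hyy - hxy * hxy
                step = np.stack(
                    [-(hyy * gx - hxy * gy) / det, -(hxx * gy - hxy * gx) / det],
                    axis=1,
                )
            np.clip(step, -2.0, 2.0, out=step)
            # backtrack subjects whose step increases q
            for _bt in range(12):
                q_new = qfun(eta + step)
                worse = q_new > q0 + 1e-12
                if not np.any(worse):
                    break
                step[worse] *= 0.5
            moved = np.max(np.abs(step), axis=1)
            eta = eta + step
            q0 = qfun(eta)
            if np.max(moved) < _INNER_TOL:
                break
        # curvature at the mode for the Laplace correction
        if d == 1:
            qp = qfun(eta + h)
            qm = qfun(eta - h)
            H = np.maximum((qp - 2 * q0 + qm) / h**2, _VAR_FLOOR)
            logdet_half = np.log(H / 2.0)
        else:
            offs = np.array(
                [[h, 0], [-h, 0], [0, h], [0, -h], [h, h], [h, -h], [-h, h], [-h, -h]]
            )
            qs = [qfun(eta + o) for o in offs]
            hxx = (qs[0] - 2 * q0 + qs[1]) / h**2
            hyy = (qs[2] - 2 * q0 + qs[3]) / h**2
            hxy = (qs[4] - qs[5] - qs[6] + qs[7]) / (4 * h**2)
            det = np.maximum(hxx * hyy - hxy * hxy, _VAR_FLOOR**2)
            logdet_half = np.log(det / 4.0)
        return eta, q0, logdet_half

    # -- OFV ----------------------------------------------------------------

    def ofv(self, model: PopulationModel, warm: bool = True) -> float:
        d = self.design
        tcl, tv = d.typical_params(model)
        if self.n_eta == 0:
            if model.sigma_prop <= 0 and model.sigma_add <= 0:
                raise NumericalLikelihoodError(
                    "no residual-error variance: likelihood is degenerate"
                )
            pred = d.pred(tcl, tv, model.f_im, model.ka_im)
            per_subject = self._data_terms(model, pred) + d.n_obs * _LOG2PI
            total = float(np.sum(per_subject))
        else:
            eta0 = self.eta_warm if warm else np.zeros_like(self.eta_warm)
            eta, q_hat, logdet_half = self._newton(model, tcl, tv, eta0)
            if warm:
                self.eta_warm = eta
            logdet_omega = 0.0
            if self.use_eta_cl:
                logdet_omega += math.log(model.omega2_cl)
            if self.use_eta_v:
                logdet_omega += math.log(model.omega2_v)
            total = float(
                np.sum(q_hat + d.n_obs * _LOG2PI + logdet_omega + logdet_half)
            )
        if not np.isfinite(total):
            raise NumericalLikelihoodError(
                "non-finite objective; check error-model variances and data"
            )
        return total

    def ebes(self, model: PopulationModel) -> np.ndarray:
        """Converged random-effect modes, shape (S, 2) as (eta_cl, eta_v)."""
        out = np.zeros((self.design.n_subjects, 2))
        if self.n_eta == 0:
            return out
        tcl, tv = self.design.typical_params(model)
        eta, _, _ = self._newton(model, tcl, tv, np.zeros_like(self.eta_warm))
        if self.use_eta_cl:
            out[:, 0] = eta[:, 0]
            if self.use_eta_v:
                out[:, 1] = eta[:, 1]
        else:
            out[:, 1] = eta[:, 0]
        # subjects with no observations sit at the prior mode
        out[self.design.n_obs == 0] = 0.0
        return out


def objective_function(dataset: Dataset, model: PopulationModel) -> float:
    """-2 log approximate marginal likelihood of the dataset (deterministic;
    inner modes are solved from a cold start)."""
    obj = _LaplaceObjective(PackedDesign(dataset), model)
    return obj.ofv(model, warm=False)


# ---------------------------------------------------------------------------
# population fit


@dataclass
class FitResult:
    estimates: PopulationModel
    ofv: float
    standard_errors: Dict[str, float]
    ebes: pd.DataFrame
    converged: bool
    n_function_evals: int
    n_iterations: int
    message: str = ""
    parameter_names: List[str] = field(default_factory=list)

    def params(self) -> Dict[str, float]:
        """Estimated parameters on the natural scale, keyed by layout name."""
        layout = ParameterLayout(self.estimates)
        x = layout.pack(self.estimates)
        return {
            e.name: (math.exp(xi) if e.log else float(xi))
            for e, xi in zip(layout.entries, x)
        }

    def summary(self) -> pd.DataFrame:
        p = self.params()
        return pd.DataFrame(
            {
                "estimate": pd.Series(p),
                "se": pd.Series(self.standard_errors),
            }
        )


_DEFAULT_INITS = {
    "theta_cl": 0.1,
    "theta_v": 0.5,
    "exp_wt_cl": 0.75,
    "exp_pma_cl": 1.0,
    "exp_wt_v": 1.0,
    "omega2_cl": 0.05,
    "omega2_v": 0.05,
    "sigma_prop": 0.2,
    "sigma_add": 0.3,
}


def _default_init(template: PopulationModel) -> PopulationModel:
    kw = {
        k: v
        for k, v in _DEFAULT_INITS.items()
        if getattr(template, k) is not None and (k.startswith(("theta", "exp")) or getattr(template, k) > 0)
    }
    return template.replace(**kw)


def fit_population(
    dataset: Dataset,
    template: PopulationModel,
    init: Optional[PopulationModel] = None,
    *,
    compute_se: bool = True,
    maxiter: int = 500,
    gtol: float = 1e-6,
    ftol: float = 1e-11,
    fd_step: float = 1e-6,
) -> FitResult:
    """Maximise the Laplace-approximate marginal likelihood.

    ``template`` defines the structure (which effects exist, which
    variances are estimated); ``init`` optionally supplies starting
    values (defaults to generic neonatal aminoglycoside inits).
    """
    if any(s.n_obs == 0 for s in dataset):
        raise ValueError("every subject must carry at least one observation")
    if len(dataset) < 30:
        warnings.warn(
            f"only {len(dataset)} subjects; population parameters may be "
            "poorly identified",
            stacklevel=2,
        )
    design = PackedDesign(dataset)
    layout = ParameterLayout(template)
    obj = _LaplaceObjective(design, template)
    x0 = layout.pack(init if init is not None else _default_init(template))

    def fun(x):
        try:
            return obj.ofv(layout.unpack(x))
        except NumericalLikelihoodError:
            return 1e10

    res = optimize.minimize(
        fun,
        x0,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "gtol": gtol, "ftol": ftol, "eps": fd_step},
    )
    estimates = layout.unpack(res.x)
    ofv = obj.ofv(estimates, warm=False)

    ses: Dict[str, float] = {}
    if compute_se:
        ses = _standard_errors(fun, res.x, layout)

    eta = obj.ebes(estimates)
    ebes = pd.DataFrame(
        {"id": design.ids, "eta_cl": eta[:, 0], "eta_v": eta[:, 1]}
    ).set_index("id")

    converged = bool(res.success and np.isfinite(ofv))
    if not converged:
        logger.warning("fit did not converge: %s", res.message)
    return FitResult(
        estimates=estimates,
        ofv=float(ofv),
        standard_errors=ses,
        ebes=ebes,
        converged=converged,
        n_function_evals=int(res.nfev),
        n_iterations=int(res.nit),
        message=str(res.message),
        parameter_names=layout.names,
    )


def _standard_errors(fun, xhat, layout: ParameterLayout) -> Dict[str, float]:
    """Delta-method SEs from the central finite-difference OFV Hessian."""
    p = len(xhat)
    h = 1e-4 * np.maximum(np.abs(xhat), 1.0)
    H = np.empty((p, p))
    f0 = fun(xhat)
    fp = np.empty(p)
    fm = np.empty(p)
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = h[i]
        fp[i] = fun(xhat + ei)
        fm[i] = fun(xhat - ei)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
    for i in range(p):
        for j in range(i + 1, p):
            ei = np.zeros(p)
            ei[i] = h[i]
            ej = np.zeros(p)
            ej[j] = h[j]
            fpp = fun(xhat + ei + ej)
            H[i, j] = H[j, i] = (
                fpp - fp[i] - fp[j] + f0
            ) / (h[i] * h[j])
    ses: Dict[str, float] = {}
    try:
        cov = 2.0 * np.linalg.pinv(H)
        var = np.diag(cov)
    except np.linalg.LinAlgError:
        var = np.full(p, np.nan)
    for e, xi, vi in zip(layout.entries, xhat, var):
        se_t = math.sqrt(vi) if vi > 0 else float("nan")
        ses[e.name] = se_t * math.exp(xi) if e.log else se_t
    return ses


def empirical_bayes(
    subject: SubjectRecord, model: PopulationModel
) -> Dict[str, float]:
    """MAP random-effect estimates for one subject under a fitted model.

    With no observations the posterior mode is the prior mode (zero);
    estimates shrink toward zero as data become sparse or noisy.
    """
    if subject.n_obs == 0:
        return {"eta_cl": 0.0, "eta_v": 0.0}
    obj = _LaplaceObjective(PackedDesign(Dataset([subject])), model)
    eta = obj.ebes(model)
    return {"eta_cl": float(eta[0, 0]), "eta_v": float(eta[0, 1])}


# ---------------------------------------------------------------------------
# stepwise covariate selection


@dataclass(frozen=True)
class CovariateCandidate:
    """A candidate covariate effect for model building.

    ``form`` is 'power' (estimated exponent), 'allometric' (theory-fixed
    exponent: 0.75 on CL, 1.0 on V) or 'sigmoid_emax' (PMA on CL only).
    """

    target: str  # CL | V
    covariate: str  # WT | GA | PMA | PNA | SCR
    form: str = "power"
    reference: Optional[float] = None

    def __post_init__(self) -> None:
        if self.target not in ("CL", "V"):
            raise ValueError(f"unknown target {self.target!r}")
        if self.form == "sigmoid_emax" and not (
            self.target == "CL" and self.covariate == "PMA"
        ):
            raise ValueError("sigmoid_emax maturation applies to PMA on CL only")

    def term(self) -> CovariateTerm:
        ref = self.reference
        if ref is None:
            ref = COVARIATE_REFERENCES[self.covariate]
        if self.form == "allometric":
            exp0 = 0.75 if self.target == "CL" else 1.0
        else:
            exp0 = 0.0
        return CovariateTerm(
            covariate=self.covariate, form=self.form, reference=ref, exponent=exp0
        )

    def label(self) -> str:
        return f"{self.covariate}~{self.target}({self.form})"


def _with_candidates(
    base: PopulationModel, cands: Sequence[CovariateCandidate]
) -> PopulationModel:
    cl_terms = list(base.extra_cl_terms)
    v_terms = list(base.extra_v_terms)
    for c in cands:
        (cl_terms if c.target == "CL" else v_terms).append(c.term())
    return base.replace(extra_cl_terms=tuple(cl_terms), extra_v_terms=tuple(v_terms))


@dataclass
class SelectionResult:
    final: FitResult
    included: List[CovariateCandidate]
    trace: pd.DataFrame


def stepwise_selection(
    dataset: Dataset,
    base: PopulationModel,
    candidates: Sequence[CovariateCandidate],
    fit_fn: Optional[Callable[[Dataset, PopulationModel], FitResult]] = None,
    forward_threshold: float = FORWARD_DELTA_OFV,
    backward_threshold: float = BACKWARD_DELTA_OFV,
) -> SelectionResult:
    """Forward-addition / backward-elimination covariate search.

    Both thresholds are strict inequalities; forward ties are broken by
    candidate order.  Candidate fits that fail to converge are skipped
    with a warning and recorded in the trace.
    """
    if fit_fn is None:
        fit_fn = lambda ds, tpl: fit_population(ds, tpl, compute_se=False)

    rows = []
    current_fit = fit_fn(dataset, base)
    ofv_current = current_fit.ofv
    included: List[CovariateCandidate] = []
    remaining = list(candidates)

    rnd = 0
    while remaining:
        rnd += 1
        best = None  # (delta, index, fit)
        for idx, cand in enumerate(remaining):
            fit = fit_fn(dataset, _with_candidates(base, included + [cand]))
            if not fit.converged:
                warnings.warn(f"candidate {cand.label()} did not converge; skipped")
                rows.append(
                    dict(stage="forward", round=rnd, candidate=cand.label(),
                         ofv_ref=ofv_current, ofv_fit=float("nan"),
                         delta_ofv=float("nan"), action="skipped"))
                continue
            delta = ofv_current - fit.ofv
            rows.append(
                dict(stage="forward", round=rnd, candidate=cand.label(),
                     ofv_ref=ofv_current, ofv_fit=fit.ofv, delta_ofv=delta,
                     action="tested"))
            if delta > forward_threshold and (best is None or delta > best[0]):
                best = (delta, idx, fit)
        if best is None:
            break
        delta, idx, fit = best
        cand = remaining.pop(idx)
        included.append(cand)
        current_fit = fit
        ofv_current = fit.ofv
        rows.append(
            dict(stage="forward", round=rnd, candidate=cand.label(),
                 ofv_ref=ofv_current + delta, ofv_fit=ofv_current,
                 delta_ofv=delta, action="added"))

    # backward elimination: drop, one at a time, the effect whose removal
    # costs the least, while that cost does not exceed the threshold
    changed = True
    while included and changed:
        changed = False
        increases = []
        for cand in included:
            others = [c for c in included if c is not cand]
            fit = fit_fn(dataset, _with_candidates(base, others))
            if not fit.converged:
                warnings.warn(
                    f"removal fit for {cand.label()} did not converge; retained")
                rows.append(
                    dict(stage="backward", round=rnd, candidate=cand.label(),
                         ofv_ref=ofv_current, ofv_fit=float("nan"),
                         delta_ofv=float("nan"), action="skipped"))
                continue
            inc = fit.ofv - ofv_current
            increases.append((inc, cand, fit))
            rows.append(
                dict(stage="backward", round=rnd, candidate=cand.label(),
                     ofv_ref=ofv_current, ofv_fit=fit.ofv, delta_ofv=inc,
                     action="tested"))
        removable = [t for t in increases if t[0] <= backward_threshold]
        if removable:
            inc, cand, fit = min(removable, key=lambda t: t[0])
            included.remove(cand)
            current_fit = fit
            ofv_current = fit.ofv
            rows.append(
                dict(stage="backward", round=rnd, candidate=cand.label(),
                     ofv_ref=ofv_current - inc, ofv_fit=ofv_current,
                     delta_ofv=inc, action="removed"))
            changed = True

    trace = pd.DataFrame(
        rows,
        columns=["stage", "round", "candidate", "ofv_ref", "ofv_fit",
                 "delta_ofv", "action"],
    )
    return SelectionResult(final=current_fit, included=included, trace=trace)
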