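"""Structural and covariate model for amikacin disposition in neonates.

The drug is described by a one-compartment model with first-order
elimination.  Clearance and volume are scaled by covariates through
power (allometric) terms; between-subject variability enters as
log-normal random effects and residual variability as a combined
proportional + additive error:

    CL_i = theta_cl * (WT/1000)^a * (PMA/30)^b * exp(eta_cl),
    V_i  = theta_v  * (WT/1000)^c * exp(eta_v),
    y_ij = C(t_ij; CL_i, V_i) * (1 + eps_prop) + eps_add.

Weight is carried in grams internally; the equations normalise by a
1000 g reference so that ``theta_cl`` and ``theta_v`` are the typical
values of a 1 kg neonate at 30 weeks postmenstrual age.  Volume is
interpreted as TOTAL litres at the reference weight (approximately
0.5 L/kg at 1 kg), with the allometric exponent acting on WT/1000.

Concentrations are closed-form superpositions over the dosing history:
IV doses are zero-order infusions (nominal 0.5 h), IM doses default to
instantaneous complete absorption, optionally first-order with rate
``ka_im``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import yaml

__all__ = [
    "CovariateSet",
    "CovariateTerm",
    "PopulationModel",
    "DoseEvent",
    "ObservationEvent",
    "IndividualParameters",
    "typical_cl",
    "typical_v",
    "individual_params",
    "concentration",
    "apply_residual_error",
    "final_model",
    "model_from_dict",
    "model_to_dict",
]

logger = logging.getLogger(__name__)

#: default normalisation constants for covariate terms (cohort medians)
COVARIATE_REFERENCES = {"WT": 1000.0, "PMA": 30.0, "GA": 30.0, "PNA": 7.0, "SCR": 45.0}

_PLAUSIBLE_WT = (300.0, 5000.0)


@dataclass(frozen=True)
class CovariateSet:
    """Per-subject covariates.

    Parameters
    ----------
    wt : float
        Body weight in grams.
    pma : float
        Postmenstrual age in weeks (decimal).
    ga : float
        Gestational age in weeks.
    pna : float
        Postnatal age in days.
    scr : float
        Serum creatinine in µmol/L.
    """

    wt: float
    pma: float
    ga: float = float("nan")
    pna: float = float("nan")
    scr: float = float("nan")

    def __post_init__(self) -> None:
        if not (self.wt > 0):
            raise ValueError(f"weight must be positive, got {self.wt}")
        if np.isfinite(self.ga) and self.pma < self.ga:
            raise ValueError(
                f"postmenstrual age ({self.pma}) cannot precede gestational age ({self.ga})"
            )
        for name in ("wt", "pma"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"covariate {name!r} must be finite")
        if not (_PLAUSIBLE_WT[0] <= self.wt <= _PLAUSIBLE_WT[1]):
            warnings.warn(
                f"weight {self.wt:.0f} g outside plausible neonatal range "
                f"{_PLAUSIBLE_WT}",
                stacklevel=2,
            )

    def value(self, covariate: str) -> float:
        return {
            "WT": self.wt,
            "PMA": self.pma,
            "GA": self.ga,
            "PNA": self.pna,
            "SCR": self.scr,
        }[covariate]


@dataclass(frozen=True)
class CovariateTerm:
    """One multiplicative covariate effect on CL or V.

    ``power`` estimates the exponent; ``allometric`` fixes it at the
    theory value supplied in ``exponent``; ``sigmoid_emax`` is the
    maturation function x^gamma / (tm50^gamma + x^gamma), used for PMA
    on clearance only.
    """

    covariate: str
    form: str = "power"  # power | allometric | sigmoid_emax
    reference: float = float("nan")
    exponent: float = 0.0
    gamma: float = 3.0
    tm50: float = 45.0

    def __post_init__(self) -> None:
        if self.covariate not in COVARIATE_REFERENCES:
            raise ValueError(f"unknown covariate {self.covariate!r}")
        if self.form not in ("power", "allometric", "sigmoid_emax"):
            raise ValueError(f"unknown covariate form {self.form!r}")
        if np.isnan(self.reference):
            object.__setattr__(
                self, "reference", COVARIATE_REFERENCES[self.covariate]
            )

    def multiplier(self, x):
        """Evaluate the effect at covariate value(s) ``x`` (array-friendly)."""
        x = np.asarray(x, dtype=float)
        if self.form in ("power", "allometric"):
            return (x / self.reference) ** self.exponent
        xg = x**self.gamma
        return xg / (self.tm50**self.gamma + xg)


@dataclass(frozen=True)
class PopulationModel:
    """Fixed effects, between-subject variances and residual error.

    The named exponents cover the final-model covariate structure
    (weight and maturation on clearance, weight on volume); ``None``
    means the term is absent.  ``extra_cl_terms`` / ``extra_v_terms``
    carry additional candidate effects used during covariate selection.
    """

    theta_cl: float
    theta_v: float
    exp_wt_cl: Optional[float] = None
    exp_pma_cl: Optional[float] = None
    exp_wt_v: Optional[float] = None
    omega2_cl: float = 0.0
    omega2_v: float = 0.0
    sigma_prop: float = 0.0
    sigma_add: float = 0.0
    ka_im: Optional[float] = None
    f_im: float = 1.0
    extra_cl_terms: tuple = field(default_factory=tuple)
    extra_v_terms: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not (self.theta_cl > 0 and self.theta_v > 0):
            raise ValueError("typical clearance and volume must be positive")
        for name in ("omega2_cl", "omega2_v", "sigma_prop", "sigma_add"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0 < self.f_im <= 1):
            raise ValueError("IM bioavailability must lie in (0, 1]")

    def replace(self, **kw) -> "PopulationModel":
        return replace(self, **kw)


@dataclass(frozen=True)
class DoseEvent:
    """A single administration: time (h since first dose), amount (mg),
    route ('IV' or 'IM'), infusion duration (h, 0 for IM)."""

    time: float
    amount: float
    route: str = "IV"
    duration: float = 0.5

    def __post_init__(self) -> None:
        if self.amount <= 0:
            raise ValueError("dose amount must be positive")
        if self.duration < 0:
            raise ValueError("infusion duration cannot be negative")
        if self.route not in ("IV", "IM"):
            raise ValueError(f"unknown route {self.route!r}")
        if self.route == "IV" and self.duration <= 0:
            raise ValueError("IV doses are infusions and need duration > 0")
        if self.route == "IM" and self.duration != 0:
            raise ValueError("IM doses carry duration 0")


@dataclass(frozen=True)
class ObservationEvent:
    """A sampled (or to-be-predicted) concentration."""

    time: float
    concentration: Optional[float] = None
    label: str = "random"  # trough | peak | random

    def __post_init__(self) -> None:
        if self.concentration is not None and self.concentration < 0:
            raise ValueError("observed concentration cannot be negative")
        if self.label not in ("trough", "peak", "random"):
            raise ValueError(f"unknown observation label {self.label!r}")


@dataclass(frozen=True)
class IndividualParameters:
    cl: float
    v: float
    eta_cl: float = 0.0
    eta_v: float = 0.0

    def __post_init__(self) -> None:
        if not (self.cl > 0 and self.v > 0):
            raise ValueError("individual CL and V must be positive")

    @property
    def k(self) -> float:
        """Elimination rate constant (1/h)."""
        return self.cl / self.v


# ---------------------------------------------------------------------------
# typical values


def typical_cl(cov: CovariateSet, model: PopulationModel) -> float:
    """Typical (population) clearance in L/h at the subject's covariates."""
    if cov.wt <= 0 or cov.pma <= 0:
        raise ValueError("weight and postmenstrual age must be positive")
    cl = model.theta_cl
    if model.exp_wt_cl is not None:
        cl *= (cov.wt / 1000.0) ** model.exp_wt_cl
    if model.exp_pma_cl is not None:
        cl *= (cov.pma / 30.0) ** model.exp_pma_cl
    for term in model.extra_cl_terms:
        x = cov.value(term.covariate)
        if not (x > 0):
            raise ValueError(
                f"covariate {term.covariate} must be positive, got {x}"
            )
        cl *= float(term.multiplier(x))
    return cl


def typical_v(cov: CovariateSet, model: PopulationModel) -> float:
    """Typical volume of distribution in litres (total, not per kg)."""
    if cov.wt <= 0:
        raise ValueError("weight must be positive")
    v = model.theta_v
    if model.exp_wt_v is not None:
        v *= (cov.wt / 1000.0) ** model.exp_wt_v
    for term in model.extra_v_terms:
        x = cov.value(term.covariate)
        if not (x > 0):
            raise ValueError(
                f"covariate {term.covariate} must be positive, got {x}"
            )
        v *= float(term.multiplier(x))
    return v


def individual_params(
    cov: CovariateSet,
    model: PopulationModel,
    eta_cl: float = 0.0,
    eta_v: float = 0.0,
) -> IndividualParameters:
    """Individual CL and V from typical values and log-normal random effects."""
    if not (np.isfinite(eta_cl) and np.isfinite(eta_v)):
        raise ValueError("random effects must be finite")
    return IndividualParameters(
        cl=typical_cl(cov, model) * float(np.exp(eta_cl)),
        v=typical_v(cov, model) * float(np.exp(eta_v)),
        eta_cl=eta_cl,
        eta_v=eta_v,
    )


# ---------------------------------------------------------------------------
# concentration engine (scalar/array time, single subject)


def concentration(
    ind: IndividualParameters,
    doses: Sequence[DoseEvent],
    t,
    model: Optional[PopulationModel] = None,
):
    """Plasma concentration (mg/L) at time(s) ``t`` under superposition.

    IV infusions contribute ``(R/CL)(1 - e^{-k te}) e^{-k td}`` with
    ``te`` the infused time and ``td`` the time since the infusion
    ended; IM doses contribute a bolus ``F·A/V·e^{-k Δ}`` by default,
    or a first-order (Bateman) term when the model sets ``ka_im``.
    Before the first dose the concentration is zero.
    """
    k = ind.k
    if not (k > 0):
        raise ValueError("elimination rate constant must be positive")
    f_im = model.f_im if model is not None else 1.0
    ka = model.ka_im if model is not None else None

    t = np.asarray(t, dtype=float)
    out = np.zeros(np.shape(t), dtype=float)
    last = -np.inf
    for d in doses:
        if d.time < last:
            raise ValueError("doses must be time-sorted")
        last = d.time
        dt = t - d.time
        if d.route == "IV":
            rate = d.amount / d.duration
            te = np.clip(dt, 0.0, d.duration)
            td = np.maximum(dt - d.duration, 0.0)
            out += (rate / ind.cl) * (1.0 - np.exp(-k * te)) * np.exp(-k * td)
        else:
            active = dt >= 0
            dtp = np.where(active, dt, 0.0)
            if ka is None:
                contrib = f_im * d.amount / ind.v * np.exp(-k * dtp)
            elif abs(ka - k) < 1e-10 * max(k, 1.0):
                # limiting form as ka -> k
                contrib = f_im * d.amount * k * dtp * np.exp(-k * dtp) / ind.v
            else:
                contrib = (
                    f_im
                    * d.amount
                    * ka
                    / (ind.v * (ka - k))
                    * (np.exp(-k * dtp) - np.exp(-ka * dtp))
                )
            out += np.where(active, contrib, 0.0)
    return out if out.ndim else float(out)


def apply_residual_error(
    pred, model: PopulationModel, noise: tuple
) -> np.ndarray:
    """Apply combined proportional + additive residual error.

    ``noise`` is a pair ``(eps_prop, eps_add)`` of draws (scalars or
    arrays matching ``pred``) from N(0, sigma_prop^2) and
    N(0, sigma_add^2).  Negative simulated concentrations are truncated
    to zero; the truncation count is logged.
    """
    pred = np.asarray(pred, dtype=float)
    eps_prop, eps_add = noise
    y = pred * (1.0 + np.asarray(eps_prop)) + np.asarray(eps_add)
    n_neg = int(np.sum(y < 0))
    if n_neg:
        logger.info("truncated %d negative simulated concentrations to 0", n_neg)
    return np.maximum(y, 0.0)


# ---------------------------------------------------------------------------
# serialisation

_MODEL_KEYS = (
    "theta_cl",
    "theta_v",
    "exp_wt_cl",
    "exp_pma_cl",
    "exp_wt_v",
    "omega2_cl",
    "omega2_v",
    "sigma_prop",
    "sigma_add",
    "ka_im",
    "f_im",
)

_TERM_KEYS = ("covariate", "form", "reference", "exponent", "gamma", "tm50")


def model_to_dict(model: PopulationModel) -> dict:
    d = {k: getattr(model, k) for k in _MODEL_KEYS}
    for side in ("cl", "v"):
        terms = getattr(model, f"extra_{side}_terms")
        if terms:
            d[f"extra_{side}_terms"] = [
                {k: getattr(t, k) for k in _TERM_KEYS} for t in terms
            ]
    return d


def model_from_dict(d: dict) -> PopulationModel:
    d = dict(d)
    for side in ("cl", "v"):
        key = f"extra_{side}_terms"
        if key in d:
            d[key] = tuple(CovariateTerm(**t) for t in d[key])
    return PopulationModel(**d)


def final_model() -> PopulationModel:
    """The packaged final covariate model (with default residual-error
    magnitudes for simulation)."""
    text = (
        resources.files("amikapk.resources")
        .joinpath("final_model.yaml")
        .read_text()
    )
    return model_from_dict(yaml.safe_load(text))
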