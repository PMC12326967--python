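"""Virtual neonatal cohorts under the institutional amikacin protocol.

The generator emulates the study population that the analysis assumes:
preterm-dominated demographics (gestational age, weight, serum
creatinine and postmenstrual age at treatment initiation drawn from
log-normal distributions matched to the reported cohort medians and
interquartile ranges), the institutional regimen (11 mg/kg every 36 h
when PMA < 29 weeks, every 24 h otherwise; IV infusions over a nominal
30 min or IM injection), and sparse therapeutic-drug-monitoring
sampling anchored to the third dose (trough 30 min before, peak 30 min
after the end of an IV infusion or 60 min after an IM injection),
optionally plus random samples within the third dosing interval.

Only marginal summaries of the demographics are reported for the
source cohort; a Gaussian-copula correlation (rho = 0.8) between
gestational age and weight is imposed so that bigger babies are the
more mature ones, and postnatal age is derived as PNA = 7·(PMA - GA).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .dataset import Dataset, SubjectRecord
from .model import (
    CovariateSet,
    DoseEvent,
    ObservationEvent,
    PopulationModel,
    apply_residual_error,
    concentration,
    individual_params,
)

__all__ = [
    "CohortSpec",
    "InvalidCohortSpec",
    "SchedulingError",
    "sample_demographics",
    "build_regimen",
    "schedule_tdm",
    "simulate_dataset",
]

# standard-normal quartile: IQR of a log-normal spans 2 * 0.674 sigma in logs
_Z75 = 0.6744897501960817

DOSE_MG_PER_KG = 11.0
PMA_CUTOFF_WK = 29.0
IV_INFUSION_H = 0.5


class InvalidCohortSpec(ValueError):
    """Cohort specification is internally inconsistent."""


class SchedulingError(ValueError):
    """TDM schedule cannot be constructed for the dosing history."""


@dataclass(frozen=True)
class _LogNormalSpec:
    median: float
    iqr: Tuple[float, float]
    bounds: Tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.iqr
        if not (0 < lo < hi):
            raise InvalidCohortSpec(f"inverted or non-positive IQR {self.iqr}")
        if not (self.bounds[0] < self.median < self.bounds[1]):
            raise InvalidCohortSpec(
                f"median {self.median} outside clipping bounds {self.bounds}"
            )

    @property
    def sigma_log(self) -> float:
        return math.log(self.iqr[1] / self.iqr[0]) / (2 * _Z75)

    def from_z(self, z: np.ndarray) -> np.ndarray:
        x = self.median * np.exp(self.sigma_log * z)
        return np.clip(x, *self.bounds)


@dataclass(frozen=True)
class CohortSpec:
    """Cohort size, randomness and demographic targets.

    Demographic defaults reproduce the source cohort summaries:
    GA median 29 (IQR 26-31) weeks, weight at initiation median 1.34
    (0.90-1.90) kg, PMA at initiation median 45+6 (39+5, 53+5) weeks,
    serum creatinine median 43 (29-57) µmol/L, each clipped to the
    reported min-max range.
    """

    n_subjects: int = 100
    seed: int = 0
    ga: _LogNormalSpec = _LogNormalSpec(29.0, (26.0, 31.0), (23.0, 41.0))
    pma: _LogNormalSpec = _LogNormalSpec(
        45 + 6 / 7, (39 + 5 / 7, 53 + 5 / 7), (25 + 6 / 7, 113 + 6 / 7)
    )
    wt: _LogNormalSpec = _LogNormalSpec(1340.0, (900.0, 1900.0), (580.0, 3770.0))
    scr: _LogNormalSpec = _LogNormalSpec(43.0, (29.0, 57.0), (15.0, 91.0))
    ga_wt_corr: float = 0.8
    route_mix: float = 0.5  # fraction of subjects dosed IM
    n_doses: int = 5
    n_random_obs: int = 1
    tdm_jitter_h: float = 0.0  # uniform +/- jitter on nominal TDM times

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise InvalidCohortSpec("need at least one subject")
        if not (0.0 <= self.route_mix <= 1.0):
            raise InvalidCohortSpec("route_mix must lie in [0, 1]")
        if not (-1.0 < self.ga_wt_corr < 1.0):
            raise InvalidCohortSpec("ga_wt_corr must lie in (-1, 1)")


def sample_demographics(
    spec: CohortSpec, rng: Optional[np.random.Generator] = None
) -> List[CovariateSet]:
    """Draw per-subject covariates matching the spec's marginal targets."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    n = spec.n_subjects
    rho = spec.ga_wt_corr
    z_shared = rng.standard_normal(n)
    z_ga = rho * z_shared + math.sqrt(1 - rho**2) * rng.standard_normal(n)
    z_wt = rho * z_shared + math.sqrt(1 - rho**2) * rng.standard_normal(n)
    ga = spec.ga.from_z(z_ga)
    wt = spec.wt.from_z(z_wt)
    pma = spec.pma.from_z(rng.standard_normal(n))
    pma = np.maximum(pma, ga + 1.0 / 7.0)  # at least one postnatal day
    scr = spec.scr.from_z(rng.standard_normal(n))
    return [
        CovariateSet(
            wt=float(wt[i]),
            pma=float(pma[i]),
            ga=float(ga[i]),
            pna=float(7.0 * (pma[i] - ga[i])),
            scr=float(scr[i]),
        )
        for i in range(n)
    ]


def build_regimen(
    cov: CovariateSet, n_doses: int, route: str = "IV"
) -> List[DoseEvent]:
    """Institutional regimen: 11 mg/kg, q36h below 29 weeks PMA, else q24h."""
    if n_doses <= 0:
        return []
    amount = DOSE_MG_PER_KG * cov.wt / 1000.0
    interval = 36.0 if cov.pma < PMA_CUTOFF_WK else 24.0
    duration = IV_INFUSION_H if route == "IV" else 0.0
    return [
        DoseEvent(time=i * interval, amount=amount, route=route, duration=duration)
        for i in range(n_doses)
    ]


def schedule_tdm(
    doses: Sequence[DoseEvent],
    route: Optional[str] = None,
    jitter_h: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> List[ObservationEvent]:
    """Trough/peak sampling times anchored to the third dose.

    Trough is drawn 30 min before the third dose; peak 30 min after the
    end of the IV infusion, or 60 min after an IM injection.
    """
    if len(doses) < 3:
        raise SchedulingError(
            f"TDM is anchored to the third dose; only {len(doses)} dose(s) given"
        )
    third = doses[2]
    route = third.route if route is None else route
    trough_t = third.time - 0.5
    peak_t = third.time + (third.duration + 0.5 if route == "IV" else 1.0)
    if jitter_h:
        if rng is None:
            raise ValueError("jitter requires a random generator")
        trough_t += rng.uniform(-jitter_h, 0.0)  # never sample after the dose
        peak_t += rng.uniform(-jitter_h, jitter_h)
    return [
        ObservationEvent(time=trough_t, label="trough"),
        ObservationEvent(time=peak_t, label="peak"),
    ]


def simulate_dataset(
    spec: CohortSpec,
    model: PopulationModel,
    seed: Optional[int] = None,
) -> Dataset:
    """Fully simulated TDM dataset under the population model.

    Per subject: draw covariates and route, build the institutional
    regimen and TDM schedule (plus ``spec.n_random_obs`` random samples
    in the third dosing interval), draw random effects from
    N(0, omega2), compute concentrations and apply residual error.
    Reproducible given (seed, spec, model); simulation-truth individual
    parameters are retained on each record.
    """
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    covs = sample_demographics(spec, rng)
    im_flags = rng.random(spec.n_subjects) < spec.route_mix
    subjects = []
    for i, cov in enumerate(covs):
        route = "IM" if im_flags[i] else "IV"
        doses = build_regimen(cov, spec.n_doses, route)
        obs_events = schedule_tdm(
            doses, jitter_h=spec.tdm_jitter_h, rng=rng
        )
        interval = doses[1].time - doses[0].time
        third_t = doses[2].time
        for _ in range(spec.n_random_obs):
            obs_events.append(
                ObservationEvent(
                    time=float(rng.uniform(third_t + 1.5, third_t + interval)),
                    label="random",
                )
            )
        eta_cl = rng.normal(0.0, math.sqrt(model.omega2_cl)) if model.omega2_cl > 0 else 0.0
        eta_v = rng.normal(0.0, math.sqrt(model.omega2_v)) if model.omega2_v > 0 else 0.0
        ind = individual_params(cov, model, eta_cl, eta_v)
        times = np.array([o.time for o in obs_events])
        pred = concentration(ind, doses, times, model)
        eps_p = rng.normal(0.0, model.sigma_prop, size=times.size)
        eps_a = rng.normal(0.0, model.sigma_add, size=times.size)
        y = apply_residual_error(pred, model, (eps_p, eps_a))
        observations = [
            ObservationEvent(time=o.time, concentration=float(y[j]), label=o.label)
            for j, o in enumerate(obs_events)
        ]
        subjects.append(
            SubjectRecord(
                id=f"SIM{i + 1:04d}",
                covariates=cov,
                doses=doses,
                observations=observations,
                true_params=ind,
            )
        )
    return Dataset(
        subjects=subjects,
        provenance={"generator": "simulate_dataset", "seed": seed,
                    "n_subjects": spec.n_subjects},
    )
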