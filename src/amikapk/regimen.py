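"""Dosing-protocol appropriateness and therapeutic-target attainment.

Mirrors the institutional therapeutic-drug-monitoring audit: a dose is
correct when it lies within ±5% of 11 mg/kg of the weight at therapy
initiation; a trough sample is appropriately timed when drawn within
30 minutes before a dose, a peak when drawn 60-90 minutes after the
injection or the start of the infusion, in both cases on or after the
third dose.  Targets are 15-25 mg/L (inclusive) for peaks and
strictly below 5 mg/L for troughs.  IV and IM groups are compared with
an independent-sample t-test on the levels and a chi-square (or
Fisher's exact, when any expected cell count is below 5) test on the
in-range proportions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import DOSE_MG_PER_KG
from .dataset import Dataset
from .model import DoseEvent, ObservationEvent

__all__ = [
    "check_dose_correct",
    "check_sampling_time",
    "in_target_range",
    "attainment",
    "AttainmentReport",
    "compare_routes",
    "RouteComparison",
    "assess_tdm",
]

PEAK_RANGE = (15.0, 25.0)
TROUGH_LIMIT = 5.0
TROUGH_WINDOW_H = 0.5
PEAK_WINDOW_H = (1.0, 1.5)
MIN_DOSE_INDEX = 3  # third dose, 1-based


def check_dose_correct(
    given_mg: float, wt_g: float, mg_per_kg: float = DOSE_MG_PER_KG
) -> bool:
    """True iff the administered dose is within ±5% (inclusive) of the
    calculated mg/kg dose for the initiation weight."""
    if given_mg <= 0 or wt_g <= 0:
        raise ValueError("dose and weight must be positive")
    target = mg_per_kg * wt_g / 1000.0
    # inclusive boundary, robust to float representation of ±5%
    return abs(given_mg - target) <= 0.05 * target * (1.0 + 1e-12)


def check_sampling_time(
    obs: ObservationEvent,
    doses: Sequence[DoseEvent],
    route: Optional[str] = None,
) -> bool:
    """Was the sample drawn in the protocol window, on/after dose three?

    Trough: within [dose_time - 0.5 h, dose_time] of the dose it
    precedes.  Peak: within [start + 1.0 h, start + 1.5 h] of the most
    recent dose start (IM injection or IV infusion initiation — the
    window is the same relative to dose time for both routes).
    """
    if not doses:
        raise ValueError("dose history is empty")
    doses = sorted(doses, key=lambda d: d.time)
    if obs.time < doses[0].time - TROUGH_WINDOW_H:
        warnings.warn("observation predates the first dose")
        return False
    if obs.label == "trough":
        for i, d in enumerate(doses):
            if d.time - TROUGH_WINDOW_H <= obs.time <= d.time:
                return i + 1 >= MIN_DOSE_INDEX
        return False
    if obs.label == "peak":
        prior = [i for i, d in enumerate(doses) if d.time <= obs.time]
        if not prior:
            return False
        i = prior[-1]
        start = doses[i].time
        lo, hi = PEAK_WINDOW_H
        return (start + lo <= obs.time <= start + hi) and (i + 1 >= MIN_DOSE_INDEX)
    return False  # random samples carry no appropriateness window


def in_target_range(conc: float, label: str) -> bool:
    """Peak in range iff 15 <= C <= 25 (inclusive); trough iff C < 5."""
    if label == "peak":
        return PEAK_RANGE[0] <= conc <= PEAK_RANGE[1]
    if label == "trough":
        return conc < TROUGH_LIMIT
    raise ValueError(f"no target range for label {label!r}")


@dataclass
class AttainmentReport:
    by_label: Dict[str, float]  # label -> proportion in range
    by_route_label: Dict[tuple, float]  # (route, label) -> proportion
    counts: Dict[str, int]
    n_excluded: int  # unlabeled / random levels

    def proportion(self, label: str, route: Optional[str] = None) -> float:
        return self.by_label[label] if route is None else self.by_route_label[(route, label)]


def attainment(levels) -> AttainmentReport:
    """Target-attainment proportions per label (and route, if given).

    ``levels``: DataFrame with columns ``label``, ``conc`` and
    optionally ``route``, or an iterable of (label, conc[, route])
    tuples.
    """
    if not isinstance(levels, pd.DataFrame):
        rows = [tuple(t) for t in levels]
        cols = ["label", "conc", "route"][: len(rows[0])] if rows else ["label", "conc"]
        levels = pd.DataFrame(rows, columns=cols)
    usable = levels[levels["label"].isin(["peak", "trough"])].copy()
    n_excl = len(levels) - len(usable)
    usable["in_range"] = [
        in_target_range(c, l) for c, l in zip(usable["conc"], usable["label"])
    ]
    by_label = usable.groupby("label")["in_range"].mean().to_dict()
    counts = usable.groupby("label")["in_range"].size().to_dict()
    by_route = {}
    if "route" in usable.columns:
        by_route = (
            usable.groupby(["route", "label"])["in_range"].mean().to_dict()
        )
    return AttainmentReport(
        by_label=by_label, by_route_label=by_route,
        counts={k: int(v) for k, v in counts.items()}, n_excluded=n_excl,
    )


@dataclass
class RouteComparison:
    label: str
    mean_iv: float
    sd_iv: float
    mean_im: float
    sd_im: float
    p_ttest: float
    prop_in_range_iv: float
    prop_in_range_im: float
    p_proportion: float
    proportion_test: str  # 'chi2' | 'fisher'
    n_iv: int
    n_im: int
    ttest_skipped: bool = False

    def to_frame(self) -> pd.DataFrame:
        """One-row table mirroring the published layout."""
        return pd.DataFrame(
            [
                {
                    "serum_concentration": self.label,
                    "iv_mean_sd": f"{self.mean_iv:.2f} ± {self.sd_iv:.2f}",
                    "im_mean_sd": f"{self.mean_im:.2f} ± {self.sd_im:.2f}",
                    "p_ttest": self.p_ttest,
                    "iv_pct_in_range": 100 * self.prop_in_range_iv,
                    "im_pct_in_range": 100 * self.prop_in_range_im,
                    "p_proportion": self.p_proportion,
                    "proportion_test": self.proportion_test,
                }
            ]
        )


def compare_routes(
    group_iv: Sequence[float], group_im: Sequence[float], label: str = "peak"
) -> RouteComparison:
    """IV-vs-IM comparison of levels and in-range proportions."""
    iv = np.asarray(group_iv, dtype=float)
    im = np.asarray(group_im, dtype=float)
    if iv.size == 0 or im.size == 0:
        raise ValueError("both route groups must be non-empty")
    skipped = iv.size < 2 or im.size < 2
    if skipped:
        p_t = float("nan")
    else:
        p_t = float(stats.ttest_ind(iv, im).pvalue)
        if not np.isfinite(p_t):  # identical constant groups
            p_t = 1.0
    in_iv = np.array([in_target_range(c, label) for c in iv])
    in_im = np.array([in_target_range(c, label) for c in im])
    table = np.array(
        [
            [in_iv.sum(), (~in_iv).sum()],
            [in_im.sum(), (~in_im).sum()],
        ]
    )
    if np.any(table.sum(axis=0) == 0):
        # all in (or all out of) range in both groups: proportions equal
        p_prop, which = 1.0, "fisher"
    else:
        expected = stats.contingency.expected_freq(table)
        if np.any(expected <= 5):
            p_prop = float(stats.fisher_exact(table).pvalue)
            which = "fisher"
        else:
            p_prop = float(stats.chi2_contingency(table).pvalue)
            which = "chi2"
    return RouteComparison(
        label=label,
        mean_iv=float(iv.mean()), sd_iv=float(iv.std(ddof=1)) if iv.size > 1 else 0.0,
        mean_im=float(im.mean()), sd_im=float(im.std(ddof=1)) if im.size > 1 else 0.0,
        p_ttest=p_t,
        prop_in_range_iv=float(in_iv.mean()),
        prop_in_range_im=float(in_im.mean()),
        p_proportion=p_prop,
        proportion_test=which,
        n_iv=int(iv.size), n_im=int(im.size),
        ttest_skipped=skipped,
    )


def assess_tdm(dataset: Dataset, mg_per_kg: float = DOSE_MG_PER_KG) -> pd.DataFrame:
    """Per-observation audit table for a cohort.

    Columns: id, route, label, time, conc, dose_correct,
    sampled_appropriately, within_range.
    """
    rows = []
    for s in dataset:
        if not s.doses:
            continue
        route = s.doses[0].route
        correct = all(
            check_dose_correct(d.amount, s.covariates.wt, mg_per_kg)
            for d in s.doses
        )
        for o in s.observations:
            if o.concentration is None:
                continue
            within = (
                in_target_range(o.concentration, o.label)
                if o.label in ("peak", "trough")
                else None
            )
            rows.append(
                dict(
                    id=s.id,
                    route=route,
                    label=o.label,
                    time=o.time,
                    conc=o.concentration,
                    dose_correct=correct,
                    sampled_appropriately=check_sampling_time(o, s.doses, route),
                    within_range=within,
                )
            )
    return pd.DataFrame(rows)
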