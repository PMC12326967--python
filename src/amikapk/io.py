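"""NONMEM-style tabular dataset I/O.

The dialect is a plain CSV with one row per event:

    ID, TIME, AMT, RATE, ROUTE, DV, MDV, EVID, WT, PMA, GA, PNA, SCR
    [, LABEL, CF]

Dose rows carry EVID=1 with AMT in mg and RATE in mg/h (0 for IM or
bolus; infusion duration is AMT/RATE when RATE > 0); observation rows
carry EVID=0, MDV=0 and the concentration in DV (mg/L).  Missing
values are written as '.'.  Covariates are carried per row; gaps are
filled last-observation-carried-forward on read, with the imputation
count logged and flagged in the CF audit column on write.  LABEL
(trough/peak/random) is an extension column preserving the sampling
annotation across round-trips.  Steady-state/ADDL expansion codes are
not supported: regimens are written as explicit rows.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .dataset import Dataset, SubjectRecord
from .model import CovariateSet, DoseEvent, ObservationEvent

__all__ = ["DatasetFormatError", "read_dataset", "write_dataset"]

logger = logging.getLogger(__name__)

MANDATORY_COLUMNS = [
    "ID", "TIME", "AMT", "RATE", "ROUTE", "DV", "MDV", "EVID",
    "WT", "PMA", "GA", "PNA", "SCR",
]
_COV_COLS = ["WT", "PMA", "GA", "PNA", "SCR"]
_NA = "."


class DatasetFormatError(ValueError):
    """The file does not conform to the dataset dialect."""


def read_dataset(path: Union[str, Path]) -> Dataset:
    """Parse a dataset file into subject records."""
    df = pd.read_csv(
        path, na_values=[_NA], dtype={"ID": str, "ROUTE": str},
        float_precision="round_trip",
    )
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise DatasetFormatError(f"missing mandatory column {col!r}")
    if (df["TIME"] < 0).any():
        bad = int(df.index[df["TIME"] < 0][0]) + 2  # 1-based incl. header
        raise DatasetFormatError(f"negative TIME at file line {bad}")
    routes = df.loc[df["EVID"] == 1, "ROUTE"].dropna().unique()
    unknown = [r for r in routes if r not in ("IV", "IM")]
    if unknown:
        raise DatasetFormatError(f"unknown ROUTE value(s) {unknown}")

    # LOCF for covariate gaps, per subject
    before = df[_COV_COLS].isna()
    df[_COV_COLS] = df.groupby("ID", sort=False)[_COV_COLS].ffill()
    # leading gaps: fall back to the first recorded value
    df[_COV_COLS] = df.groupby("ID", sort=False)[_COV_COLS].bfill()
    n_gaps = int((before & df[_COV_COLS].notna()).any(axis=1).sum())
    if n_gaps:
        logger.info("carried forward covariates on %d rows", n_gaps)

    subjects = []
    for sid, g in df.groupby("ID", sort=False):
        g = g.sort_values(["TIME", "EVID"], ascending=[True, False], kind="stable")
        first = g.iloc[0]
        cov = CovariateSet(
            wt=float(first["WT"]),
            pma=float(first["PMA"]),
            ga=float(first["GA"]) if pd.notna(first["GA"]) else float("nan"),
            pna=float(first["PNA"]) if pd.notna(first["PNA"]) else float("nan"),
            scr=float(first["SCR"]) if pd.notna(first["SCR"]) else float("nan"),
        )
        doses = []
        observations = []
        for _, row in g.iterrows():
            if row["EVID"] == 1:
                rate = float(row["RATE"]) if pd.notna(row["RATE"]) else 0.0
                amt = float(row["AMT"])
                doses.append(
                    DoseEvent(
                        time=float(row["TIME"]),
                        amount=amt,
                        route=str(row["ROUTE"]),
                        duration=amt / rate if rate > 0 else 0.0,
                    )
                )
            elif row["EVID"] == 0 and row.get("MDV", 0) == 0:
                observations.append(
                    ObservationEvent(
                        time=float(row["TIME"]),
                        concentration=float(row["DV"]) if pd.notna(row["DV"]) else None,
                        label=str(row["LABEL"]) if "LABEL" in g.columns and pd.notna(row["LABEL"]) else "random",
                    )
                )
        subjects.append(
            SubjectRecord(id=str(sid), covariates=cov, doses=doses,
                          observations=observations)
        )
    return Dataset(subjects=subjects, provenance={"source": str(path),
                                                  "locf_rows": n_gaps})


def write_dataset(dataset: Dataset, path: Union[str, Path]) -> None:
    """Write a dataset deterministically (subjects in order, rows by
    time with dose rows before observations at ties)."""
    rows = []
    for s in dataset:
        cov = s.covariates
        base = dict(
            ID=s.id, WT=cov.wt, PMA=cov.pma, GA=cov.ga, PNA=cov.pna,
            SCR=cov.scr, CF=0,
        )
        for d in s.doses:
            rows.append(
                dict(base, TIME=d.time, AMT=d.amount,
                     RATE=d.amount / d.duration if d.duration > 0 else 0.0,
                     ROUTE=d.route, DV=np.nan, MDV=1, EVID=1, LABEL=np.nan)
            )
        for o in s.observations:
            rows.append(
                dict(base, TIME=o.time, AMT=np.nan, RATE=np.nan, ROUTE=np.nan,
                     DV=o.concentration, MDV=0 if o.concentration is not None else 1,
                     EVID=0, LABEL=o.label)
            )
    cols = MANDATORY_COLUMNS + ["LABEL", "CF"]
    df = pd.DataFrame(rows, columns=cols)
    df = df.sort_values(["ID", "TIME", "EVID"],
                        ascending=[True, True, False], kind="stable")
    # keep the original subject order (ids may not sort lexically)
    order = {s.id: i for i, s in enumerate(dataset)}
    df["_o"] = df["ID"].map(order)
    df = df.sort_values(["_o", "TIME", "EVID"],
                        ascending=[True, True, False], kind="stable").drop(columns="_o")
    df.to_csv(path, index=False, na_rep=_NA)
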