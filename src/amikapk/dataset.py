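"""Subject records and dataset container.

A :class:`SubjectRecord` bundles one neonate's covariates, dosing
history and observations (plus the simulation-truth individual
parameters when the record was generated rather than observed).  A
:class:`Dataset` is an ordered collection of subjects with unique ids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, List, Optional, Sequence

from .model import (
    CovariateSet,
    DoseEvent,
    IndividualParameters,
    ObservationEvent,
)

__all__ = ["SubjectRecord", "Dataset"]


@dataclass
class SubjectRecord:
    id: str
    covariates: CovariateSet
    doses: List[DoseEvent] = field(default_factory=list)
    observations: List[ObservationEvent] = field(default_factory=list)
    true_params: Optional[IndividualParameters] = None

    def __post_init__(self) -> None:
        self.doses = sorted(self.doses, key=lambda d: d.time)
        self.observations = sorted(self.observations, key=lambda o: o.time)
        if self.doses and self.observations:
            t0 = self.doses[0].time
            if self.observations[0].time < t0:
                raise ValueError(
                    f"subject {self.id}: observation at t="
                    f"{self.observations[0].time} precedes first dose at t={t0}"
                )

    @property
    def n_obs(self) -> int:
        return len(self.observations)


@dataclass
class Dataset:
    subjects: List[SubjectRecord]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate subject ids: {dupes}")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self) -> Iterator[SubjectRecord]:
        return iter(self.subjects)

    def __getitem__(self, i) -> SubjectRecord:
        return self.subjects[i]

    @property
    def n_observations(self) -> int:
        return sum(s.n_obs for s in self.subjects)

    def subset(self, indices: Sequence[int], relabel: bool = False) -> "Dataset":
        """New dataset from subject positions; ``relabel`` assigns fresh
        unique ids (needed when resampling with replacement)."""
        subs = []
        for j, i in enumerate(indices):
            s = self.subjects[i]
            if relabel:
                s = SubjectRecord(
                    id=f"{s.id}#{j}",
                    covariates=s.covariates,
                    doses=list(s.doses),
                    observations=list(s.observations),
                    true_params=s.true_params,
                )
            subs.append(s)
        return Dataset(subjects=subs, provenance=dict(self.provenance))
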