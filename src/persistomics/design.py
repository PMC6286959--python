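"""Study design: treatments x timepoints x replicates.

The experimental layout modelled here is a repeat-dose / washout design:
cells are treated daily for five days (sampled at T1, T3, T5) and then
allowed to recover compound-free, with a final sampling three days after
washout (R3). Every contrast downstream is a test compound versus the
time-matched vehicle control, never pooled across timepoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

DEFAULT_TIMEPOINTS = ("T1", "T3", "T5", "R3")


class InvalidDesignError(ValueError):
    """Raised when a design cannot support within-cell variance estimation."""


@dataclass(frozen=True)
class Sample:
    sample_id: str
    treatment: str
    timepoint: str
    replicate: int


@dataclass(frozen=True)
class StudyDesign:
    """Fully crossed treatments x timepoints x replicates sample map.

    The first treatment is the vehicle control; timepoints whose label
    starts with ``R`` are flagged as post-washout (recovery phase).
    """

    treatments: tuple[str, ...]
    timepoints: tuple[str, ...]
    n_replicates: int
    samples: tuple[Sample, ...] = field(default=())

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(ids) != len(set(ids)):
            raise InvalidDesignError("sample_ids are not unique")

    @property
    def control(self) -> str:
        return self.treatments[0]

    @property
    def test_treatments(self) -> tuple[str, ...]:
        return self.treatments[1:]

    @property
    def recovery_timepoints(self) -> tuple[str, ...]:
        return tuple(t for t in self.timepoints if t.upper().startswith("R"))

    @property
    def treatment_timepoints(self) -> tuple[str, ...]:
        return tuple(t for t in self.timepoints if not t.upper().startswith("R"))

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def samples_for(self, treatment: str, timepoint: str) -> list[str]:
        return [
            s.sample_id
            for s in self.samples
            if s.treatment == treatment and s.timepoint == timepoint
        ]

    def contrast(self, treatment: str, timepoint: str) -> tuple[list[str], list[str]]:
        """(treatment samples, time-matched control samples) for one contrast."""
        if treatment not in self.treatments:
            raise KeyError(f"unknown treatment {treatment!r}")
        if timepoint not in self.timepoints:
            raise KeyError(f"unknown timepoint {timepoint!r}")
        return (
            self.samples_for(treatment, timepoint),
            self.samples_for(self.control, timepoint),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "treatment": [s.treatment for s in self.samples],
                "timepoint": [s.timepoint for s in self.samples],
                "replicate": [s.replicate for s in self.samples],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "StudyDesign":
        treatments = tuple(dict.fromkeys(frame["treatment"]))
        timepoints = tuple(dict.fromkeys(frame["timepoint"]))
        samples = tuple(
            Sample(r.sample_id, r.treatment, r.timepoint, int(r.replicate))
            for r in frame.itertuples()
        )
        n_reps = int(frame.groupby(["treatment", "timepoint"]).size().min())
        design = cls(treatments, timepoints, n_reps, samples)
        design.validate()
        return design

    def validate(self) -> None:
        """Check the invariants required for downstream contrasts."""
        counts = self.to_frame().groupby(["treatment", "timepoint"]).size()
        if (counts < 2).any():
            bad = counts[counts < 2].index.tolist()
            raise InvalidDesignError(f"cells with <2 replicates: {bad}")
        for tp in self.timepoints:
            if not self.samples_for(self.control, tp):
                raise InvalidDesignError(f"no control series at timepoint {tp!r}")


def generate_design(
    n_treatments: int | tuple[str, ...] = 3,
    timepoints: tuple[str, ...] = DEFAULT_TIMEPOINTS,
    n_reps: int = 3,
    seed: int = 0,
) -> StudyDesign:
    """Build a fully crossed design.

    Parameters
    ----------
    n_treatments
        Number of treatment arms *including* the vehicle control, or an
        explicit tuple of labels (first label = control). With 3 arms the
        default labels are ``control``, ``OTA``, ``KBrO3``.
    timepoints
        Ordered sampling labels; labels starting with ``R`` are treated as
        post-washout.
    n_reps
        Biological replicates per (treatment, timepoint) cell; at least 2
        so that within-cell variance is estimable.
    seed
        Accepted for interface symmetry with the simulators; the layout
        itself is deterministic.
    """
    if n_reps < 2:
        raise InvalidDesignError("n_reps must be >= 2 (no within-cell variance)")
    if not timepoints:
        raise InvalidDesignError("timepoints must be non-empty")
    if isinstance(n_treatments, int):
        if n_treatments < 1:
            raise InvalidDesignError("need at least a control arm")
        named = ("control", "OTA", "KBrO3")
        if n_treatments <= len(named):
            treatments = named[:n_treatments]
        else:
            treatments = named + tuple(
                f"compound{i}" for i in range(1, n_treatments - len(named) + 1)
            )
    else:
        treatments = tuple(n_treatments)
    samples = tuple(
        Sample(f"{trt}_{tp}_r{rep}", trt, tp, rep)
        for trt in treatments
        for tp in timepoints
        for rep in range(1, n_reps + 1)
    )
    design = StudyDesign(tuple(treatments), tuple(timepoints), n_reps, samples)
    design.validate()
    return design
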