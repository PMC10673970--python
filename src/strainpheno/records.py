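"""Core data containers for regional longitudinal strain analysis.

A subject's deformation data is one cardiac cycle of speckle-tracking
longitudinal strain (%) for the six apical-4-chamber LV segments, together
with the timing landmarks (RR interval, aortic valve closure) and the
covariates used for cohort matching. Shortening is negative by convention,
so a healthy segment dips to roughly -15 to -25 % at end-systole and
returns to baseline in diastole.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Fixed wall/level ordering used for every 6 x T matrix in the package.
SEGMENTS: tuple[str, ...] = (
    "basal-septal",
    "mid-septal",
    "apical-septal",
    "apical-lateral",
    "mid-lateral",
    "basal-lateral",
)

#: Segments where carrier phenotype modifiers concentrate (apical/mid septal
#: and apical lateral), matching where regional disease expression is seen.
MODIFIER_SEGMENTS: tuple[str, ...] = ("mid-septal", "apical-septal", "apical-lateral")

#: Apical segments, where peak-strain reduction is most pronounced.
APICAL_SEGMENTS: tuple[str, ...] = ("apical-septal", "apical-lateral")

#: Closed set of ground-truth phenotype labels carried by synthetic records.
#: O_LIKE marks a variant carrier whose curves follow the control template
#: (pre-phenotypical carrier); A-D are the four morphology phenotypes
#: (diastolic notch, double peak, post-systolic shortening, reduced peak).
PHENOTYPES: tuple[str, ...] = ("CONTROL", "O_LIKE", "A", "B", "C", "D")

CARRIER_PHENOTYPES: tuple[str, ...] = ("O_LIKE", "A", "B", "C", "D")

STRAIN_RANGE = (-60.0, 40.0)


class RecordError(ValueError):
    """A DeformationRecord violated one of its invariants."""


@dataclass
class DeformationRecord:
    """One echocardiogram's six regional strain curves plus metadata.

    curves holds a 6 x L matrix (rows in SEGMENTS order) of strain in %
    uniformly sampled over one RR interval; avc_time is milliseconds from
    cycle onset. followup_years / event_sustained_va are optional survival
    follow-up fields for carriers.
    """

    subject_id: str
    echo_id: str
    group: str                      # "carrier" | "control"
    phenotype_truth: Optional[str]  # member of PHENOTYPES, or None if unknown
    age: float
    sex: str                        # "male" | "female"
    heart_rate: float               # bpm
    rr_interval: float              # ms
    avc_time: float                 # ms
    curves: np.ndarray              # (6, L) strain %
    followup_years: Optional[float] = None
    event_sustained_va: Optional[bool] = None

    def __post_init__(self) -> None:
        self.curves = np.asarray(self.curves, dtype=float)
        self.validate()

    def validate(self) -> None:
        sid = self.subject_id
        if self.group not in ("carrier", "control"):
            raise RecordError(f"{sid}: group must be carrier|control, got {self.group!r}")
        if self.phenotype_truth is not None and self.phenotype_truth not in PHENOTYPES:
            raise RecordError(f"{sid}: unknown phenotype {self.phenotype_truth!r}")
        if self.sex not in ("male", "female"):
            raise RecordError(f"{sid}: sex must be male|female, got {self.sex!r}")
        if self.curves.ndim != 2 or self.curves.shape[0] != len(SEGMENTS):
            raise RecordError(f"{sid}: curves must be 6 x L, got shape {self.curves.shape}")
        if self.curves.shape[1] < 20:
            raise RecordError(f"{sid}: curves need length >= 20, got {self.curves.shape[1]}")
        if not np.all(np.isfinite(self.curves)):
            raise RecordError(f"{sid}: non-finite strain values")
        lo, hi = STRAIN_RANGE
        if self.curves.min() < lo or self.curves.max() > hi:
            raise RecordError(f"{sid}: strain outside [{lo}, {hi}] %")
        if not (0.0 < self.avc_time < self.rr_interval):
            raise RecordError(
                f"{sid}: AVC time {self.avc_time} ms must lie strictly inside "
                f"(0, RR={self.rr_interval} ms)"
            )

    @property
    def n_samples(self) -> int:
        return self.curves.shape[1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DeformationRecord):
            return NotImplemented
        scalar = all(
            getattr(self, f) == getattr(other, f)
            for f in (
                "subject_id", "echo_id", "group", "phenotype_truth", "age",
                "sex", "heart_rate", "rr_interval", "avc_time",
                "followup_years", "event_sustained_va",
            )
        )
        return scalar and np.array_equal(self.curves, other.curves)


@dataclass
class NormalizedCurveSet:
    """6 x T strain matrix on the normalized 1-second time axis.

    The time axis is warped so that aortic valve closure sits at a fixed
    fraction of the cycle (index ``avc_index`` of the T-point grid).
    """

    subject_id: str
    matrix: np.ndarray  # (6, T)
    avc_index: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(SEGMENTS):
            raise ValueError(f"matrix must be 6 x T, got {self.matrix.shape}")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("non-finite values in normalized matrix")
        if not (0 <= self.avc_index < self.matrix.shape[1]):
            raise ValueError("avc_index outside the sample grid")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    @property
    def time_grid(self) -> np.ndarray:
        T = self.matrix.shape[1]
        return np.linspace(0.0, 1.0, T)


def segment_index(name: str) -> int:
    """Row index of a segment name, with an explicit error for typos."""
    try:
        return SEGMENTS.index(name)
    except ValueError:
        raise ValueError(
            f"unknown segment {name!r}; expected one of {SEGMENTS}"
        ) from None
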