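"""Core domain types shared across the simulation, engine and metrics layers.

Time is carried in two forms throughout the package: relative seconds from
the start of a patient's monitored stay (``t_s`` / ``start_s`` / ``end_s``),
and an absolute, timezone-naive ``start`` datetime that anchors a trace on
the wall clock for hour-of-day analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from enum import Enum

import numpy as np


class Region(str, Enum):
    """Body region bearing weight, as inferred from the roll angle.

    The lateral regions are bounded by the turn-angle threshold (default
    20 degrees): angles above ``+threshold`` load the right side, below
    ``-threshold`` the left side, anything in between loads the back.
    ``UPRIGHT`` covers out-of-bed / standing time, flagged by the posture
    channel rather than the roll angle.
    """

    LEFT = "left"
    BACK = "back"
    RIGHT = "right"
    UPRIGHT = "upright"


#: The three in-bed regions whose sustained-load clocks the engine tracks.
BED_REGIONS = (Region.LEFT, Region.BACK, Region.RIGHT)


class ComplianceState(str, Enum):
    COMPLIANT = "compliant"
    NONCOMPLIANT = "noncompliant"
    EXEMPT = "exempt"


class Display(str, Enum):
    """Colour shown at the nurses' station for one patient."""

    GREEN = "green"
    YELLOW = "yellow"
    RED = "red"
    NONE = "none"


class Posture(str, Enum):
    IN_BED = "in_bed"
    UPRIGHT = "upright"


class ExemptionReason(str, Enum):
    REFUSED = "refused"
    OFF_UNIT = "off_unit"
    CLINICAL = "clinical"


@dataclass(frozen=True)
class ExemptionInterval:
    """A documented period during which a missed turn does not count
    against compliance (patient refusal, off-unit, clinical reason).

    ``start_s``/``end_s`` are seconds relative to the trace start.
    """

    start_s: float
    end_s: float
    reason: ExemptionReason = ExemptionReason.CLINICAL

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValueError(
                f"exemption interval must have start < end, got "
                f"[{self.start_s}, {self.end_s}]"
            )
        if self.start_s < 0:
            raise ValueError("exemption interval cannot start before the trace")


@dataclass
class PatientTrace:
    """An ordered 10-s position trace for one patient.

    Attributes
    ----------
    patient_id : str
        Opaque identifier.
    start : datetime
        Absolute wall-clock time of the first sample (whole seconds).
    t_s : ndarray of int64
        Sample times in seconds from ``start``; strictly increasing.
    angle_deg : ndarray of float
        Signed roll angle, positive toward the patient's right side.
    upright : ndarray of bool
        Posture flag; True where the patient is out of bed / standing.
    exemptions : list of ExemptionInterval
        Documented missed-turn exemptions, relative to ``start``.
    """

    patient_id: str
    start: datetime
    t_s: np.ndarray
    angle_deg: np.ndarray
    upright: np.ndarray
    exemptions: list[ExemptionInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=np.int64)
        self.angle_deg = np.asarray(self.angle_deg, dtype=float)
        self.upright = np.asarray(self.upright, dtype=bool)
        n = self.t_s.size
        if n == 0:
            raise ValueError(f"trace {self.patient_id!r} is empty")
        if self.angle_deg.size != n or self.upright.size != n:
            raise ValueError(
                f"trace {self.patient_id!r}: column lengths disagree "
                f"({n} times, {self.angle_deg.size} angles, "
                f"{self.upright.size} posture flags)"
            )
        if self.t_s[0] < 0:
            raise ValueError(f"trace {self.patient_id!r}: negative sample time")
        if n > 1 and not np.all(np.diff(self.t_s) > 0):
            bad = int(np.flatnonzero(np.diff(self.t_s) <= 0)[0]) + 1
            raise ValueError(
                f"trace {self.patient_id!r}: sample times not strictly "
                f"increasing at sample index {bad}"
            )

    @property
    def n_samples(self) -> int:
        return int(self.t_s.size)

    def __eq__(self, other: object) -> bool:  # array-aware equality
        if not isinstance(other, PatientTrace):
            return NotImplemented
        return (
            self.patient_id == other.patient_id
            and self.start == other.start
            and np.array_equal(self.t_s, other.t_s)
            and np.array_equal(self.angle_deg, other.angle_deg)
            and np.array_equal(self.upright, other.upright)
            and self.exemptions == other.exemptions
        )


@dataclass(frozen=True)
class TurnEvent:
    """A registered change of in-bed region.

    The event is *qualifying* when the vacated region stays offloaded for
    at least the decompression time; ``t_qualified_s`` is then the moment
    decompression completed (``t_change_s`` + decompression time).
    """

    t_change_s: float
    from_region: Region
    to_region: Region
    qualifying: bool
    t_qualified_s: float | None = None

    def __post_init__(self) -> None:
        if self.qualifying and self.t_qualified_s is None:
            raise ValueError("qualifying turn must carry t_qualified_s")


@dataclass(frozen=True)
class TimelineInterval:
    start_s: float
    end_s: float
    state: ComplianceState
    display: Display

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class ComplianceTimeline:
    """Ordered compliance/display intervals for one patient.

    Intervals are non-overlapping and ordered; a jump between consecutive
    intervals marks an unmonitored gap (sensor dropout), which belongs to
    neither the compliant nor the non-compliant tally.
    """

    patient_id: str
    start: datetime
    intervals: list[TimelineInterval]

    def duration_s(self, state: ComplianceState) -> float:
        return sum(iv.duration_s for iv in self.intervals if iv.state is state)

    @property
    def compliant_s(self) -> float:
        return self.duration_s(ComplianceState.COMPLIANT)

    @property
    def noncompliant_s(self) -> float:
        return self.duration_s(ComplianceState.NONCOMPLIANT)

    @property
    def exempt_s(self) -> float:
        return self.duration_s(ComplianceState.EXEMPT)

    @property
    def monitored_s(self) -> float:
        return sum(iv.duration_s for iv in self.intervals)


@dataclass(frozen=True)
class PatientRecord:
    """Demographics and study metadata for one enrolled patient."""

    patient_id: str
    phase: str  # "baseline" or "post"
    age: int
    sex: str  # "F" or "M"
    braden: int
    isolation: bool
    monitored_h: float
    start: datetime | None = None

    def __post_init__(self) -> None:
        if not 6 <= self.braden <= 23:
            raise ValueError(f"Braden score {self.braden} outside scale bounds 6..23")
        if self.monitored_h <= 0:
            raise ValueError("monitored_h must be positive")
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be 'F' or 'M', got {self.sex!r}")
        if self.phase not in ("baseline", "post"):
            raise ValueError(f"phase must be 'baseline' or 'post', got {self.phase!r}")
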