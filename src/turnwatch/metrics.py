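"""The three compliance statistics computed from scored timelines.

* per-patient compliance: time compliant with the turn protocol divided
  by total monitored time;
* pooled (phase) compliance: total compliant time across patients over
  total monitored time — a monitored-time-weighted pooling, not a mean
  of per-patient fractions;
* turn-protocol adherence: patient-hours with 100% compliance per
  consecutive 100-hour monitoring block;
* average hourly compliance: compliant over monitored time pooled into
  24 hour-of-day bins.

Documented-exemption time never counts against a patient: by default it
is kept in monitored time and treated as compliant-equivalent
(``exempt_policy="as_compliant"``); ``"exclude"`` drops it from both the
numerator and the denominator instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable, Sequence

import numpy as np

from .model import ComplianceState, ComplianceTimeline, PatientRecord

_EPOCH = datetime(1970, 1, 1)
_EXEMPT_POLICIES = ("as_compliant", "exclude")


def _epoch_s(dt: datetime) -> float:
    return (dt - _EPOCH).total_seconds()


def _credit_times(
    timeline: ComplianceTimeline, exempt_policy: str
) -> tuple[float, float]:
    """Return (compliant-credit seconds, monitored-denominator seconds)."""
    if exempt_policy not in _EXEMPT_POLICIES:
        raise ValueError(f"exempt_policy must be one of {_EXEMPT_POLICIES}")
    c = timeline.compliant_s
    n = timeline.noncompliant_s
    x = timeline.exempt_s
    if exempt_policy == "as_compliant":
        return c + x, c + n + x
    return c, c + n


def patient_compliance(
    timeline: ComplianceTimeline, exempt_policy: str = "as_compliant"
) -> float:
    """Fraction of a patient's monitored time compliant with the turn
    protocol."""
    num, den = _credit_times(timeline, exempt_policy)
    if den <= 0:
        raise ValueError(
            f"timeline for {timeline.patient_id!r} has zero monitored time"
        )
    return num / den


def phase_compliance(
    timelines: Sequence[ComplianceTimeline], exempt_policy: str = "as_compliant"
) -> float:
    """Pooled compliance for a phase: summed compliant time over summed
    monitored time (equivalently, the monitored-time-weighted mean of the
    per-patient fractions)."""
    if not timelines:
        raise ValueError("phase_compliance needs at least one timeline")
    num = den = 0.0
    for tl in timelines:
        a, b = _credit_times(tl, exempt_policy)
        num += a
        den += b
    if den <= 0:
        raise ValueError("zero total monitored time across the phase")
    return num / den


def _patient_hours(
    timelines: Sequence[ComplianceTimeline], min_hour_fraction: float
) -> list[tuple[float, str, bool]]:
    """Wall-clock patient-hours: (hour start epoch, patient id, fully
    compliant flag).  An hour counts only if the patient was monitored
    for at least ``min_hour_fraction`` of it."""
    rows: list[tuple[float, str, bool]] = []
    for tl in timelines:
        e0 = _epoch_s(tl.start)
        hours: dict[float, list[float]] = {}
        for iv in tl.intervals:
            a, b = e0 + iv.start_s, e0 + iv.end_s
            h = math.floor(a / 3600.0) * 3600.0
            while h < b:
                overlap = min(b, h + 3600.0) - max(a, h)
                acc = hours.setdefault(h, [0.0, 0.0])
                acc[0] += overlap
                if iv.state is ComplianceState.NONCOMPLIANT:
                    acc[1] += overlap
                h += 3600.0
        for h, (monitored, noncompliant) in hours.items():
            if monitored >= min_hour_fraction * 3600.0:
                rows.append((h, tl.patient_id, noncompliant == 0.0))
    rows.sort()
    return rows


def block_adherence(
    timelines: Sequence[ComplianceTimeline],
    block_h: int = 100,
    min_hour_fraction: float = 0.5,
) -> np.ndarray:
    """Turn-protocol adherence per consecutive block of ``block_h``
    patient-monitoring hours.

    Patient-hours are ordered chronologically (ties broken by patient
    id), chunked into blocks, and each block reports the fraction of its
    hours that were 100% compliant; a trailing partial block is dropped.
    """
    if block_h < 1:
        raise ValueError("block_h must be >= 1")
    rows = _patient_hours(timelines, min_hour_fraction)
    n_blocks = len(rows) // block_h
    if n_blocks == 0:
        raise ValueError(
            f"need at least {block_h} monitored patient-hours, got {len(rows)}"
        )
    ok = np.array([r[2] for r in rows[: n_blocks * block_h]], dtype=float)
    return ok.reshape(n_blocks, block_h).mean(axis=1)


def hourly_profile(
    timelines: Sequence[ComplianceTimeline], exempt_policy: str = "as_compliant"
) -> tuple[np.ndarray, np.ndarray]:
    """Compliant and monitored seconds pooled into 24 hour-of-day bins."""
    if exempt_policy not in _EXEMPT_POLICIES:
        raise ValueError(f"exempt_policy must be one of {_EXEMPT_POLICIES}")
    compliant = np.zeros(24)
    monitored = np.zeros(24)
    for tl in timelines:
        e0 = _epoch_s(tl.start)
        for iv in tl.intervals:
            if iv.state is ComplianceState.EXEMPT and exempt_policy == "exclude":
                continue
            credit = iv.state is not ComplianceState.NONCOMPLIANT
            a, b = e0 + iv.start_s, e0 + iv.end_s
            h = math.floor(a / 3600.0) * 3600.0
            while h < b:
                overlap = min(b, h + 3600.0) - max(a, h)
                bin_idx = int((h % 86400.0) // 3600.0)
                monitored[bin_idx] += overlap
                if credit:
                    compliant[bin_idx] += overlap
                h += 3600.0
    return compliant, monitored


def hourly_compliance(
    timelines: Sequence[ComplianceTimeline], exempt_policy: str = "as_compliant"
) -> np.ndarray:
    """Average compliance for each hour of the day (24 values).

    Bins with no monitored time report NaN rather than zero.
    """
    compliant, monitored = hourly_profile(timelines, exempt_policy)
    with np.errstate(invalid="ignore"):
        out = np.where(monitored > 0, compliant / np.maximum(monitored, 1e-300), np.nan)
    return out


@dataclass
class PhaseSummary:
    """Aggregated compliance results for one study phase."""

    phase: str
    n_patients: int
    monitored_h: float
    pooled_compliance: float
    per_patient_compliance: list[float]
    block_adherence: list[float]
    hourly_compliance: list[float]  # NaN for empty bins
    records: list[PatientRecord] = field(default_factory=list)


def phase_summary(
    timelines: Sequence[ComplianceTimeline],
    records: Iterable[PatientRecord] = (),
    phase: str = "baseline",
    block_h: int = 100,
    exempt_policy: str = "as_compliant",
) -> PhaseSummary:
    """Compute all three compliance statistics for one phase.

    Block adherence is reported empty when the phase holds fewer than
    ``block_h`` monitored patient-hours.
    """
    per_patient = [patient_compliance(tl, exempt_policy) for tl in timelines]
    try:
        blocks = list(block_adherence(timelines, block_h))
    except ValueError:
        blocks = []
    return PhaseSummary(
        phase=phase,
        n_patients=len(timelines),
        monitored_h=sum(tl.monitored_s for tl in timelines) / 3600.0,
        pooled_compliance=phase_compliance(timelines, exempt_policy),
        per_patient_compliance=per_patient,
        block_adherence=[float(b) for b in blocks],
        hourly_compliance=[float(v) for v in hourly_compliance(timelines, exempt_policy)],
        records=list(records),
    )
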