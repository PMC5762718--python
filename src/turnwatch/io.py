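"""CSV readers/writers and provenance hashing.

All files are plain UTF-8 comma-separated text with a header row and an
optional leading ``# config_hash=...`` comment carrying a SHA-256 digest
of the run configuration.  Traces carry both an ISO-8601 absolute
timestamp and the integer relative second, so files are self-describing
and round-trip exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timedelta
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import (
    ComplianceState,
    ComplianceTimeline,
    Display,
    ExemptionInterval,
    ExemptionReason,
    PatientRecord,
    PatientTrace,
    TimelineInterval,
)

_TRACE_COLUMNS = ["patient_id", "timestamp", "t_s", "angle_deg", "posture"]
_EXEMPTION_COLUMNS = ["patient_id", "start_s", "end_s", "reason"]
_RECORD_COLUMNS = [
    "patient_id", "phase", "age", "sex", "braden", "isolation", "monitored_h", "start",
]
_TIMELINE_COLUMNS = ["patient_id", "start", "start_s", "end_s", "state", "display"]

_ISO = "%Y-%m-%dT%H:%M:%S"


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Enum):
        return obj.value
    if isinstance(obj, datetime):
        return obj.strftime(_ISO)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def config_hash(*configs) -> str:
    """SHA-256 digest of the canonical JSON form of the given configs."""
    payload = json.dumps([_jsonable(c) for c in configs], sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def _write_frame(df: pd.DataFrame, path, cfg_hash: str | None) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        if cfg_hash:
            fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, index=False)


def _read_frame(path, required: Sequence[str], what: str) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{what} file {path} is empty") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what} file {path} is missing columns: {missing}")
    if df.empty:
        raise ValueError(f"{what} file {path} contains no rows")
    return df


# --- traces ----------------------------------------------------------------

def write_trace_csv(
    traces: Iterable[PatientTrace], path, cfg_hash: str | None = None
) -> None:
    frames = []
    for tr in traces:
        stamps = [
            (tr.start + timedelta(seconds=int(t))).strftime(_ISO) for t in tr.t_s
        ]
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": tr.patient_id,
                    "timestamp": stamps,
                    "t_s": tr.t_s,
                    "angle_deg": tr.angle_deg,
                    "posture": np.where(tr.upright, "upright", "in_bed"),
                }
            )
        )
    if not frames:
        raise ValueError("no traces to write")
    _write_frame(pd.concat(frames, ignore_index=True), path, cfg_hash)


def read_trace_csv(path) -> list[PatientTrace]:
    """Read traces; raises ``ValueError`` on missing columns, empty files,
    unsorted or duplicated timestamps (naming the offending row)."""
    df = _read_frame(path, _TRACE_COLUMNS, "trace")
    bad_posture = ~df["posture"].isin(["in_bed", "upright"])
    if bad_posture.any():
        row = int(df.index[bad_posture][0])
        raise ValueError(f"unknown posture value at data row {row}")
    traces = []
    for pid, g in df.groupby("patient_id", sort=False):
        t = g["t_s"].to_numpy(dtype=np.int64)
        if t.size > 1:
            diffs = np.diff(t)
            if np.any(diffs <= 0):
                row = int(g.index[int(np.flatnonzero(diffs <= 0)[0]) + 1])
                kind = "duplicate" if diffs[diffs <= 0][0] == 0 else "out-of-order"
                raise ValueError(
                    f"{kind} timestamp for patient {pid!r} at data row {row}"
                )
        first = datetime.strptime(str(g["timestamp"].iloc[0]), _ISO)
        start = first - timedelta(seconds=int(t[0]))
        traces.append(
            PatientTrace(
                patient_id=str(pid),
                start=start,
                t_s=t,
                angle_deg=g["angle_deg"].to_numpy(dtype=float),
                upright=(g["posture"] == "upright").to_numpy(),
            )
        )
    return traces


# --- exemptions ------------------------------------------------------------

def write_exemptions_csv(
    exemptions: dict[str, Sequence[ExemptionInterval]], path,
    cfg_hash: str | None = None,
) -> None:
    rows = [
        {
            "patient_id": pid,
            "start_s": ex.start_s,
            "end_s": ex.end_s,
            "reason": ex.reason.value,
        }
        for pid, exs in exemptions.items()
        for ex in exs
    ]
    df = pd.DataFrame(rows, columns=_EXEMPTION_COLUMNS)
    _write_frame(df, path, cfg_hash)


def read_exemptions_csv(path) -> dict[str, list[ExemptionInterval]]:
    try:
        df = _read_frame(path, _EXEMPTION_COLUMNS, "exemption")
    except ValueError as err:
        if "no rows" in str(err):
            return {}
        raise
    out: dict[str, list[ExemptionInterval]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["patient_id"]), []).append(
            ExemptionInterval(
                float(row["start_s"]),
                float(row["end_s"]),
                ExemptionReason(row["reason"]),
            )
        )
    return out


# --- patient records -------------------------------------------------------

def write_records_csv(
    records: Iterable[PatientRecord], path, cfg_hash: str | None = None
) -> None:
    rows = [
        {
            "patient_id": r.patient_id,
            "phase": r.phase,
            "age": r.age,
            "sex": r.sex,
            "braden": r.braden,
            "isolation": r.isolation,
            "monitored_h": r.monitored_h,
            "start": r.start.strftime(_ISO) if r.start else "",
        }
        for r in records
    ]
    _write_frame(pd.DataFrame(rows, columns=_RECORD_COLUMNS), path, cfg_hash)


def read_records_csv(path) -> list[PatientRecord]:
    df = _read_frame(path, _RECORD_COLUMNS, "record")
    records = []
    for _, row in df.iterrows():
        start = (
            datetime.strptime(str(row["start"]), _ISO)
            if isinstance(row["start"], str) and row["start"]
            else None
        )
        records.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                phase=str(row["phase"]),
                age=int(row["age"]),
                sex=str(row["sex"]),
                braden=int(row["braden"]),
                isolation=bool(row["isolation"]),
                monitored_h=float(row["monitored_h"]),
                start=start,
            )
        )
    return records


# --- timelines -------------------------------------------------------------

def write_timeline_csv(
    timelines: Iterable[ComplianceTimeline], path, cfg_hash: str | None = None
) -> None:
    rows = [
        {
            "patient_id": tl.patient_id,
            "start": tl.start.strftime(_ISO),
            "start_s": iv.start_s,
            "end_s": iv.end_s,
            "state": iv.state.value,
            "display": iv.display.value,
        }
        for tl in timelines
        for iv in tl.intervals
    ]
    _write_frame(pd.DataFrame(rows, columns=_TIMELINE_COLUMNS), path, cfg_hash)


def read_timeline_csv(path) -> list[ComplianceTimeline]:
    df = _read_frame(path, _TIMELINE_COLUMNS, "timeline")
    out = []
    for pid, g in df.groupby("patient_id", sort=False):
        start = datetime.strptime(str(g["start"].iloc[0]), _ISO)
        intervals = [
            TimelineInterval(
                float(r["start_s"]),
                float(r["end_s"]),
                ComplianceState(r["state"]),
                Display(r["display"]),
            )
            for _, r in g.iterrows()
        ]
        out.append(ComplianceTimeline(str(pid), start, intervals))
    return out
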