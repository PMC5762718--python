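"""Turn-detection and compliance engine.

Transforms a 10-s position trace into sustained-position intervals, turn
events, and a compliance/display timeline, following the monitoring-system
rules used on the study unit:

* the patient loads one of three in-bed regions (left / back / right),
  classified from the roll angle against a turn-angle threshold
  (default 20 degrees; the boundary angles belong to the back region);
* each region carries a *sustained-load clock* that accrues while the
  region is loaded and resets only once the region has been continuously
  offloaded for the decompression time (default 15 min) — an excursion
  shorter than that is not a real turn, and the clock resumes where it
  left off when the patient settles back;
* compliance: the patient is non-compliant from the instant the current
  region's clock reaches the turn period plus the grace period
  (default 120 + 15 = 135 min) until a qualifying turn resets it;
* display: the nurses'-station colour ignores the grace period — green
  below 105 min sustained, yellow from 105 min, red from 120 min.

Documented exemption intervals override the state to EXEMPT (display
blank); the underlying clocks keep running, so non-compliance resumes
after an exemption ends if the patient still has not turned.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import (
    BED_REGIONS,
    ComplianceState,
    ComplianceTimeline,
    Display,
    ExemptionInterval,
    PatientTrace,
    Posture,
    Region,
    TimelineInterval,
    TurnEvent,
)

# integer codes used internally for vectorised classification
_LEFT, _BACK, _RIGHT, _UPRIGHT = 0, 1, 2, 3
_CODE_TO_REGION = {
    _LEFT: Region.LEFT,
    _BACK: Region.BACK,
    _RIGHT: Region.RIGHT,
    _UPRIGHT: Region.UPRIGHT,
}


@dataclass(frozen=True)
class EngineConfig:
    """Tunable thresholds of the turn-detection engine.

    Defaults are the study-unit configuration: a 120-min turn period with
    a 15-min grace period applied to the compliance metric only, a 15-min
    decompression requirement, a 20-degree turn-angle threshold and a
    green display window of 105 min.  ``debounce_min`` suppresses
    single-sample region flicker; ``max_gap_min`` is the longest sensor
    dropout bridged before time is treated as unmonitored.
    """

    turn_period_min: float = 120.0
    grace_min: float = 15.0
    decompression_min: float = 15.0
    angle_threshold_deg: float = 20.0
    green_window_min: float = 105.0
    sample_interval_s: float = 10.0
    debounce_min: float = 1.0
    max_gap_min: float = 5.0

    def __post_init__(self) -> None:
        if not 0 < self.green_window_min < self.turn_period_min:
            raise ValueError("need 0 < green_window_min < turn_period_min")
        if self.grace_min < 0:
            raise ValueError("grace_min must be >= 0")
        if self.decompression_min <= 0:
            raise ValueError("decompression_min must be > 0")
        if self.angle_threshold_deg <= 0:
            raise ValueError("angle_threshold_deg must be > 0")
        if self.sample_interval_s <= 0:
            raise ValueError("sample_interval_s must be > 0")
        if self.debounce_min < 0:
            raise ValueError("debounce_min must be >= 0")
        if self.max_gap_min <= 0:
            raise ValueError("max_gap_min must be > 0")

    # second-valued views used throughout the engine
    @property
    def turn_period_s(self) -> float:
        return self.turn_period_min * 60.0

    @property
    def limit_s(self) -> float:
        """Sustained seconds at which non-compliance begins."""
        return (self.turn_period_min + self.grace_min) * 60.0

    @property
    def green_window_s(self) -> float:
        return self.green_window_min * 60.0

    @property
    def decompression_s(self) -> float:
        return self.decompression_min * 60.0

    @property
    def debounce_s(self) -> float:
        return self.debounce_min * 60.0

    @property
    def max_gap_s(self) -> float:
        return self.max_gap_min * 60.0


@dataclass(frozen=True)
class RegionInterval:
    """A sustained stay in one region, ``[start_s, end_s)``."""

    start_s: float
    end_s: float
    region: Region

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def classify_region(
    angle_deg: float,
    posture: Posture | str = Posture.IN_BED,
    threshold_deg: float = 20.0,
) -> Region:
    """Classify a single reading into a body region.

    Right side: angle strictly greater than ``+threshold``; left side:
    strictly less than ``-threshold``; the closed band in between,
    including both boundary angles, is the back.  An upright posture flag
    overrides the angle entirely.
    """
    if not np.isfinite(angle_deg):
        raise ValueError(f"non-finite roll angle: {angle_deg!r}")
    if Posture(posture) is Posture.UPRIGHT:
        return Region.UPRIGHT
    if angle_deg > threshold_deg:
        return Region.RIGHT
    if angle_deg < -threshold_deg:
        return Region.LEFT
    return Region.BACK


def _classify_codes(
    angle_deg: np.ndarray, upright: np.ndarray, threshold_deg: float
) -> np.ndarray:
    if not np.all(np.isfinite(angle_deg)):
        bad = int(np.flatnonzero(~np.isfinite(angle_deg))[0])
        raise ValueError(f"non-finite roll angle at sample index {bad}")
    codes = np.full(angle_deg.shape, _BACK, dtype=np.int8)
    codes[angle_deg > threshold_deg] = _RIGHT
    codes[angle_deg < -threshold_deg] = _LEFT
    codes[upright] = _UPRIGHT
    return codes


def _dwell_ends(t: np.ndarray, config: EngineConfig) -> tuple[np.ndarray, np.ndarray]:
    """End time of each sample's dwell and indices where a segment ends.

    A reading is held until the next one arrives; gaps longer than
    ``max_gap_min`` are not bridged — the dwell ends one sample interval
    after the reading and a new monitored segment starts at the next one.
    """
    delta = config.sample_interval_s
    ends = np.empty(t.shape, dtype=float)
    if t.size > 1:
        diffs = np.diff(t).astype(float)
        ends[:-1] = np.where(diffs <= config.max_gap_s, t[1:], t[:-1] + delta)
        break_after = np.flatnonzero(diffs > config.max_gap_s)
    else:
        break_after = np.array([], dtype=int)
    ends[-1] = t[-1] + delta
    return ends, break_after


def _debounce(
    runs: list[tuple[float, float, int]], debounce_s: float
) -> list[tuple[float, float, int]]:
    """Absorb region runs shorter than the debounce window into the
    surrounding region.  The first run establishes the starting region
    regardless of its length."""
    cur_s, cur_e, cur_c = runs[0]
    out: list[tuple[float, float, int]] = []
    for s, e, c in runs[1:]:
        if c == cur_c:
            cur_e = e
        elif e - s >= debounce_s:
            out.append((cur_s, cur_e, cur_c))
            cur_s, cur_e, cur_c = s, e, c
        else:
            cur_e = e  # excursion too short to register; absorb
    out.append((cur_s, cur_e, cur_c))
    return out


def segment_regions(
    trace: PatientTrace, config: EngineConfig = EngineConfig()
) -> list[RegionInterval]:
    """Debounce a raw trace into sustained-region intervals.

    Returns ordered intervals; within a monitored segment they are
    contiguous, and a jump between consecutive intervals marks an
    unmonitored gap.
    """
    t = trace.t_s.astype(float)
    codes = _classify_codes(trace.angle_deg, trace.upright, config.angle_threshold_deg)
    ends, break_after = _dwell_ends(t, config)

    intervals: list[RegionInterval] = []
    seg_starts = np.concatenate([[0], break_after + 1])
    seg_stops = np.concatenate([break_after, [t.size - 1]])
    for lo, hi in zip(seg_starts, seg_stops):
        seg_codes = codes[lo : hi + 1]
        change = np.flatnonzero(np.diff(seg_codes)) + lo
        run_first = np.concatenate([[lo], change + 1])
        run_last = np.concatenate([change, [hi]])
        runs = [
            (t[i], float(ends[j]), int(codes[i]))
            for i, j in zip(run_first, run_last)
        ]
        for s, e, c in _debounce(runs, config.debounce_s):
            intervals.append(RegionInterval(s, e, _CODE_TO_REGION[c]))
    return intervals


def _segment_ends(intervals: Sequence[RegionInterval]) -> list[float]:
    """For each interval, the end time of its monitored segment."""
    ends = [0.0] * len(intervals)
    seg_end = intervals[-1].end_s
    for i in range(len(intervals) - 1, -1, -1):
        if i < len(intervals) - 1 and intervals[i + 1].start_s > intervals[i].end_s:
            seg_end = intervals[i].end_s
        ends[i] = seg_end
    return ends


def detect_turns(
    region_intervals: Sequence[RegionInterval],
    config: EngineConfig = EngineConfig(),
) -> list[TurnEvent]:
    """Emit a TurnEvent for every in-bed region change.

    A turn qualifies when the vacated region stays continuously offloaded
    for the decompression time (time spent upright counts as offloading).
    If monitoring ends before decompression could be observed, the turn
    is conservatively non-qualifying.  Transitions into or out of the
    upright posture are not turns.
    """
    ivs = list(region_intervals)
    if not ivs:
        return []
    seg_ends = _segment_ends(ivs)
    events: list[TurnEvent] = []
    for i in range(1, len(ivs)):
        prev, cur = ivs[i - 1], ivs[i]
        if cur.start_s > prev.end_s:  # unmonitored gap, no observable turn
            continue
        if prev.region not in BED_REGIONS or cur.region not in BED_REGIONS:
            continue
        t0 = cur.start_s
        reoccupied = None
        j = i
        while j < len(ivs):
            if j > i and ivs[j].start_s > ivs[j - 1].end_s:
                break  # offload observation censored by a gap
            if ivs[j].region is prev.region:
                reoccupied = ivs[j].start_s
                break
            j += 1
        offload_end = reoccupied if reoccupied is not None else seg_ends[i]
        qualifying = offload_end - t0 >= config.decompression_s
        events.append(
            TurnEvent(
                t_change_s=t0,
                from_region=prev.region,
                to_region=cur.region,
                qualifying=qualifying,
                t_qualified_s=t0 + config.decompression_s if qualifying else None,
            )
        )
    return events


def display_state(
    sustained_min: float, config: EngineConfig = EngineConfig()
) -> Display:
    """Nurses'-station colour for a given sustained time on one side.

    Green below the green window (turned within the past 105 min), yellow
    once the green window is reached (a turn is due within 15 min), red
    once the full turn period has elapsed.  The grace period plays no
    part here.
    """
    if sustained_min < 0:
        raise ValueError("sustained_min must be non-negative")
    if sustained_min < config.green_window_min:
        return Display.GREEN
    if sustained_min < config.turn_period_min:
        return Display.YELLOW
    return Display.RED


def _validate_exemptions(
    exemptions: Sequence[ExemptionInterval],
) -> list[ExemptionInterval]:
    exs = sorted(exemptions, key=lambda e: e.start_s)
    for a, b in zip(exs, exs[1:]):
        if b.start_s < a.end_s:
            raise ValueError(
                f"overlapping exemption intervals: [{a.start_s}, {a.end_s}] "
                f"and [{b.start_s}, {b.end_s}]"
            )
    return exs


def _apply_exemptions(
    pieces: list[TimelineInterval], exemptions: Sequence[ExemptionInterval]
) -> list[TimelineInterval]:
    if not exemptions:
        return pieces
    exs = _validate_exemptions(exemptions)
    bounds = [(e.start_s, e.end_s) for e in exs]
    out: list[TimelineInterval] = []
    for piece in pieces:
        cursor = piece.start_s
        for es, ee in bounds:
            if ee <= cursor or es >= piece.end_s:
                continue
            a, b = max(es, cursor), min(ee, piece.end_s)
            if a > cursor:
                out.append(TimelineInterval(cursor, a, piece.state, piece.display))
            out.append(TimelineInterval(a, b, ComplianceState.EXEMPT, Display.NONE))
            cursor = b
        if cursor < piece.end_s:
            out.append(TimelineInterval(cursor, piece.end_s, piece.state, piece.display))
    return out


def _merge_pieces(pieces: list[TimelineInterval]) -> list[TimelineInterval]:
    merged: list[TimelineInterval] = []
    for p in pieces:
        if p.end_s <= p.start_s:
            continue
        if (
            merged
            and merged[-1].end_s == p.start_s
            and merged[-1].state is p.state
            and merged[-1].display is p.display
        ):
            merged[-1] = TimelineInterval(
                merged[-1].start_s, p.end_s, p.state, p.display
            )
        else:
            merged.append(p)
    return merged


def compliance_timeline(
    trace: PatientTrace,
    exemptions: Sequence[ExemptionInterval] | None = None,
    config: EngineConfig = EngineConfig(),
) -> ComplianceTimeline:
    """Score a trace into a compliance/display timeline.

    Every monitored instant is COMPLIANT, NONCOMPLIANT or EXEMPT:
    non-compliance starts the moment the current region's sustained-load
    clock reaches turn period + grace; upright time is compliant and
    zeroes all clocks; exemptions override the state but leave the clocks
    running.  Clocks start at zero at the trace start and after any
    unmonitored gap (no look-back).
    """
    if exemptions is None:
        exemptions = trace.exemptions
    intervals = segment_regions(trace, config)
    limit_s = config.limit_s
    red_s = config.turn_period_s
    green_s = config.green_window_s

    clocks: dict[Region, float] = {r: 0.0 for r in BED_REGIONS}
    vacated_at: dict[Region, float] = {}
    pieces: list[TimelineInterval] = []
    prev: RegionInterval | None = None

    for iv in intervals:
        if prev is not None:
            if iv.start_s > prev.end_s:  # dropout: fresh clocks, no look-back
                clocks = {r: 0.0 for r in BED_REGIONS}
                vacated_at = {}
            elif prev.region in BED_REGIONS and prev.region is not iv.region:
                vacated_at[prev.region] = prev.end_s

        if iv.region is Region.UPRIGHT:
            # standing/ambulating offloads every region
            clocks = {r: 0.0 for r in BED_REGIONS}
            vacated_at = {}
            pieces.append(
                TimelineInterval(
                    iv.start_s, iv.end_s, ComplianceState.COMPLIANT, Display.GREEN
                )
            )
        else:
            region = iv.region
            if region in vacated_at:
                if iv.start_s - vacated_at[region] >= config.decompression_s:
                    clocks[region] = 0.0
                del vacated_at[region]
            c0 = clocks[region]
            cuts = sorted(
                {
                    iv.start_s + (threshold - c0)
                    for threshold in (green_s, red_s, limit_s)
                    if c0 < threshold < c0 + iv.duration_s
                }
            )
            bounds = [iv.start_s, *cuts, iv.end_s]
            for a, b in zip(bounds[:-1], bounds[1:]):
                c = c0 + (a - iv.start_s)
                state = (
                    ComplianceState.NONCOMPLIANT
                    if c >= limit_s
                    else ComplianceState.COMPLIANT
                )
                if c >= red_s:
                    disp = Display.RED
                elif c >= green_s:
                    disp = Display.YELLOW
                else:
                    disp = Display.GREEN
                pieces.append(TimelineInterval(a, b, state, disp))
            clocks[region] = c0 + iv.duration_s
        prev = iv

    pieces = _apply_exemptions(pieces, exemptions)
    return ComplianceTimeline(trace.patient_id, trace.start, _merge_pieces(pieces))
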