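"""Unit and property tests for the turn-detection/compliance engine."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_trace
from turnwatch import (
    ComplianceState,
    Display,
    EngineConfig,
    ExemptionInterval,
    Region,
    classify_region,
    compliance_timeline,
    constant_trace,
    detect_turns,
    display_state,
    piecewise_trace,
    segment_regions,
)

MIN = 6  # samples per minute at 10-s sampling


# --- region classification -------------------------------------------------

@pytest.mark.parametrize(
    "angle,posture,expected",
    [
        (25.0, "in_bed", Region.RIGHT),
        (21.0, "in_bed", Region.RIGHT),
        (20.0, "in_bed", Region.BACK),  # boundary belongs to the back band
        (0.0, "in_bed", Region.BACK),
        (-20.0, "in_bed", Region.BACK),
        (-21.0, "in_bed", Region.LEFT),
        (-25.0, "in_bed", Region.LEFT),
        (45.0, "upright", Region.UPRIGHT),  # posture flag wins over the angle
    ],
)
def test_classify_region(angle, posture, expected):
    assert classify_region(angle, posture) is expected


def test_classify_region_rejects_nonfinite():
    with pytest.raises(ValueError):
        classify_region(float("nan"), "in_bed")


# --- segmentation / debounce -----------------------------------------------

def test_constant_hour_is_single_back_interval():
    trace = make_trace([(360, 0.0, False)])  # 1 h at 0 degrees
    intervals = segment_regions(trace)
    assert len(intervals) == 1
    iv = intervals[0]
    assert (iv.start_s, iv.end_s, iv.region) == (0.0, 3600.0, Region.BACK)


def test_single_sample_excursion_is_absorbed():
    trace = make_trace([(180, 0.0, False), (1, -30.0, False), (180, 0.0, False)])
    intervals = segment_regions(trace)
    assert len(intervals) == 1
    assert intervals[0].region is Region.BACK
    assert intervals[0].end_s - intervals[0].start_s == 3610.0


def test_sustained_change_registers():
    trace = make_trace([(180, 0.0, False), (180, -45.0, False)])
    intervals = segment_regions(trace)
    assert [iv.region for iv in intervals] == [Region.BACK, Region.LEFT]
    assert intervals[1].start_s == 1800.0


def test_empty_trace_rejected():
    with pytest.raises(ValueError):
        make_trace([])


def test_long_gap_splits_segments():
    t = np.concatenate([np.arange(60) * 10, 600 + 601 + np.arange(60) * 10])
    trace = make_trace([(120, 0.0, False)])
    trace.t_s = t.astype(np.int64)  # inject a >5-min dropout
    intervals = segment_regions(trace)
    assert len(intervals) == 2
    assert intervals[0].end_s == 600.0  # dwell ends one interval after last reading
    assert intervals[1].start_s == 1201.0


# --- turn detection ---------------------------------------------------------

def test_adequate_turn_qualifies_after_decompression():
    trace = piecewise_trace([(60, 0.0, "in_bed"), (15, -45.0, "in_bed")])
    events = detect_turns(segment_regions(trace))
    assert len(events) == 1
    ev = events[0]
    assert (ev.from_region, ev.to_region) == (Region.BACK, Region.LEFT)
    assert ev.qualifying
    assert ev.t_qualified_s == 3600.0 + 900.0


def test_under_decompressed_excursion_resumes_clock():
    # back 60 min -> left 10 min -> back: the excursion does not qualify and
    # the back clock resumes at 60 min, so non-compliance starts 75 min into
    # the return (total sustained 135 min).
    trace = piecewise_trace(
        [(60, 0.0, "in_bed"), (10, -45.0, "in_bed"), (80, 0.0, "in_bed")]
    )
    events = detect_turns(segment_regions(trace))
    assert [ev.qualifying for ev in events] == [False, True]
    timeline = compliance_timeline(trace)
    nc = [iv for iv in timeline.intervals if iv.state is ComplianceState.NONCOMPLIANT]
    assert nc and nc[0].start_s == 4200.0 + 4500.0


def test_no_region_change_no_events():
    assert detect_turns(segment_regions(constant_trace(90))) == []


# --- display state ----------------------------------------------------------

@pytest.mark.parametrize(
    "sustained_min,expected",
    [
        (0, Display.GREEN),
        (104, Display.GREEN),
        (105, Display.YELLOW),
        (110, Display.YELLOW),
        (119, Display.YELLOW),
        (120, Display.RED),
        (125, Display.RED),
    ],
)
def test_display_state(sustained_min, expected):
    assert display_state(sustained_min) is expected


def test_display_state_rejects_negative():
    with pytest.raises(ValueError):
        display_state(-1.0)


def test_display_red_while_metric_still_compliant():
    # at 125 min sustained the bar is red but the 15-min grace keeps the
    # compliance metric green
    timeline = compliance_timeline(constant_trace(125))
    assert timeline.noncompliant_s == 0.0
    assert timeline.intervals[-1].display is Display.RED


# --- compliance timeline ----------------------------------------------------

def test_no_noncompliance_before_grace_expires():
    timeline = compliance_timeline(constant_trace(134))
    assert timeline.noncompliant_s == 0.0


def test_noncompliance_starts_at_turn_period_plus_grace():
    timeline = compliance_timeline(constant_trace(200))
    nc = [iv for iv in timeline.intervals if iv.state is ComplianceState.NONCOMPLIANT]
    assert nc[0].start_s == 135 * 60.0
    assert nc[-1].end_s == timeline.intervals[-1].end_s  # red to end of monitoring


def test_exemption_override_absorbs_noncompliance():
    trace = constant_trace(200)
    span = float(trace.t_s[-1] + 10)
    exempt = [ExemptionInterval(120 * 60.0, span)]
    timeline = compliance_timeline(trace, exempt)
    assert timeline.noncompliant_s == 0.0
    assert timeline.exempt_s == span - 7200.0
    assert all(
        iv.display is Display.NONE
        for iv in timeline.intervals
        if iv.state is ComplianceState.EXEMPT
    )


def test_clocks_keep_running_under_exemption():
    # a mid-stay exemption masks the state but not the sustained clock:
    # non-compliance resumes the moment the exemption ends
    trace = constant_trace(200)
    timeline = compliance_timeline(trace, [ExemptionInterval(7200.0, 9000.0)])
    nc = [iv for iv in timeline.intervals if iv.state is ComplianceState.NONCOMPLIANT]
    assert nc[0].start_s == 9000.0


def test_overlapping_exemptions_rejected():
    trace = constant_trace(100)
    with pytest.raises(ValueError, match="overlapping"):
        compliance_timeline(
            trace, [ExemptionInterval(0.0, 600.0), ExemptionInterval(300.0, 900.0)]
        )


def test_upright_time_is_compliant_and_resets_clocks():
    trace = piecewise_trace(
        [(100, 0.0, "in_bed"), (20, 0.0, "upright"), (100, 0.0, "in_bed")]
    )
    timeline = compliance_timeline(trace)
    assert timeline.noncompliant_s == 0.0
    assert timeline.monitored_s == 220 * 60.0


def test_removing_a_qualifying_turn_never_helps():
    turned = piecewise_trace(
        [(120, 0.0, "in_bed"), (20, -45.0, "in_bed"), (60, 0.0, "in_bed")]
    )
    flat = piecewise_trace([(200, 0.0, "in_bed")])
    assert (
        compliance_timeline(flat).compliant_s
        <= compliance_timeline(turned).compliant_s
    )
    assert compliance_timeline(turned).noncompliant_s == 0.0
    assert compliance_timeline(flat).noncompliant_s == 65 * 60.0


# --- conservation property ---------------------------------------------------

region_segment = st.tuples(
    st.integers(min_value=1, max_value=120),  # samples (10 s .. 20 min)
    st.sampled_from([-45.0, -21.0, -20.0, 0.0, 20.0, 21.0, 45.0]),
    st.booleans(),
)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(region_segment, min_size=1, max_size=12))
def test_monitored_time_is_conserved(segments):
    """COMPLIANT + NONCOMPLIANT + EXEMPT time equals monitored time, and
    non-compliant instants always display red."""
    trace = make_trace(segments)
    span = float(trace.t_s[-1] + 10)
    exempt = [ExemptionInterval(0.0, min(600.0, span))]
    timeline = compliance_timeline(trace, exempt)
    total = timeline.compliant_s + timeline.noncompliant_s + timeline.exempt_s
    assert total == pytest.approx(span)
    assert timeline.monitored_s == pytest.approx(span)
    for iv in timeline.intervals:
        if iv.state is ComplianceState.NONCOMPLIANT:
            assert iv.display is Display.RED


def test_engine_config_validation():
    with pytest.raises(ValueError):
        EngineConfig(green_window_min=130.0)  # must sit below the turn period
    with pytest.raises(ValueError):
        EngineConfig(decompression_min=0.0)
    with pytest.raises(ValueError):
        EngineConfig(grace_min=-1.0)
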