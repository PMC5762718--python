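"""Tests for the compliance metrics (per-patient, pooled, block, hourly)."""

from __future__ import annotations

from datetime import datetime

import numpy as np
import pytest

from turnwatch import (
    ComplianceState,
    ComplianceTimeline,
    Display,
    TimelineInterval,
    block_adherence,
    hourly_compliance,
    patient_compliance,
    phase_compliance,
    phase_summary,
)
from turnwatch.metrics import hourly_profile

C, N, X = ComplianceState.COMPLIANT, ComplianceState.NONCOMPLIANT, ComplianceState.EXEMPT
TOP_OF_HOUR = datetime(2013, 5, 1, 8, 0, 0)


def tl(pieces, start=TOP_OF_HOUR, pid="p"):
    displays = {C: Display.GREEN, N: Display.RED, X: Display.NONE}
    return ComplianceTimeline(
        pid, start, [TimelineInterval(a, b, s, displays[s]) for a, b, s in pieces]
    )


def hours_tl(total_h, noncompliant_hours=(), pid="p", start=TOP_OF_HOUR):
    """A timeline of whole hours; the listed hour indices carry one
    non-compliant minute each."""
    pieces = []
    for h in range(total_h):
        a = h * 3600.0
        if h in noncompliant_hours:
            pieces.append((a, a + 60.0, N))
            pieces.append((a + 60.0, a + 3600.0, C))
        else:
            pieces.append((a, a + 3600.0, C))
    return tl(pieces, start=start, pid=pid)


# --- per-patient compliance -------------------------------------------------

def test_fully_compliant_patient():
    assert patient_compliance(tl([(0.0, 3600.0, C)])) == 1.0


def test_constant_side_fraction():
    # 200-min stay on one side: compliant until the 135-min onset
    timeline = tl([(0.0, 8100.0, C), (8100.0, 12000.0, N)])
    assert patient_compliance(timeline) == pytest.approx(135 / 200)


def test_exempt_time_counts_as_compliant_by_default():
    timeline = tl([(0.0, 3600.0, C), (3600.0, 5400.0, N), (5400.0, 7200.0, X)])
    assert patient_compliance(timeline) == pytest.approx((3600 + 1800) / 7200)
    assert patient_compliance(timeline, "exclude") == pytest.approx(3600 / 5400)


def test_zero_monitored_time_rejected():
    with pytest.raises(ValueError, match="zero monitored"):
        patient_compliance(tl([]))


def test_target_construction_64_percent():
    # 100 h monitored with 36 h non-compliant -> 64%
    timeline = tl([(0.0, 64 * 3600.0, C), (64 * 3600.0, 100 * 3600.0, N)])
    assert patient_compliance(timeline) == pytest.approx(0.64)


# --- pooled phase compliance -------------------------------------------------

def test_pooling_is_time_weighted_not_mean():
    p1 = tl([(0.0, 50 * 3600.0, C), (50 * 3600.0, 100 * 3600.0, N)], pid="p1")
    p2 = tl([(0.0, 10 * 3600.0, C)], pid="p2")
    pooled = phase_compliance([p1, p2])
    assert pooled == pytest.approx(60 / 110)
    naive_mean = np.mean([patient_compliance(p1), patient_compliance(p2)])
    assert pooled != pytest.approx(naive_mean)


def test_pooling_equal_hours():
    p1 = tl([(0.0, 50 * 3600.0, C), (50 * 3600.0, 100 * 3600.0, N)], pid="p1")
    p2 = tl([(0.0, 100 * 3600.0, C)], pid="p2")
    assert phase_compliance([p1, p2]) == pytest.approx(150 / 200)


def test_phase_compliance_is_weighted_mean_of_patients():
    rng = np.random.default_rng(7)
    timelines = []
    for i in range(10):
        mon = float(rng.integers(2, 50)) * 3600.0
        split = float(rng.uniform(0.2, 1.0)) * mon
        timelines.append(tl([(0.0, split, C), (split, mon, N)], pid=f"p{i}"))
    weights = np.array([t.monitored_s for t in timelines])
    values = np.array([patient_compliance(t) for t in timelines])
    assert phase_compliance(timelines) == pytest.approx(
        float((weights * values).sum() / weights.sum())
    )


def test_split_invariance():
    whole = tl([(0.0, 7200.0, C), (7200.0, 10800.0, N)])
    split = tl(
        [(0.0, 3600.0, C), (3600.0, 7200.0, C), (7200.0, 9000.0, N), (9000.0, 10800.0, N)]
    )
    assert patient_compliance(whole) == patient_compliance(split)
    assert phase_compliance([whole]) == phase_compliance([split])


# --- block adherence ---------------------------------------------------------

def test_fully_compliant_block():
    assert block_adherence([hours_tl(100)]).tolist() == [1.0]


def test_partial_block_adherence():
    bad = set(range(10, 46))  # 36 of 100 hours touched by non-compliance
    assert block_adherence([hours_tl(100, bad)]).tolist() == [pytest.approx(0.64)]


def test_trailing_partial_block_dropped():
    blocks = block_adherence([hours_tl(250)])
    assert len(blocks) == 2


def test_insufficient_hours_rejected():
    with pytest.raises(ValueError, match="patient-hours"):
        block_adherence([hours_tl(50)])


def test_blocks_pool_across_patients():
    p1 = hours_tl(60, pid="a")
    p2 = hours_tl(60, noncompliant_hours={0}, pid="b",
                  start=datetime(2013, 5, 4, 8, 0, 0))
    blocks = block_adherence([p1, p2])
    assert len(blocks) == 1
    assert blocks[0] == pytest.approx(0.99)  # 1 bad hour among the first 100


# --- hourly compliance -------------------------------------------------------

def test_fully_compliant_cohort_hourly():
    out = hourly_compliance([hours_tl(48, pid="a"), hours_tl(48, pid="b")])
    assert np.allclose(out, 1.0)


def test_night_noncompliance_depresses_night_bins():
    # start at midnight; hours 2,3 of each day carry non-compliance
    bad = {2, 3, 26, 27}
    timeline = hours_tl(48, bad, start=datetime(2013, 5, 1, 0, 0, 0))
    out = hourly_compliance([timeline])
    assert out[2] < 1.0 and out[3] < 1.0
    others = [out[h] for h in range(24) if h not in (2, 3)]
    assert np.allclose(others, 1.0)


def test_unmonitored_bins_are_nan():
    timeline = tl([(0.0, 3600.0, C)], start=datetime(2013, 5, 1, 10, 0, 0))
    out = hourly_compliance([timeline])
    assert out[10] == 1.0
    assert np.isnan(np.delete(out, 10)).all()


def test_hourly_weighted_mean_matches_phase_compliance():
    rng = np.random.default_rng(11)
    timelines = []
    for i in range(6):
        mon = float(rng.integers(5, 40)) * 3600.0
        split = float(rng.uniform(0.3, 1.0)) * mon
        start = datetime(2013, 5, 1, int(rng.integers(0, 24)), 0, 0)
        timelines.append(tl([(0.0, split, C), (split, mon, N)], start=start, pid=f"p{i}"))
    compliant, monitored = hourly_profile(timelines)
    assert compliant.sum() / monitored.sum() == pytest.approx(
        phase_compliance(timelines)
    )


# --- phase summary -----------------------------------------------------------

def test_phase_summary_shapes():
    timelines = [hours_tl(120, {5}, pid="a"), hours_tl(30, pid="b")]
    summary = phase_summary(timelines, phase="baseline")
    assert summary.n_patients == 2
    assert summary.monitored_h == pytest.approx(150.0)
    assert len(summary.block_adherence) == 1
    assert len(summary.hourly_compliance) == 24
    assert 0.0 < summary.pooled_compliance <= 1.0
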