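"""Shared fixtures and trace builders for the test suite."""

from __future__ import annotations

from datetime import datetime

import numpy as np
import pytest

from turnwatch import (
    EngineConfig,
    ExemptionInterval,
    PatientTrace,
    make_phase_regimes,
)

DELTA = 10.0


def make_trace(
    segments,
    *,
    delta=DELTA,
    start=datetime(2013, 5, 1, 8, 0, 0),
    patient_id="test",
    exemptions=(),
):
    """Trace from (n_samples, angle_deg, upright) segments on a uniform grid."""
    angles, uprights = [], []
    for count, angle, upright in segments:
        angles.append(np.full(count, float(angle)))
        uprights.append(np.full(count, bool(upright)))
    angle = np.concatenate(angles)
    t = np.arange(angle.size, dtype=np.int64) * int(delta)
    return PatientTrace(
        patient_id=patient_id,
        start=start,
        t_s=t,
        angle_deg=angle,
        upright=np.concatenate(uprights),
        exemptions=list(exemptions),
    )


def random_trace(rng, hours=24.0, delta=DELTA, upright_prob=0.05, spike_prob=0.01):
    """Random piecewise-constant region trace with noise, occasional
    exact-boundary angles and single-sample spikes, for oracle
    equivalence checks.  Uniform sampling, no gaps."""
    total_s = hours * 3600.0
    n = int(total_s / delta)
    t = np.arange(n, dtype=np.int64) * int(delta)
    angle = np.empty(n)
    upright = np.zeros(n, dtype=bool)
    base_angles = {0: -45.0, 1: 0.0, 2: 45.0}
    i = 0
    while i < n:
        dur = max(1, int(rng.exponential(2400.0) / delta))
        j = min(n, i + dur)
        if rng.random() < upright_prob:
            upright[i:j] = True
            angle[i:j] = rng.normal(0.0, 5.0, j - i)
        else:
            region = int(rng.integers(0, 3))
            angle[i:j] = base_angles[region] + rng.normal(0.0, 5.0, j - i)
        i = j
    # exact boundary values and wild single-sample spikes
    boundary = rng.random(n) < 0.01
    angle[boundary] = rng.choice([-21.0, -20.0, 20.0, 21.0], boundary.sum())
    spikes = rng.random(n) < spike_prob
    angle[spikes] = rng.uniform(-60.0, 60.0, spikes.sum())
    return PatientTrace(
        patient_id="random",
        start=datetime(2013, 6, 1, 12, 0, 0),
        t_s=t,
        angle_deg=angle,
        upright=upright,
    )


def random_exemptions(rng, total_s, delta=DELTA, max_n=3):
    """Up to ``max_n`` non-overlapping exemptions on the sample grid."""
    out = []
    cursor = 0.0
    for _ in range(int(rng.integers(0, max_n + 1))):
        gap = float(rng.uniform(0, total_s / 4))
        start = cursor + np.floor(gap / delta) * delta
        dur = np.floor(float(rng.uniform(600, 7200)) / delta) * delta
        end = min(start + dur, total_s)
        if end <= start or start >= total_s:
            break
        out.append(ExemptionInterval(start, end))
        cursor = end
    return out


@pytest.fixture(scope="session")
def study_engine():
    return EngineConfig()


@pytest.fixture(scope="session")
def calibrated_regimes():
    """Baseline/post simulation regimes calibrated to the study's pooled
    compliance levels (64% and 98%)."""
    return make_phase_regimes(0.64, 0.98)
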