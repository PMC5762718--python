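"""Independent brute-force oracles used by the test suite.

The per-sample compliance simulator walks a uniformly sampled trace one
10-s dwell at a time, updating per-region sustained-load clocks with
plain scalar arithmetic — no interval algebra — so it checks the
engine's interval-based implementation through a genuinely different
code path.  Hand-formula t and chi-square statistics serve the same role
for the stats module.
"""

from __future__ import annotations

import math

import numpy as np

L, B, R, U = 0, 1, 2, 3
COMP, NONCOMP, EXEMPT = 0, 1, 2
GREEN, YELLOW, RED, NONE = 0, 1, 2, 3

_STATE_NAME = {COMP: "compliant", NONCOMP: "noncompliant", EXEMPT: "exempt"}
_DISP_NAME = {GREEN: "green", YELLOW: "yellow", RED: "red", NONE: "none"}


def _classify(angle: float, upright: bool, threshold: float) -> int:
    if upright:
        return U
    if angle > threshold:
        return R
    if angle < -threshold:
        return L
    return B


def _debounced_codes(codes, t, delta, debounce_s):
    runs = []
    s = 0
    n = len(codes)
    for i in range(1, n + 1):
        if i == n or codes[i] != codes[s]:
            runs.append([t[s], t[i - 1] + delta, codes[s]])
            s = i
    out = [runs[0][:]]
    for start, end, code in runs[1:]:
        if code == out[-1][2]:
            out[-1][1] = end
        elif end - start >= debounce_s:
            out.append([start, end, code])
        else:
            out[-1][1] = end
    acc = np.empty(n, dtype=np.int8)
    k = 0
    for start, end, code in out:
        count = int(round((end - start) / delta))
        acc[k : k + count] = code
        k += count
    assert k == n
    return acc


def per_sample_states(trace, exemptions, config):
    """Per-dwell compliance state and display colour for a uniformly
    sampled, gap-free trace.  Returns (state codes, display codes)."""
    delta = config.sample_interval_s
    t = trace.t_s.astype(float)
    assert np.all(np.diff(t) == delta), "oracle assumes uniform sampling"
    codes = np.array(
        [
            _classify(a, bool(u), config.angle_threshold_deg)
            for a, u in zip(trace.angle_deg, trace.upright)
        ],
        dtype=np.int8,
    )
    codes = _debounced_codes(codes, t, delta, config.debounce_min * 60.0)

    limit = (config.turn_period_min + config.grace_min) * 60.0
    red = config.turn_period_min * 60.0
    green = config.green_window_min * 60.0
    decomp = config.decompression_min * 60.0

    clocks = {L: 0.0, B: 0.0, R: 0.0}
    vacated: dict[int, float] = {}
    prev = -1
    n = codes.size
    states = np.empty(n, dtype=np.int8)
    disps = np.empty(n, dtype=np.int8)
    for i in range(n):
        c = int(codes[i])
        if c == U:
            clocks = {L: 0.0, B: 0.0, R: 0.0}
            vacated = {}
            states[i] = COMP
            disps[i] = GREEN
        else:
            if prev >= 0 and prev != c and prev != U:
                vacated[prev] = t[i]
            if c in vacated:
                if t[i] - vacated[c] >= decomp:
                    clocks[c] = 0.0
                del vacated[c]
            cl = clocks[c]
            states[i] = NONCOMP if cl >= limit else COMP
            if cl >= red:
                disps[i] = RED
            elif cl >= green:
                disps[i] = YELLOW
            else:
                disps[i] = GREEN
            clocks[c] = cl + delta
        prev = c
    for ex in exemptions:
        sel = (t >= ex.start_s) & (t < ex.end_s)
        states[sel] = EXEMPT
        disps[sel] = NONE
    return states, disps


def timeline_to_samples(timeline, t):
    """Expand an engine timeline to per-dwell state/display codes, for
    direct comparison with ``per_sample_states``."""
    starts = np.array([iv.start_s for iv in timeline.intervals])
    ends = np.array([iv.end_s for iv in timeline.intervals])
    state_code = {"compliant": COMP, "noncompliant": NONCOMP, "exempt": EXEMPT}
    disp_code = {"green": GREEN, "yellow": YELLOW, "red": RED, "none": NONE}
    st = np.array([state_code[iv.state.value] for iv in timeline.intervals], dtype=np.int8)
    dp = np.array([disp_code[iv.display.value] for iv in timeline.intervals], dtype=np.int8)
    idx = np.searchsorted(starts, t.astype(float), side="right") - 1
    assert np.all(idx >= 0) and np.all(t < ends[idx]), "sample outside timeline"
    return st[idx], dp[idx]


# --- textbook-formula statistics ------------------------------------------

def student_t_oracle(a, b):
    """Pooled-variance two-sample t statistic and df, straight from the
    textbook formula."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    stat = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    return stat, float(na + nb - 2)


def welch_t_oracle(a, b):
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    stat = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    return stat, df


def chi2_oracle(table):
    """Pearson chi-square statistic from expected counts, by hand."""
    table = np.asarray(table, float)
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    expected = rows * cols / table.sum()
    return float(((table - expected) ** 2 / expected).sum())
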