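"""Synthetic cohort generator.

The sensor data behind the original pre/post comparison were never
released, so this module simulates position traces with the statistical
structure the analysis assumes: 10-s sampling of a lateral roll angle
with Gaussian noise, scheduled caregiver-assisted turns every two hours
that are each missed with a tunable probability, spontaneous self-turns
as a Poisson process, occasional "sink-back" drift in which a patient
settles out of an achieved side-lying angle, contiguous daytime
out-of-bed blocks, documented exemption intervals, and cohort
demographics resembling an adult medical unit.

``make_phase_regimes`` calibrates the caregiver miss probability by
bisection so the pooled engine-scored compliance of the two simulated
phases lands on chosen targets (e.g. 64% baseline, 98% after the
monitoring display was switched on).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta

import numpy as np

from .engine import EngineConfig, compliance_timeline
from .model import ExemptionInterval, ExemptionReason, PatientRecord, PatientTrace

#: Nominal first admission date of the simulated study window.
STUDY_START = datetime(2013, 5, 1)

_LEFT, _BACK, _RIGHT = 0, 1, 2
#: Caregiver turn rotation: left -> back -> right -> back -> ...
_CAREGIVER_CYCLE = (_LEFT, _BACK, _RIGHT, _BACK)
_BASE_ANGLE = {_LEFT: -1.0, _BACK: 0.0, _RIGHT: +1.0}


@dataclass(frozen=True)
class Demographics:
    """Distributions for the simulated patient records.

    Ages and Braden scores are drawn from clipped normals; defaults mirror
    an adult medical-unit baseline cohort (mean age 58, 47% female, mean
    Braden 20.8 with observed range 11-23, 5 of 75 patients in isolation).
    """

    age_mean: float = 58.0
    age_sd: float = 18.0
    age_min: int = 18
    age_max: int = 97
    female_prob: float = 0.47
    braden_mean: float = 20.8
    braden_sd: float = 2.2
    braden_min: int = 11
    braden_max: int = 23
    isolation_prob: float = 5 / 75


BASELINE_DEMOGRAPHICS = Demographics()
POST_DEMOGRAPHICS = Demographics(
    age_mean=63.0, female_prob=0.56, braden_mean=19.9, isolation_prob=5 / 63
)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the patient-trace simulator.

    The defaults describe the baseline study conditions: ~58 h mean stays
    (7,982 monitored hours over 138 patients), a 120-min caregiver turn
    schedule with a miss probability that reproduces the observed ~64%
    pooled baseline compliance, a modest self-turn rate, 45-degree
    side-lying angles with 5-degree sensor noise, and sparse documented
    exemptions.
    """

    n_patients: int = 75
    mean_stay_h: float = 58.0
    min_stay_h: float = 12.0  # unit inclusion criterion: >= 12 h expected stay
    sample_interval_s: float = 10.0
    self_turn_rate_per_h: float = 0.15
    caregiver_period_min: float = 120.0
    miss_probability: float = 0.62
    lateral_angle_deg: float = 45.0
    angle_noise_sd_deg: float = 5.0
    sink_back_prob: float = 0.1
    sink_back_halflife_min: float = 20.0
    exemption_rate_per_100h: float = 0.5
    upright_fraction: float = 0.05
    demographics: Demographics = field(default_factory=Demographics)
    phase: str = "baseline"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.mean_stay_h <= 0:
            raise ValueError("mean_stay_h must be > 0")
        if self.min_stay_h <= 0:
            raise ValueError("min_stay_h must be > 0")
        if self.sample_interval_s <= 0 or 60 % self.sample_interval_s != 0:
            raise ValueError("sample_interval_s must divide 60 s evenly")
        for name in ("miss_probability", "sink_back_prob", "upright_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.upright_fraction >= 1:
            raise ValueError("upright_fraction must be < 1")
        for name in ("self_turn_rate_per_h", "exemption_rate_per_100h"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.sink_back_halflife_min <= 0:
            raise ValueError("sink_back_halflife_min must be > 0")
        if self.caregiver_period_min <= 0:
            raise ValueError("caregiver_period_min must be > 0")
        if self.phase not in ("baseline", "post"):
            raise ValueError("phase must be 'baseline' or 'post'")


def _truncated_exponential(rng: np.random.Generator, mean: float, floor: float) -> float:
    """Exponential stay length conditioned on exceeding the floor."""
    for _ in range(1000):
        draw = rng.exponential(mean)
        if draw >= floor:
            return draw
    return floor


def _quantize(x: float, delta: float) -> float:
    return math.floor(x / delta) * delta


def simulate_patient(
    config: SimulationConfig,
    patient_seed: int,
    patient_id: str | None = None,
) -> tuple[PatientTrace, PatientRecord]:
    """Simulate one patient's stay.

    All randomness derives from ``patient_seed`` through independent
    sub-streams (stay length, turn schedule, self-turns, sensor noise,
    demographics, exemptions, out-of-bed blocks), so holding the seed
    fixed while varying one parameter leaves the other draws aligned —
    raising ``miss_probability`` only adds misses, it never reshuffles
    the rest of the stay.
    """
    ss = np.random.SeedSequence(patient_seed)
    r_stay, r_sched, r_self, r_noise, r_demo, r_exempt, r_up = (
        np.random.default_rng(child) for child in ss.spawn(7)
    )
    delta = config.sample_interval_s

    stay_h = _truncated_exponential(r_stay, config.mean_stay_h, config.min_stay_h)
    n = max(1, int(stay_h * 3600 // delta))
    stay_s = n * delta

    # admission moment (whole seconds, daytime hours)
    day = int(r_demo.integers(0, 120))
    sod = int(r_demo.integers(8 * 3600, 20 * 3600))
    start = STUDY_START + timedelta(days=day, seconds=sod)

    # --- latent region sequence -------------------------------------------
    period_s = config.caregiver_period_min * 60.0
    sched = np.arange(period_s, stay_s, period_s)
    u_sched = r_sched.random((sched.size, 2))
    n_self = int(r_self.poisson(config.self_turn_rate_per_h * stay_s / 3600.0))
    self_t = np.sort(r_self.uniform(0.0, stay_s, n_self))
    u_self = r_self.random(n_self)

    events = sorted(
        [(float(t), 0, k) for k, t in enumerate(sched)]
        + [(_quantize(float(t), delta), 1, j) for j, t in enumerate(self_t)]
    )

    seg_start: list[float] = [0.0]
    seg_code: list[int] = [_BACK]
    seg_sink: list[bool] = [False]
    cur = _BACK
    ptr = 0
    for t_ev, kind, idx in events:
        if t_ev >= stay_s:
            break
        if kind == 0:  # scheduled caregiver turn
            u_miss, u_sink = u_sched[idx]
            if u_miss < config.miss_probability:
                continue  # nobody came
            target = _CAREGIVER_CYCLE[ptr]
            ptr = (ptr + 1) % len(_CAREGIVER_CYCLE)
            if target == cur:
                target = _CAREGIVER_CYCLE[ptr]
                ptr = (ptr + 1) % len(_CAREGIVER_CYCLE)
            sink = bool(u_sink < config.sink_back_prob) and target != _BACK
        else:  # self-turn to a uniformly random different region
            others = [c for c in (_LEFT, _BACK, _RIGHT) if c != cur]
            target = others[min(int(u_self[idx] * 2), 1)]
            sink = False
        if target != cur:
            seg_start.append(t_ev)
            seg_code.append(target)
            seg_sink.append(sink)
            cur = target

    # --- emission ----------------------------------------------------------
    t = (np.arange(n, dtype=np.int64) * int(delta)).astype(np.int64)
    starts = np.asarray(seg_start)
    codes = np.asarray(seg_code)
    idx = np.searchsorted(starts, t.astype(float), side="right") - 1
    base = np.array([_BASE_ANGLE[_LEFT], _BASE_ANGLE[_BACK], _BASE_ANGLE[_RIGHT]])
    angle = base[codes[idx]] * config.lateral_angle_deg

    # sink-back: the achieved lateral angle decays linearly toward flat,
    # halving at the configured half-life (gone entirely at twice it)
    halflife_s = config.sink_back_halflife_min * 60.0
    for k, sinking in enumerate(seg_sink):
        if not sinking:
            continue
        s0 = starts[k]
        s1 = starts[k + 1] if k + 1 < starts.size else stay_s
        sel = (t >= s0) & (t < s1)
        factor = np.clip(1.0 - (t[sel] - s0) / (2.0 * halflife_s), 0.0, 1.0)
        angle[sel] = angle[sel] * factor

    if config.angle_noise_sd_deg > 0:
        angle = angle + r_noise.normal(0.0, config.angle_noise_sd_deg, n)

    # --- out-of-bed blocks (contiguous daytime ambulation) ----------------
    upright = np.zeros(n, dtype=bool)
    if config.upright_fraction > 0:
        block_len = _quantize(config.upright_fraction * 86400.0, delta)
        start_sod = float(sod)
        day_k = 0
        while True:
            day_origin = day_k * 86400.0 - start_sod
            if day_origin >= stay_s:
                break
            w0 = day_origin + 8 * 3600.0
            w1 = day_origin + 20 * 3600.0 - block_len
            u = float(r_up.uniform())  # draw regardless, to keep streams aligned
            if w1 > w0 and block_len > 0:
                b0 = _quantize(w0 + u * (w1 - w0), delta)
                b1 = b0 + block_len
                lo, hi = max(b0, 0.0), min(b1, stay_s)
                if hi > lo:
                    upright[(t >= lo) & (t < hi)] = True
            day_k += 1

    # --- documented exemption intervals -----------------------------------
    exemptions: list[ExemptionInterval] = []
    n_ex = int(r_exempt.poisson(config.exemption_rate_per_100h * stay_h / 100.0))
    if n_ex > 0:
        ex_starts = np.sort(r_exempt.uniform(0.0, stay_s, n_ex))
        ex_durs = r_exempt.uniform(1800.0, 5400.0, n_ex)
        reasons = r_exempt.integers(0, len(ExemptionReason), n_ex)
        last_end = 0.0
        reason_list = list(ExemptionReason)
        for s, d, r in zip(ex_starts, ex_durs, reasons):
            s = _quantize(float(s), delta)
            e = min(_quantize(float(s + d), delta), stay_s)
            if s < last_end or e <= s:
                continue
            exemptions.append(ExemptionInterval(s, e, reason_list[int(r)]))
            last_end = e

    # --- demographics ------------------------------------------------------
    demo = config.demographics
    age = int(round(float(np.clip(r_demo.normal(demo.age_mean, demo.age_sd),
                                  demo.age_min, demo.age_max))))
    sex = "F" if r_demo.random() < demo.female_prob else "M"
    braden = int(round(float(np.clip(r_demo.normal(demo.braden_mean, demo.braden_sd),
                                     demo.braden_min, demo.braden_max))))
    isolation = bool(r_demo.random() < demo.isolation_prob)

    pid = patient_id or f"{config.phase}-{patient_seed % 1_000_000:06d}"
    trace = PatientTrace(
        patient_id=pid,
        start=start,
        t_s=t,
        angle_deg=angle,
        upright=upright,
        exemptions=exemptions,
    )
    record = PatientRecord(
        patient_id=pid,
        phase=config.phase,
        age=age,
        sex=sex,
        braden=braden,
        isolation=isolation,
        monitored_h=stay_s / 3600.0,
        start=start,
    )
    return trace, record


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[PatientTrace], list[PatientRecord]]:
    """Simulate a full phase cohort; per-patient seeds spawn
    deterministically from ``config.seed``."""
    if config.n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_patients)
    traces: list[PatientTrace] = []
    records: list[PatientRecord] = []
    for i, child in enumerate(children):
        pseed = int(child.generate_state(1, np.uint64)[0] % (2**31))
        tr, rec = simulate_patient(
            config, pseed, patient_id=f"{config.phase}-{i:03d}"
        )
        traces.append(tr)
        records.append(rec)
    return traces, records


def pooled_cohort_compliance(
    config: SimulationConfig, engine_config: EngineConfig = EngineConfig()
) -> float:
    """Simulate a cohort and return its pooled engine-scored compliance."""
    from .metrics import phase_compliance  # local import, avoids cycle at import time

    traces, _ = simulate_cohort(config)
    timelines = [compliance_timeline(tr, tr.exemptions, engine_config) for tr in traces]
    return phase_compliance(timelines)


def make_phase_regimes(
    target_low: float,
    target_high: float,
    *,
    base_config: SimulationConfig | None = None,
    engine_config: EngineConfig | None = None,
    n_baseline: int = 75,
    n_post: int = 63,
    calibration_n: int = 40,
    calibration_seed: int = 1_305_001,
    tol: float = 0.01,
    max_iter: int = 12,
) -> tuple[SimulationConfig, SimulationConfig]:
    """Calibrate baseline/post simulation regimes to pooled-compliance targets.

    Pooled engine compliance is monotone non-increasing in the caregiver
    miss probability, so a bisection over ``miss_probability`` (evaluated
    on a fixed-seed calibration cohort of ``calibration_n`` patients)
    finds regimes whose pooled compliance approximates ``target_low`` and
    ``target_high``.  Raises ``ValueError`` when a target lies well
    outside the achievable range or the targets are mis-ordered.
    """
    if not 0 < target_low < target_high <= 1:
        raise ValueError(
            f"need 0 < target_low < target_high <= 1, got "
            f"({target_low}, {target_high})"
        )
    base = base_config if base_config is not None else SimulationConfig()
    eng = engine_config if engine_config is not None else EngineConfig()

    cache: dict[float, float] = {}

    def pooled(m: float) -> float:
        if m not in cache:
            cfg = replace(
                base,
                miss_probability=m,
                n_patients=calibration_n,
                seed=calibration_seed,
            )
            cache[m] = pooled_cohort_compliance(cfg, eng)
        return cache[m]

    c_best = pooled(0.0)  # compliance with no missed turns
    c_worst = pooled(1.0)  # compliance on self-turns alone
    slack = 0.05

    def solve(target: float) -> float:
        if target >= c_best:
            if target - c_best > slack:
                raise ValueError(
                    f"target compliance {target:.3f} unattainable: even with no "
                    f"missed turns the regime reaches only {c_best:.3f}"
                )
            return 0.0
        if target <= c_worst:
            if c_worst - target > slack:
                raise ValueError(
                    f"target compliance {target:.3f} unattainable: even with "
                    f"every scheduled turn missed the regime stays at "
                    f"{c_worst:.3f}"
                )
            return 1.0
        lo, hi = 0.0, 1.0  # pooled(lo) >= target >= pooled(hi)
        best_err, best_m = abs(c_best - target), 0.0
        for _ in range(max_iter):
            mid = 0.5 * (lo + hi)
            val = pooled(mid)
            if abs(val - target) < best_err:
                best_err, best_m = abs(val - target), mid
            if best_err <= tol:
                break
            if val > target:
                lo = mid
            else:
                hi = mid
        return best_m

    m_baseline = solve(target_low)
    m_post = solve(target_high)

    baseline = replace(
        base,
        miss_probability=m_baseline,
        phase="baseline",
        n_patients=n_baseline,
        demographics=BASELINE_DEMOGRAPHICS,
    )
    post = replace(
        base,
        miss_probability=m_post,
        phase="post",
        n_patients=n_post,
        demographics=POST_DEMOGRAPHICS,
        seed=base.seed + 1,
    )
    return baseline, post


# ---------------------------------------------------------------------------
# deterministic trace builders (used by tests, examples and sweeps)
# ---------------------------------------------------------------------------

def piecewise_trace(
    segments: list[tuple[float, float, str]],
    *,
    sample_interval_s: float = 10.0,
    start: datetime | None = None,
    patient_id: str = "trace",
    include_final_reading: bool = False,
) -> PatientTrace:
    """Build a noiseless trace from ``(duration_min, angle_deg, posture)``
    segments sampled on the regular grid.

    The monitored span equals the summed durations; with
    ``include_final_reading`` one extra reading extends the final segment
    by a single sample interval, so the trace observes the patient *at*
    the nominal end mark rather than one interval before it.
    """
    delta = sample_interval_s
    ts: list[np.ndarray] = []
    angles: list[np.ndarray] = []
    uprights: list[np.ndarray] = []
    t0 = 0.0
    for duration_min, angle, posture in segments:
        count = int(round(duration_min * 60.0 / delta))
        if count <= 0:
            raise ValueError("segment shorter than one sample interval")
        seg_t = t0 + np.arange(count) * delta
        ts.append(seg_t)
        angles.append(np.full(count, float(angle)))
        uprights.append(np.full(count, posture == "upright"))
        t0 = float(seg_t[-1] + delta)
    if include_final_reading:
        ts.append(np.array([t0]))
        angles.append(np.array([float(segments[-1][1])]))
        uprights.append(np.array([segments[-1][2] == "upright"]))
    return PatientTrace(
        patient_id=patient_id,
        start=start or datetime(2013, 5, 1, 8, 0, 0),
        t_s=np.concatenate(ts).astype(np.int64),
        angle_deg=np.concatenate(angles),
        upright=np.concatenate(uprights),
    )


def constant_trace(
    duration_min: float,
    angle_deg: float = 0.0,
    **kwargs,
) -> PatientTrace:
    """A constant-position in-bed trace observed through the
    ``duration_min`` mark (readings at t = 0, 10, ..., 60*duration s)."""
    return piecewise_trace(
        [(duration_min, angle_deg, "in_bed")], include_final_reading=True, **kwargs
    )
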