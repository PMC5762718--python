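# Methods

## The monitoring model

A wearable chest sensor reports a patient's roll angle every 10 s. The
engine reduces that stream to which of three in-bed regions is bearing
weight — right side (angle > +20°), back (−20° … +20°, boundaries
inclusive), left side (angle < −20°) — with an upright/out-of-bed
posture flag overriding the angle. A *turn* is a change of region; it is
*qualifying* only if the vacated region then stays continuously
offloaded for the decompression time (15 min). The protocol allows at
most 120 min (the turn period) sustained on any one region; the
compliance metric adds a 15-min grace period, so non-compliant time
accrues from the instant 135 sustained minutes are reached. The bedside
display ignores the grace period: green below 105 sustained minutes,
yellow from 105, red from 120.

### Sustained-time semantics

Each in-bed region carries its own sustained-load clock. The clock
accrues while the region is loaded and resets only when the region's own
continuous offload reaches the decompression time; an excursion shorter
than that (rocking, a half-turn that slides back) does not qualify, and
the clock *resumes* where it left off. Without resumption, brief
wiggling would trivially reset the 120-min clock and the metric would be
meaningless. One consequence of per-region accounting: a qualifying turn
into a region that was itself vacated less than 15 min ago resumes that
region's clock rather than restarting it — the tissue on that side was
never relieved.

Upright time is compliant and zeroes all three clocks: standing or
ambulating offloads every recumbent surface. Clocks start at zero at the
trace start and after any unmonitored gap (no look-back). Sampling gaps
up to 5 min are bridged by holding the last reading; longer dropouts are
excluded from monitored time entirely.

Boundary conventions are half-open and consistent across the two state
machines: the compliance state switches at sustained = 135 min exactly,
the display turns yellow at 105 and red at 120 exactly. Because the
non-compliance threshold lies at or above the red threshold, every
non-compliant instant displays red (the display is strictly the more
alarmist of the two).

### Exemptions

A documented reason a turn could not be performed (refusal, off-unit,
clinical contraindication) masks the affected span as EXEMPT with a
blank display. The clocks keep running underneath: if the exemption ends
and the patient still has not turned, non-compliance resumes
immediately. By default exempt time stays in monitored time and counts
as compliant-equivalent ("a missed turn with a documented reason has no
negative impact"); `exempt_policy="exclude"` removes it from both
numerator and denominator instead.

## Engine implementation and its oracle

The engine is interval-based: samples are classified, merged into runs,
debounced (a new region must persist ≥ 1 min to register; shorter
excursions are absorbed into the surrounding region), and the clock
arithmetic is done on intervals, splitting them analytically at the
105/120/135-min crossings. The test suite replays randomized 24-h traces
through an independent per-sample simulator that advances one 10-s dwell
at a time and demands bit-exact agreement of every dwell's state and
colour. With the default thresholds all lying on the 10-s grid, the two
formulations must agree exactly, and they do (1,000 traces in the
acceptance suite).

## Compliance metrics

* **Per-patient compliance** — compliant time / monitored time.
* **Pooled phase compliance** — summed compliant time / summed monitored
  time, i.e. the monitored-time-weighted mean of the per-patient values
  (not their plain mean; the two differ whenever stays differ in
  length).
* **Turn-protocol adherence** — wall-clock patient-hours are ordered
  chronologically (ties by patient id) and chunked into consecutive
  blocks of 100; each block reports the fraction of its hours containing
  zero non-compliant time. An hour counts for a patient only if they
  were monitored for at least 30 min of it; the trailing partial block
  is dropped. The hour grid is aligned to the top of the wall-clock
  hour, not to trace starts.
* **Average hourly compliance** — compliant over monitored time pooled
  into 24 hour-of-day bins across patients and days; an unmonitored bin
  reports NaN, never 0.

Note that block adherence is a much stricter statistic than pooled
compliance (one non-compliant minute voids a whole hour), so a cohort at
64% pooled compliance sits near 50% block adherence.

## Synthetic cohort

No patient data were released, so the generator emulates the data's
structure:

* **Stays**: exponential with mean 58 h, conditioned on ≥ 12 h (the
  unit's inclusion criterion). 75 baseline + 63 post patients at these
  stay lengths give on the order of the study's ~8,000 monitored hours.
* **Caregiver turns** every 120 min on a fixed left → back → right →
  back rotation (skipping the current region), each independently missed
  with probability `miss_probability` — the single dial separating the
  two phases.
* **Self-turns** as a Poisson process (default 0.15/h) to a uniformly
  random different region; the sensor cannot distinguish self- from
  assisted turns, and neither does the generator downstream.
* **Angles**: back ≈ 0°, sides ≈ ±45°, Gaussian sensor noise (sd 5°).
* **Sink-back**: with probability 0.1 per caregiver turn to a side, the
  achieved angle decays linearly toward flat, halving at 20 min — the
  silent failure mode in which a patient settles back into the pillows
  and the offload never registers.
* **Out-of-bed time**: one contiguous daytime block per day totalling
  `upright_fraction` (default 5%) of the day.
* **Exemptions**: Poisson at 0.5 per 100 h, 30–90 min long,
  non-overlapping.
* **Demographics**: ages and Braden scores from clipped normals matching
  the two phase cohorts (means 58/63 years, Braden 20.8/19.9 with sd
  2.2 on the 11–23 observed range, 47%/56% female, ~5 isolation patients
  per phase).

Every patient draws from seven independent sub-streams spawned from the
patient seed, so raising the miss probability with seeds held fixed only
adds misses without reshuffling anything else; pooled compliance is
consequently monotone in the miss probability, which is what makes the
calibration well-posed.

### Regime calibration

`make_phase_regimes(target_low, target_high)` bisects the miss
probability against pooled engine compliance evaluated on a fixed-seed
40-patient calibration cohort (tolerance 1 pp, ≤ 12 iterations). The
published pooled levels (64% baseline, 98% post) calibrate to miss ≈
0.62 and ≈ 0. With no missed turns the simulated ceiling is ≈ 96.6%
rather than 100%: sink-back occasionally hides a turn and the simulator
deliberately has no "nurse responds to the red bar" feedback loop, so
the post regime approaches the 98% target from below, within the ±5 pp
calibration band. Targets outside the achievable range raise an error
rather than silently clamping.

### What the generator does not model

No nurse/ward agent behaviour (misses are i.i.d. rather than
workload-clustered), no bed exits or falls, no pressure-injury
incidence, no circadian structure in turning quality beyond the daytime
ambulation block. Passing tests therefore demonstrate that the engine,
metrics and inference behave correctly on data with this structure — not
that the simulated effect sizes would be observed on a real ward.

## Inference

The primary comparison is a two-sample t test on *per-patient*
compliance fractions (a test needs per-unit observations; the pooled
fraction is a single number). Student's pooled-variance variant,
two-tailed, is the default; Welch and a one-sided variant
(alternative: post > baseline) are available. Degenerate zero-variance
inputs return the documented limits (statistic 0, p = 1 when means
agree; p → 0 otherwise). The sex comparison is a Pearson chi-square test
of independence on the 2×2 phase-by-sex table without continuity
correction; the Braden comparison is the same two-tailed Student t. The
isolation subgroup (~5 per phase) runs the same t test but is flagged
underpowered in the report whenever a phase has fewer than 10 isolation
patients. The sample-size formula n = Z²·sd²/e² truncates (63 from
1.96, 0.5, 0.123); a ceiling variant is available by flag.

## Numerical and design choices

* Thresholds are compared half-open as described above; all default
  thresholds are multiples of the 10-s sample interval, so interval
  splits land on the grid.
* `constant_trace(D)` includes the reading *at* the D-minute mark
  (readings t = 0 … 60·D s): observing a sustained duration of exactly D
  requires the sample at D. `piecewise_trace` spans exactly the stated
  durations.
* Sample size uses a 1e-12 relative guard before truncation so exact
  ratios are not lost to floating point.
* Turn qualification censored by end of monitoring (offload still in
  progress) is conservatively non-qualifying.
* CSV round-trips are exact: shortest-repr float writing with
  round-trip float parsing, ISO-8601 whole-second timestamps.
* The problem sizes used by the test suite (40-patient calibration
  cohorts, 20 end-to-end replicates, 1,000 oracle traces, 10,000 null
  replicates for type-I calibration) keep the whole suite under a few
  minutes on one core while leaving Monte-Carlo error well inside the
  asserted tolerances.

## Known limitations

* The baseline cohort is simulated with the same mechanism as the post
  cohort; real baseline non-compliance is surely not i.i.d. per
  scheduled turn.
* Block adherence depends on the (unstated in any source) ordering of
  patient-hours; chronological ordering was chosen and is a documented
  convention, not a finding.
* The engine's resumption-across-failed-excursions rule and the
  upright-resets-clocks rule are deliberate modelling choices where the
  commercial system's behaviour is not public; both are isolated behind
  `EngineConfig` and the timeline semantics documented above.
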