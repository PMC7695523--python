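# Methods

## The problem and the model

People with COPD suffer acute exacerbations — deteriorations in respiratory
health beyond normal day-to-day variation — and earlier treatment is
associated with faster recovery. The pipeline implemented here asks whether
home telemonitoring can give objective early warning. Each patient is
monitored at home with a pulse oximeter under one of two designs:

* **once-daily arm** — a single morning spot reading of heart rate (HR) and
  oxygen saturation (SpO2), before medication and after rest;
* **overnight arm** — a wrist oximeter worn through the night, sampling HR
  and SpO2 every 4 seconds (~6,300 samples over a 7-hour night), collapsed
  to one nightly summary value.

All patients additionally keep a daily diary card with the CAT symptom score
(0–40 points) and peak expiratory flow (PEF, L/min).

The statistical core is per-patient standardization. After discarding the
first monitored week (run-in, while patients learn the equipment), a 14-day
*stable window* defines, per variable, a baseline mean `x̄` and sample SD
`s` (n−1 denominator). Every daily value `X` becomes a Z score

    Z = (X − x̄) / s

so one threshold applies to all variables and all patients: a day is
*abnormal* when `|Z| ≥ 1.96`, the nominal 95% band of the stable state. A
*composite oximetry score* `Z_HR − Z_SpO2` pools the two unidirectional
signatures of an exacerbation (HR up, SpO2 down). For symptoms, a separate
raw-points criterion flags days on which CAT exceeds the baseline mean by at
least the minimal clinically important difference (2 points).

Day 0 is the day exacerbation treatment (oral corticosteroids or
antibiotics) started. Event-aligned series run over day indices −14..+13; a
variable's *lead time* is `−(first abnormal day in −14..0)`, the days of
warning it would have provided. Event-level performance contrasts crossings
in the pre-event fortnight (sensitivity) with crossings in a second,
disjoint stable fortnight (specificity and PPV, standard definitions).

## Eligibility and window conventions

* Patients without a fully observed 14-consecutive-day stable window (all
  four variables, post-run-in, before the pre-event fortnight) are excluded
  (`insufficient_stable_data`). The window used is the *first* fully
  observed span; a window with gaps would make the baseline SD undefined,
  so "the fortnight with fewest missing values" reduces to this rule.
* Event patients with ≥2 consecutive missing days during days −14..−1 are
  excluded (`consecutive_missing_preexacerbation`). Single missing days are
  tolerated and left missing — no imputation.
* Nights are attributed to the waking morning's date (the date of the final
  sample), aligning them with the once-daily morning protocol. The nightly
  statistic is the arithmetic mean of valid samples (median via config).
* The second stable window is the fortnight immediately after the baseline
  window, truncated if necessary so it cannot touch the pre-event
  fortnight; flags there are computed over its observed days.
* Day −15 in all event-aligned output is a display convention (the stable
  mean, Z = 0 by construction) and never enters statistics or detection.
* The recovery phase is days +1..+13; day 0 is summarized separately
  (configurable via `post_phase_includes_day0`).
* The pre-event detection window is −14..0 inclusive by default
  (configurable), and a single abnormal day suffices to flag a patient
  (`consecutive_days_required` offers stricter k-consecutive-day flagging
  for false-alarm control).
* Samples with HR outside 20–250 beats/min or SpO2 outside 50–100% are
  retained but flagged invalid and excluded from aggregation, keeping QC
  counts auditable. Detection is two-sided by default, with a directional
  option (up for HR/CAT/composite, down for SpO2/PEF).
* No multiple-testing adjustment is applied anywhere; reports state this.

## The synthetic cohort

The package ships a generator so every stage runs with no external data. It
emulates first and second moments, prodromal drift, recovery, measurement
design and missingness — not full physiology.

Per-variable stable levels and day-to-day SDs (generator defaults):

| variable | once-daily | overnight |
|---|---|---|
| HR (beats/min) | 77.1 (SD 3.6) | 70.0 (SD 1.8) |
| SpO2 (%) | 94.0 (SD 0.81) | 91.0 (SD 0.36) |
| CAT (points) | 15.6 (SD 1.46) | same (diary, both arms) |
| PEF (L/min) | 214 (SD 13.8) | same (diary, both arms) |

An exacerbation adds a piecewise-linear effect: zero before
`−prodrome_days` (default 7), a linear ramp to the maximal effect at day 0
(+10 beats/min overnight / +7 once-daily for HR; −1.2% / −2.0% for SpO2;
+7 CAT points; −34 L/min PEF), then a linear decay to zero over
`recovery_days` (default 13). The linear ramp is the simplest shape
consistent with group trajectories that drift gradually and cross the
threshold several days before treatment; it is configurable in length.

Overnight nights are i.i.d. Gaussian samples around the night's level
(within-night SD 8 beats/min and 2% — the latter matching the devices'
stated accuracy), quantized to integer beats/min and integer %, which is
the granularity the devices emit. Averaging ~6,300 samples reduces
within-night noise to ~0.1 beats/min, so the overnight arm's day-to-day SD
is essentially its night-level SD — the arms' signal-to-noise difference
emerges from the measurement design rather than being hard-coded per arm.
Spot readings are likewise quantized; a `spot_noise_sd_*` knob adds extra
morning measurement noise (default 0, since the configured once-daily SDs
already describe spot-reading variability).

Two generator choices deserve emphasis:

* **HR–SpO2 day-level correlation** (`stable_corr_hr_spo2`, default 0.72).
  With independent day-level fluctuations the composite score's stable SD
  would be √2 times a single variable's, and essentially every patient
  would cross ±1.96 at some point in a stable fortnight — contradicting the
  observed behaviour of stable composite scores, where roughly a quarter of
  patients cross in two weeks. A shared day effect (activity, temperature,
  measurement context moving HR and SpO2 together) shrinks the composite's
  stable variance; 0.72 reproduces a ~27% stable-fortnight crossing
  probability under the estimated-baseline analysis. The sign and size of
  this correlation are the generator's least-constrained assumptions.
* **CAT day-to-day SD 1.46.** Published group tables can mix group-mean
  SEM-style SDs with within-patient day-to-day SDs; the generator always
  uses day-to-day variability (what the Z denominator estimates).

Single event per patient (monitoring stops after recovery from the first
exacerbation). Event treatment days fall 49–56 days after monitoring start,
leaving run-in, baseline fortnight and the second stable fortnight disjoint
from the pre-event fortnight. Non-event patients are monitored for 56 days
by default — a deliberately compressed stand-in for the study design's
up-to-six-months follow-up that still contains every analysis window.
Missingness drops whole days independently (default 3%), plus an occasional
forced 2-day gap in the pre-event fortnight (default probability 5%) so the
exclusion rules are exercised. Randomness derives from one root seed with
per-patient child streams keyed by patient index, so cohorts are
byte-reproducible and effect-size changes leave noise draws untouched
(enabling matched-seed monotonicity checks).

What the generator does **not** model: circadian structure, autocorrelated
noise, apnea or artifact bursts, reporting biases in diary cards, or
between-patient heterogeneity in baselines beyond the arm-level means.
Passing tests therefore demonstrate the pipeline's statistical machinery
and the direction of design effects — not clinical performance on real
recordings.

## Numerical and statistical choices

* Sample SD with n−1 denominator throughout; zero-variance baselines raise
  an error rather than flooring the SD.
* Quantization to device granularity slightly inflates realized day-to-day
  SDs for low-SD quantized variables (e.g. once-daily SpO2 realizes ~0.85
  against a configured 0.81); nightly means are unaffected. For the same
  reason false-alarm calibration is evaluated on the overnight arm's
  nightly means, which are effectively continuous.
* With the baseline estimated from 14 days, the realized two-sided
  false-alarm rate at 1.96 exceeds the nominal 5% (a Student-t effect,
  ~8% per patient-day); the calibration analysis reports both the
  known-baseline and estimated-baseline rates.
* Lead-time quartiles use the (n+1)-position convention of clinical tables;
  censored patients (no crossing before treatment) are excluded from
  medians and counted separately.
* Omnibus phase comparisons use ANOVA, switching to Kruskal-Wallis when a
  Shapiro normality check fails (or when forced); pairwise comparisons are
  unadjusted t / Mann-Whitney tests; variability comparisons use a
  two-sided variance-ratio F test; lead-time comparisons use Wilcoxon
  (paired, within patients) and Mann-Whitney (between arms). Degenerate
  inputs (constant groups, all-censored arms, empty denominators) yield
  p = 1, `None`, or an explicit "undefined" rather than NaN surprises.
* Event-level 2×2 tables use the standard definitions
  sens = TP/(TP+FN), spec = TN/(TN+FP), PPV = TP/(TP+FP), with counts
  always surfaced alongside the fractions.

## Problem sizes used in the checks

The shipped test suite and `scripts/acceptance.py` run the study conditions
at 200 patients (100 per arm) for cohort-level checks, 110 no-event
overnight patients × ~107 post-run-in days (>20,000 patient-days) for
false-alarm calibration, and 1–2-hour synthetic nights for unit-level
fixtures where full nights add nothing. These sizes are the package's own
choice of a cohort large enough for stable medians and Monte-Carlo rates
while keeping a full run in tens of seconds.

## Known limitations

* Synthetic-only validation; no real device recordings are bundled.
* The composite score's false-alarm behaviour hinges on the assumed HR–SpO2
  day-level correlation (see above).
* Naive local dates; no time zones, daylight-saving handling, or sleep
  staging. Night attribution assumes nights end by 06:00.
* Patient-level trajectories from any particular study (peak Z magnitudes,
  published lead-time medians, specificity/PPV) depend on raw clinical data
  and are not reproduced by simulation; the generator only encodes their
  levels, variabilities and directions.
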