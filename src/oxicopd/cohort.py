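"""Synthetic monitoring cohort with two pulse-oximetry arms.

The generator emulates the statistical structure the detection analysis
assumes.  Each patient carries

* a stable baseline per variable (heart rate, SpO2, CAT, PEF) with Gaussian
  day-to-day fluctuation; heart-rate and SpO2 day levels are correlated
  (``stable_corr_hr_spo2``), which governs how often the composite oximetry
  score strays outside its nominal band during stable fortnights;
* for the overnight arm, a 4-second within-night sample stream (i.i.d.
  Gaussian around the night's level, quantized to integer beats/min and
  integer %) whose nightly mean almost eliminates within-night noise;
* for the once-daily arm, a single quantized morning spot reading per day;
* for event patients, a linear prodromal drift over ``prodrome_days`` that
  peaks on the treatment day (day 0) and decays linearly to zero over
  ``recovery_days``;
* day-level missingness, plus (for event patients) an occasional 2-day run of
  missing data inside the pre-exacerbation fortnight so the downstream
  exclusion rules are exercised.

Randomness derives from one root seed: patient ``i`` owns child streams
spawned from ``SeedSequence([seed, i])`` in a fixed order, so regenerating a
cohort with the same seed is byte-identical, and changing an effect size
(e.g. ``delta_hr_overnight``) leaves every noise draw untouched.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from datetime import date, timedelta
from pathlib import Path
from typing import Iterator, Optional

import numpy as np

from .config import SimConfig
from .errors import DataError
from .io import (
    ARM_ONCE_DAILY,
    ARM_OVERNIGHT,
    CAT,
    HR,
    PEF,
    SPO2,
    VARIABLES,
    DiaryEntry,
    OximetryRecording,
    PatientRecord,
    write_diary,
    write_manifest,
    write_oximetry,
)

#: event patients start no earlier than run-in (7) + baseline fortnight (14)
#: + a second stable fortnight (14) after monitoring begins
_MIN_EVENT_OFFSET = 35
_EVENT_JITTER_DAYS = 8


@dataclass(frozen=True)
class PatientTruth:
    """Ground truth for one simulated patient."""

    patient_id: str
    arm: str
    has_event: bool
    treatment_day: Optional[date]
    true_baselines: dict[str, float]
    true_sds: dict[str, float]
    true_deltas: dict[str, float]


def _arm_params(config: SimConfig, arm: str) -> tuple[dict, dict, dict]:
    if arm == ARM_OVERNIGHT:
        base = {
            HR: config.baseline_hr_overnight,
            SPO2: config.baseline_spo2_overnight,
        }
        sd = {HR: config.sd_hr_overnight, SPO2: config.sd_spo2_overnight}
        delta = {HR: config.delta_hr_overnight, SPO2: config.delta_spo2_overnight}
    else:
        base = {
            HR: config.baseline_hr_once_daily,
            SPO2: config.baseline_spo2_once_daily,
        }
        sd = {HR: config.sd_hr_once_daily, SPO2: config.sd_spo2_once_daily}
        delta = {HR: config.delta_hr_once_daily, SPO2: config.delta_spo2_once_daily}
    base.update({CAT: config.baseline_cat, PEF: config.baseline_pef})
    sd.update({CAT: config.sd_cat, PEF: config.sd_pef})
    delta.update({CAT: config.delta_cat, PEF: config.delta_pef})
    return base, sd, delta


def exacerbation_profile(
    day_offset: float, variable: str, config: SimConfig, arm: str = ARM_OVERNIGHT
) -> float:
    """Additive prodrome/recovery effect at ``day_offset`` from treatment day.

    Zero before ``-prodrome_days``, a linear ramp to the variable's maximal
    effect at day 0, then a linear return to zero at ``+recovery_days``.
    Units are the variable's own (beats/min, %, points, L/min); the sign
    follows the configured delta (positive for HR and CAT, negative for SpO2
    and PEF).
    """
    if variable not in VARIABLES:
        raise DataError(f"unknown variable '{variable}'")
    _, _, deltas = _arm_params(config, arm)
    delta = deltas[variable]
    p, r = config.prodrome_days, config.recovery_days
    if day_offset < -p or day_offset > r:
        return 0.0
    if day_offset <= 0:
        return delta * (1.0 + day_offset / p)
    return delta * (1.0 - day_offset / r)


def _patient_id(index: int) -> str:
    return f"P{index + 1:04d}"


def _missingness_rng(config: SimConfig, patient_id: str) -> np.random.Generator:
    # keyed on the patient id so the op is reproducible standalone
    tag = zlib.crc32(patient_id.encode())
    return np.random.default_rng(np.random.SeedSequence([config.seed, 1 << 20, tag]))


def inject_missingness(record: PatientRecord, config: SimConfig) -> PatientRecord:
    """Drop whole monitored days from a record, deterministically per seed.

    Each day is dropped independently with ``missing_day_prob``; for event
    patients, with probability ``consecutive_miss_prob`` an additional run of
    two consecutive days inside the pre-exacerbation fortnight (days -14..-1)
    is removed.
    """
    days = sorted(
        {e.date for e in record.diary}
        | {r.morning_date for r in record.recordings}
    )
    if not days:
        return record
    rng = _missingness_rng(config, record.patient_id)
    u = rng.uniform(size=len(days))
    dropped = {d for d, x in zip(days, u) if x < config.missing_day_prob}
    run_draw = rng.uniform()
    run_start = int(rng.integers(-14, -1))  # run covers run_start, run_start+1
    if record.treatment_day is not None and run_draw < config.consecutive_miss_prob:
        dropped.add(record.treatment_day + timedelta(days=run_start))
        dropped.add(record.treatment_day + timedelta(days=run_start + 1))
    if not dropped:
        return record
    return replace(
        record,
        recordings=[r for r in record.recordings if r.morning_date not in dropped],
        diary=[e for e in record.diary if e.date not in dropped],
    )


def _simulate_patient(
    index: int, arm: str, has_event: bool, config: SimConfig
) -> tuple[PatientRecord, PatientTruth]:
    pid = _patient_id(index)
    streams = np.random.SeedSequence([config.seed, index]).spawn(4)
    rng_assign = np.random.default_rng(streams[0])
    rng_day = np.random.default_rng(streams[1])
    rng_night = np.random.default_rng(streams[2])
    rng_diary = np.random.default_rng(streams[3])

    base, sd, delta = _arm_params(config, arm)

    if has_event:
        t_off = (
            _MIN_EVENT_OFFSET
            + max(config.prodrome_days, 14)
            + int(rng_assign.integers(0, _EVENT_JITTER_DAYS))
        )
        n_days = t_off + config.recovery_days + 1
        treatment_day = config.monitoring_start + timedelta(days=t_off)
    else:
        t_off = None
        n_days = config.monitoring_days_no_event
        treatment_day = None

    offsets = np.arange(n_days)
    profile = {v: np.zeros(n_days) for v in VARIABLES}
    if has_event:
        for v in VARIABLES:
            profile[v] = np.array(
                [exacerbation_profile(d - t_off, v, config, arm) for d in offsets]
            )

    # correlated day-level fluctuation of HR and SpO2 (shared physiological
    # day effect); CAT and PEF fluctuate independently
    z_hr = rng_day.standard_normal(n_days)
    z_ind = rng_day.standard_normal(n_days)
    rho = config.stable_corr_hr_spo2
    z_sp = rho * z_hr + np.sqrt(max(0.0, 1.0 - rho * rho)) * z_ind
    hr_level = base[HR] + sd[HR] * z_hr + profile[HR]
    sp_level = base[SPO2] + sd[SPO2] * z_sp + profile[SPO2]

    cat_vals = base[CAT] + sd[CAT] * rng_diary.standard_normal(n_days) + profile[CAT]
    pef_vals = base[PEF] + sd[PEF] * rng_diary.standard_normal(n_days) + profile[PEF]
    cat_vals = np.clip(np.rint(cat_vals), 0, 40).astype(int)
    pef_vals = np.clip(np.rint(pef_vals), 0, None).astype(int)

    day0 = np.datetime64(config.monitoring_start)
    recordings: list[OximetryRecording] = []
    if arm == ARM_OVERNIGHT:
        n_samp = config.samples_per_night
        step = np.timedelta64(config.sample_interval_s, "s")
        # nights end at 06:00 of the attributed (waking) day
        night_span = np.timedelta64(int(round(config.night_length_h * 3600)), "s")
        hr_noise = rng_night.standard_normal((n_days, n_samp))
        sp_noise = rng_night.standard_normal((n_days, n_samp))
        hr_samples = np.rint(
            hr_level[:, None] + config.within_night_sd_hr * hr_noise
        ).astype(np.int16)
        sp_samples = np.clip(
            np.rint(sp_level[:, None] + config.within_night_sd_spo2 * sp_noise),
            0,
            100,
        ).astype(np.int16)
        rel = np.arange(n_samp) * step
        for k in range(n_days):
            morning = (day0 + k).astype("datetime64[s]")
            start = morning + np.timedelta64(6 * 3600, "s") - night_span
            recordings.append(
                OximetryRecording(
                    patient_id=pid,
                    timestamps=start + rel,
                    heart_rate=hr_samples[k],
                    spo2=sp_samples[k],
                )
            )
    else:
        spot_hr = np.rint(
            hr_level + config.spot_noise_sd_hr * rng_night.standard_normal(n_days)
        ).astype(int)
        spot_sp = np.clip(
            np.rint(
                sp_level
                + config.spot_noise_sd_spo2 * rng_night.standard_normal(n_days)
            ),
            0,
            100,
        ).astype(int)
        for k in range(n_days):
            stamp = (day0 + k).astype("datetime64[s]") + np.timedelta64(
                8 * 3600, "s"
            )
            recordings.append(
                OximetryRecording(
                    patient_id=pid,
                    timestamps=np.array([stamp]),
                    heart_rate=np.array([spot_hr[k]]),
                    spo2=np.array([spot_sp[k]]),
                )
            )

    diary = [
        DiaryEntry(
            date=config.monitoring_start + timedelta(days=int(k)),
            cat=int(cat_vals[k]),
            pef=float(pef_vals[k]),
        )
        for k in range(n_days)
    ]
    record = PatientRecord(
        patient_id=pid,
        arm=arm,
        recordings=recordings,
        diary=diary,
        treatment_day=treatment_day,
        monitoring_start=config.monitoring_start,
    )
    record = inject_missingness(record, config)
    truth = PatientTruth(
        patient_id=pid,
        arm=arm,
        has_event=has_event,
        treatment_day=treatment_day,
        true_baselines=dict(base),
        true_sds=dict(sd),
        true_deltas=dict(delta),
    )
    return record, truth


def _assignments(config: SimConfig) -> list[tuple[str, bool]]:
    n = config.n_patients
    n_over = int(round(config.arm_split * n))
    plan = []
    for arm, size in ((ARM_OVERNIGHT, n_over), (ARM_ONCE_DAILY, n - n_over)):
        k_events = int(round(config.exacerbation_fraction * size))
        plan.extend((arm, j < k_events) for j in range(size))
    return plan


def iter_cohort(config: SimConfig) -> Iterator[tuple[PatientRecord, PatientTruth]]:
    """Yield simulated patients one at a time (memory-friendly for large runs)."""
    for index, (arm, has_event) in enumerate(_assignments(config)):
        yield _simulate_patient(index, arm, has_event, config)


def simulate_cohort(
    config: SimConfig,
) -> tuple[list[PatientRecord], list[PatientTruth]]:
    """Simulate the full cohort; reproducible given ``config.seed``."""
    records, truths = [], []
    for record, truth in iter_cohort(config):
        records.append(record)
        truths.append(truth)
    return records, truths


def write_truth(truths: list[PatientTruth], path) -> None:
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["patient_id", "arm", "has_event", "treatment_day"]
            + [f"baseline_{v}" for v in VARIABLES]
            + [f"sd_{v}" for v in VARIABLES]
            + [f"delta_{v}" for v in VARIABLES]
        )
        for t in truths:
            writer.writerow(
                [
                    t.patient_id,
                    t.arm,
                    int(t.has_event),
                    t.treatment_day.isoformat() if t.treatment_day else "",
                ]
                + [t.true_baselines[v] for v in VARIABLES]
                + [t.true_sds[v] for v in VARIABLES]
                + [t.true_deltas[v] for v in VARIABLES]
            )


def write_cohort(config: SimConfig, outdir) -> tuple[Path, Path, Path, Path]:
    """Simulate and write ``oximetry.csv``, ``diary.csv``, ``manifest.csv``
    and ``truth.csv`` under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, truths = simulate_cohort(config)
    paths = (
        outdir / "oximetry.csv",
        outdir / "diary.csv",
        outdir / "manifest.csv",
        outdir / "truth.csv",
    )
    write_oximetry(records, paths[0])
    write_diary(records, paths[1])
    write_manifest(records, paths[2])
    write_truth(truths, paths[3])
    return paths
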