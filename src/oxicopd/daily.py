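"""From raw recordings to QC'd one-value-per-day series.

Overnight sample streams are collapsed to a nightly summary statistic
(arithmetic mean of valid samples by default) attributed to the waking
morning's date, which aligns the two arms on a common daily grid.  The first
monitored week (equipment run-in) is removed from every series.  Eligibility
follows two rules: a patient must have a fully observed 14-consecutive-day
stable window for every variable before the pre-exacerbation fortnight, and
an event patient must not have two or more consecutive missing days during
days -14..-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Mapping, Optional

import numpy as np

from .errors import DataError
from .io import (
    ARM_OVERNIGHT,
    CAT,
    HR,
    PEF,
    SPO2,
    VARIABLES,
    OximetryRecording,
    PatientRecord,
)

RUN_IN_DAYS = 7
STABLE_WINDOW_DAYS = 14
#: event-aligned day indices: -14..-1 pre, 0 treatment start, +1..+13 recovery
DAY_INDEX_MIN = -14
DAY_INDEX_MAX = 13

REASON_INSUFFICIENT_STABLE = "insufficient_stable_data"
REASON_CONSECUTIVE_MISSING = "consecutive_missing_preexacerbation"


@dataclass
class DailySeries:
    """One value per calendar day for a single variable."""

    patient_id: str
    variable: str
    values: dict[date, float] = field(default_factory=dict)
    n_samples: dict[date, int] = field(default_factory=dict)


@dataclass
class AlignedSeries:
    """Day-indexed values relative to treatment start (day 0)."""

    patient_id: str
    variable: str
    values: dict[int, float] = field(default_factory=dict)


@dataclass
class EligibilityResult:
    patient_id: str
    eligible: bool
    reasons: list[str] = field(default_factory=list)


def aggregate_night(
    recording: OximetryRecording,
    attribution: str = "morning",
    statistic: str = "mean",
) -> Optional[tuple[date, float, float, int]]:
    """Collapse one night (or spot reading) to ``(date, HR, SpO2, n_valid)``.

    Samples flagged invalid by the physiologic range check are excluded; a
    night with zero valid samples is reported missing (``None``).
    """
    if len(recording) == 0:
        return None
    mask = recording.valid
    n_valid = int(mask.sum())
    if n_valid == 0:
        return None
    agg = np.median if statistic == "median" else np.mean
    hr = float(agg(np.asarray(recording.heart_rate, dtype=float)[mask]))
    sp = float(agg(np.asarray(recording.spo2, dtype=float)[mask]))
    if attribution == "evening":
        day = recording.start_date
    else:
        day = recording.morning_date
    return day, hr, sp, n_valid


def build_daily_series(
    patient: PatientRecord, nightly_statistic: str = "mean"
) -> dict[str, DailySeries]:
    """Build the four per-day series for a patient, dropping the run-in week.

    HR and SpO2 come from :func:`aggregate_night` (the once-daily arm's
    single spot reading is the degenerate one-sample case); CAT and PEF come
    from the diary.  Days earlier than ``monitoring_start + 7`` are removed.
    """
    if patient.monitoring_start is None:
        raise DataError(f"patient {patient.patient_id} has no monitoring_start")
    cutoff = patient.monitoring_start + timedelta(days=RUN_IN_DAYS)
    series = {
        v: DailySeries(patient_id=patient.patient_id, variable=v)
        for v in VARIABLES
    }
    for rec in patient.recordings:
        agg = aggregate_night(rec, statistic=nightly_statistic)
        if agg is None:
            continue
        day, hr, sp, n_valid = agg
        if day < cutoff:
            continue
        series[HR].values[day] = hr
        series[HR].n_samples[day] = n_valid
        series[SPO2].values[day] = sp
        series[SPO2].n_samples[day] = n_valid
    for entry in patient.diary:
        if entry.date < cutoff:
            continue
        series[CAT].values[entry.date] = float(entry.cat)
        series[CAT].n_samples[entry.date] = 1
        series[PEF].values[entry.date] = float(entry.pef)
        series[PEF].n_samples[entry.date] = 1
    return series


def _stable_region(
    monitoring_start: date, treatment_day: Optional[date], last_day: date
) -> tuple[date, date]:
    """Inclusive date range available as 'stable state' data."""
    start = monitoring_start + timedelta(days=RUN_IN_DAYS)
    if treatment_day is not None:
        # stable days must precede the pre-exacerbation fortnight (-14..-1)
        end = treatment_day + timedelta(days=DAY_INDEX_MIN - 1)
    else:
        end = last_day
    return start, end


def find_stable_window(
    daily: Mapping[str, DailySeries],
    monitoring_start: date,
    treatment_day: Optional[date] = None,
) -> Optional[list[date]]:
    """First 14-consecutive-day span fully observed for every variable.

    Returns the window's dates, or ``None`` when no such span exists inside
    the stable region (which makes the patient ineligible).
    """
    all_dates = set()
    for s in daily.values():
        all_dates.update(s.values)
    if not all_dates:
        return None
    start, end = _stable_region(monitoring_start, treatment_day, max(all_dates))
    day = start
    while day + timedelta(days=STABLE_WINDOW_DAYS - 1) <= end:
        window = [day + timedelta(days=k) for k in range(STABLE_WINDOW_DAYS)]
        if all(d in daily[v].values for v in VARIABLES for d in window):
            return window
        day += timedelta(days=1)
    return None


def check_eligibility(
    daily: Mapping[str, DailySeries],
    monitoring_start: date,
    treatment_day: Optional[date] = None,
) -> EligibilityResult:
    """Apply the two exclusion rules (run-in already removed by construction)."""
    pid = next(iter(daily.values())).patient_id if daily else "?"
    reasons: list[str] = []
    if find_stable_window(daily, monitoring_start, treatment_day) is None:
        reasons.append(REASON_INSUFFICIENT_STABLE)
    if treatment_day is not None:
        for v in VARIABLES:
            missing_run = 0
            found = False
            for off in range(DAY_INDEX_MIN, 0):  # days -14..-1
                d = treatment_day + timedelta(days=off)
                if d in daily[v].values:
                    missing_run = 0
                else:
                    missing_run += 1
                    if missing_run >= 2:
                        found = True
                        break
            if found:
                reasons.append(REASON_CONSECUTIVE_MISSING)
                break
    return EligibilityResult(patient_id=pid, eligible=not reasons, reasons=reasons)


def align_to_event(series: DailySeries, treatment_day: Optional[date]) -> AlignedSeries:
    """Map calendar dates to event-relative indices -14..+13 (day 0 = treatment)."""
    if treatment_day is None:
        raise DataError(
            f"patient {series.patient_id} has no treatment day to align to"
        )
    aligned = AlignedSeries(patient_id=series.patient_id, variable=series.variable)
    for idx in range(DAY_INDEX_MIN, DAY_INDEX_MAX + 1):
        d = treatment_day + timedelta(days=idx)
        if d in series.values:
            aligned.values[idx] = series.values[d]
    return aligned


def second_stable_window(
    stable_window: list[date], treatment_day: Optional[date] = None
) -> list[date]:
    """The comparison fortnight right after the baseline window.

    Used to estimate false-positive behaviour on data not involved in
    baseline calibration.  For event patients the window is truncated so it
    cannot reach into the pre-exacerbation fortnight.
    """
    start = stable_window[-1] + timedelta(days=1)
    days = [start + timedelta(days=k) for k in range(STABLE_WINDOW_DAYS)]
    if treatment_day is not None:
        limit = treatment_day + timedelta(days=DAY_INDEX_MIN - 1)
        days = [d for d in days if d <= limit]
    return days
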