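from datetime import date, timedelta

import numpy as np
import pytest

from oxicopd import (
    CAT,
    HR,
    PEF,
    SPO2,
    DataError,
    OximetryRecording,
    align_to_event,
    check_eligibility,
    find_stable_window,
)
from oxicopd.daily import (
    REASON_CONSECUTIVE_MISSING,
    REASON_INSUFFICIENT_STABLE,
    DailySeries,
    aggregate_night,
    build_daily_series,
    second_stable_window,
)

START = date(2017, 1, 1)


def _recording(stamps, hr, spo2, pid="P1"):
    return OximetryRecording(
        pid,
        np.array(stamps, dtype="datetime64[s]"),
        np.array(hr, dtype=float),
        np.array(spo2, dtype=float),
    )


def _daily(present_offsets, pid="P1", variables=(HR, SPO2, CAT, PEF)):
    """DailySeries map with a value on START+k for each k in present_offsets."""
    out = {}
    for v in variables:
        vals = {START + timedelta(days=k): 70.0 + k for k in present_offsets}
        out[v] = DailySeries(patient_id=pid, variable=v, values=dict(vals))
    return out


def test_aggregate_night_mean_and_missing():
    rec = _recording(
        ["2017-01-02T23:00:00", "2017-01-02T23:00:04", "2017-01-02T23:00:08"],
        [68, 70, 72],
        [91, 92, 93],
    )
    day, hr, sp, n = aggregate_night(rec)
    assert (day, hr, sp, n) == (date(2017, 1, 2), 70.0, 92.0, 3)

    invalid = _recording(["2017-01-02T23:00:00"], [300], [45])
    assert aggregate_night(invalid) is None


def test_aggregate_night_matches_brute_force(small_cohort):
    records, _ = small_cohort
    overnight = next(r for r in records if r.arm == "overnight")
    for rec in overnight.recordings[:10]:
        mask = rec.valid
        want_hr = float(np.asarray(rec.heart_rate, float)[mask].mean())
        _, hr, sp, n = aggregate_night(rec)
        assert hr == pytest.approx(want_hr, abs=1e-12)
        assert n == int(mask.sum())


def test_long_night_mean_is_tight():
    """7 h at 4 s (6,300 samples) with SD 8 pins the nightly mean near 70."""
    rng = np.random.default_rng(0)
    n = 6300
    stamps = np.datetime64("2017-01-01T23:00:00") + np.arange(n) * np.timedelta64(
        4, "s"
    )
    hr = np.rint(70 + 8 * rng.standard_normal(n))
    rec = _recording(stamps, hr, np.full(n, 92))
    _, hr_mean, _, _ = aggregate_night(rec)
    assert abs(hr_mean - 70.0) < 0.5


def test_run_in_week_is_removed():
    entries_days = 21
    from oxicopd import DiaryEntry, PatientRecord

    record = PatientRecord(
        patient_id="P1",
        arm="once_daily",
        recordings=[],
        diary=[
            DiaryEntry(date=START + timedelta(days=k), cat=16, pef=210.0)
            for k in range(entries_days)
        ],
        monitoring_start=START,
    )
    daily = build_daily_series(record)
    days = sorted(daily[CAT].values)
    assert len(days) == 14  # days 8..21 of the 21 monitored days
    assert days[0] == START + timedelta(days=7)
    # removal is idempotent: nothing below the cutoff survives to remove again
    assert all(d >= START + timedelta(days=7) for d in days)


def test_spot_reading_becomes_that_days_value():
    from oxicopd import PatientRecord

    rec = _recording(["2017-01-10T08:00:00"], [78], [94])
    record = PatientRecord(
        patient_id="P1",
        arm="once_daily",
        recordings=[rec],
        diary=[],
        monitoring_start=START,
    )
    daily = build_daily_series(record)
    assert daily[HR].values == {date(2017, 1, 10): 78.0}
    assert daily[SPO2].values == {date(2017, 1, 10): 94.0}


def test_eligibility_happy_path():
    daily = _daily(range(7, 21))  # 14 clean post-run-in days
    result = check_eligibility(daily, START, None)
    assert result.eligible and result.reasons == []


def test_eligibility_insufficient_stable_days():
    daily = _daily(range(7, 17))  # only 10 stable days
    result = check_eligibility(daily, START, None)
    assert not result.eligible
    assert result.reasons == [REASON_INSUFFICIENT_STABLE]


def test_eligibility_consecutive_missing_preexacerbation():
    treatment = START + timedelta(days=40)
    offsets = set(range(7, 54))
    offsets -= {34, 35}  # days -6 and -5 relative to treatment
    daily = _daily(sorted(offsets))
    result = check_eligibility(daily, START, treatment)
    assert not result.eligible
    assert REASON_CONSECUTIVE_MISSING in result.reasons

    # a single missing day is tolerated
    daily_single = _daily(sorted(set(range(7, 54)) - {35}))
    assert check_eligibility(daily_single, START, treatment).eligible


def test_stable_window_is_first_fully_observed_fortnight():
    offsets = sorted(set(range(7, 40)) - {9})  # day 9 missing
    daily = _daily(offsets)
    window = find_stable_window(daily, START, None)
    assert window[0] == START + timedelta(days=10)
    assert len(window) == 14

    second = second_stable_window(window)
    assert second[0] == window[-1] + timedelta(days=1)
    assert len(second) == 14


def test_second_window_truncated_before_preexacerbation():
    treatment = START + timedelta(days=40)
    window = [START + timedelta(days=k) for k in range(14, 28)]
    second = second_stable_window(window, treatment)
    assert all(d <= treatment - timedelta(days=15) for d in second)


def test_align_to_event_date_arithmetic():
    treatment = date(2017, 2, 10)
    series = DailySeries(
        patient_id="P1",
        variable=HR,
        values={
            date(2017, 2, 5): 75.0,
            date(2017, 2, 10): 80.0,
            date(2017, 2, 23): 71.0,
            date(2017, 1, 1): 70.0,  # far outside the aligned range
        },
    )
    aligned = align_to_event(series, treatment)
    assert aligned.values == {-5: 75.0, 0: 80.0, 13: 71.0}
    with pytest.raises(DataError, match="treatment day"):
        align_to_event(series, None)
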