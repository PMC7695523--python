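from datetime import date, timedelta

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oxicopd import (
    CAT,
    HR,
    AnalysisConfig,
    BaselineStats,
    DataError,
    DegenerateBaselineError,
    SimConfig,
    baseline_stats,
    baseline_window_z,
    composite_score,
    composite_zseries,
    iter_cohort,
    mcid_flags,
    zscore,
    zseries,
)
from oxicopd.daily import AlignedSeries, DailySeries
from oxicopd.pipeline import analyze_patient
from oxicopd.scoring import STABLE_MEAN_INDEX

START = date(2017, 1, 1)


def _series(values, pid="P1", variable=HR):
    return DailySeries(
        patient_id=pid,
        variable=variable,
        values={START + timedelta(days=k): float(x) for k, x in enumerate(values)},
    )


def _window(n=14):
    return [START + timedelta(days=k) for k in range(n)]


def test_baseline_mean_and_sample_sd():
    stats = baseline_stats(_series(range(1, 15)), _window())
    assert stats.mean == pytest.approx(7.5)
    assert stats.sd == pytest.approx(np.std(np.arange(1, 15), ddof=1))
    assert stats.sd == pytest.approx(4.1833, abs=1e-4)
    assert stats.n_days == 14


def test_degenerate_baseline_is_an_error():
    with pytest.raises(DegenerateBaselineError):
        baseline_stats(_series([70.0] * 14), _window())


def test_baseline_requires_complete_window():
    series = _series(range(1, 14))  # 13 days only
    with pytest.raises(DataError, match="missing"):
        baseline_stats(series, _window())


def test_baseline_estimate_tracks_true_mean():
    rng = np.random.default_rng(4)
    series = _series(rng.normal(70.0, 1.8, size=14))
    stats = baseline_stats(series, _window())
    assert abs(stats.mean - 70.0) <= 3 * 1.8 / np.sqrt(14)


def test_zscore_arithmetic():
    hr = BaselineStats("P1", HR, mean=77.1, sd=3.6, n_days=14)
    assert zscore(77.1, hr) == 0.0
    assert zscore(80.0, hr) == pytest.approx(0.8056, abs=1e-4)
    spo2 = BaselineStats("P1", "SpO2", mean=91.0, sd=0.36, n_days=14)
    assert zscore(89.8, spo2) == pytest.approx(-3.3333, abs=1e-4)


def test_composite_score_examples():
    assert composite_score(0.0, 0.0) == 0.0
    assert composite_score(2.0, -1.5) == 3.5
    # a tachycardia peak of +1.7 SD with a desaturation of -1.8 SD
    assert composite_score(1.7, -1.80) == pytest.approx(3.5)
    assert composite_score(None, -1.0) is None
    assert composite_score(1.0, None) is None


@given(
    a=st.floats(-50, 50, allow_nan=False),
    b=st.floats(-50, 50, allow_nan=False),
)
def test_composite_score_antisymmetric_under_sign_flip(a, b):
    assert composite_score(a, b) == pytest.approx(-composite_score(-a, -b))


def test_zseries_values_and_display_day():
    baseline = BaselineStats("P1", HR, mean=70.0, sd=2.0, n_days=14)
    aligned = AlignedSeries(
        "P1", HR, values={-3: 70.0, 0: 70.0 + 1.96 * 2.0, 5: 66.0}
    )
    zs = zseries(aligned, baseline)
    assert zs.z[STABLE_MEAN_INDEX] == 0.0
    assert zs.z[-3] == 0.0
    assert zs.z[0] == pytest.approx(1.96)
    assert zs.z[5] == pytest.approx(-2.0)
    assert STABLE_MEAN_INDEX not in zs.data_days()


def test_composite_zseries_requires_both_components():
    zhr = zseries(
        AlignedSeries("P1", HR, {-1: 74.0, 0: 78.0}),
        BaselineStats("P1", HR, 70.0, 2.0, 14),
    )
    zsp = zseries(
        AlignedSeries("P1", "SpO2", {0: 90.0}),
        BaselineStats("P1", "SpO2", 92.0, 1.0, 14),
    )
    comp = composite_zseries(zhr, zsp)
    assert set(comp.data_days()) == {0}
    assert comp.z[0] == pytest.approx(4.0 - (-2.0))


def test_baseline_window_z_exactly_standardized(small_cohort):
    """Mean 0 and sample SD 1 over the calibration fortnight, by construction."""
    from oxicopd.daily import build_daily_series, find_stable_window

    records, _ = small_cohort
    checked = 0
    for record in records:
        daily = build_daily_series(record)
        window = find_stable_window(
            daily, record.monitoring_start, record.treatment_day
        )
        if window is None:
            continue
        for v, series in daily.items():
            try:
                stats = baseline_stats(series, window)
            except DegenerateBaselineError:
                continue
            z = baseline_window_z(series, window, stats)
            assert abs(z.mean()) < 1e-12
            assert abs(z.std(ddof=1) - 1.0) < 1e-12
            checked += 1
    assert checked >= 40


def test_event_day_composite_crosses_threshold_in_most_replicates():
    """With default effect sizes the composite Z at day 0 exceeds 1.96 in
    >= 90% of overnight event patients."""
    cfg = SimConfig(
        n_patients=100,
        arm_split=1.0,
        exacerbation_fraction=1.0,
        missing_day_prob=0.0,
        consecutive_miss_prob=0.0,
        night_length_h=1.0,
        seed=13,
    )
    acfg = AnalysisConfig()
    hits = total = 0
    for record, _ in iter_cohort(cfg):
        pa = analyze_patient(record, acfg)
        if not pa.eligible or "composite" not in pa.z_event:
            continue
        z0 = pa.z_event["composite"].z.get(0)
        if z0 is None:
            continue
        total += 1
        hits += z0 > 1.96
    assert total >= 90
    assert hits / total >= 0.90


def test_mcid_flags():
    baseline = BaselineStats("P1", CAT, mean=15.6, sd=1.0, n_days=14)
    flat = AlignedSeries("P1", CAT, {k: 15.6 for k in range(-5, 5)})
    assert mcid_flags(flat, baseline) == set()
    series = AlignedSeries("P1", CAT, {-5: 18.3, -6: 17.5, 0: 22.6})
    assert mcid_flags(series, baseline) == {-5, 0}
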