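import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oxicopd import (
    CAT,
    COMPOSITE,
    HR,
    SPO2,
    DataError,
    PerformanceTable,
    ZSeries,
    detect_abnormal_days,
    event_performance,
    group_z_trajectory,
    paired_lead_comparison,
    phase_summaries,
    summarize_lead_times,
    time_to_treatment,
    unpaired_lead_comparison,
)
from oxicopd.evaluate import format_median_iqr


def _zs(mapping, variable=CAT, pid="P1"):
    return ZSeries(pid, variable, dict(mapping))


def test_quiet_series_yields_no_detection():
    zs = _zs({d: 0.5 for d in range(-14, 14)})
    det = detect_abnormal_days(zs)
    assert det.abnormal_days == set()
    assert det.first_abnormal_day is None
    assert time_to_treatment(det) is None


def test_sustained_symptom_crossing_from_day_minus_5():
    zs = _zs({d: (2.5 if d >= -5 else 0.3) for d in range(-14, 14)})
    det = detect_abnormal_days(zs)
    assert det.first_abnormal_day == -5
    assert det.abnormal_days == set(range(-5, 14))
    assert time_to_treatment(det) == 5


def test_composite_crossing_window():
    zs = _zs(
        {d: (2.2 if -7 <= d <= 0 else 0.0) for d in range(-14, 14)},
        variable=COMPOSITE,
    )
    det = detect_abnormal_days(zs)
    assert det.abnormal_days >= set(range(-7, 1))
    assert det.first_abnormal_day == -7


def test_display_index_never_detected():
    zs = ZSeries("P1", HR, {-15: 0.0, -2: 5.0})
    assert detect_abnormal_days(zs).abnormal_days == {-2}


def test_directional_detection_respects_expected_sign():
    drop = _zs({-3: -2.5}, variable=HR)
    assert detect_abnormal_days(drop, direction="two_sided").abnormal_days == {-3}
    assert detect_abnormal_days(drop, direction="directional").abnormal_days == set()
    desat = _zs({-3: -2.5}, variable=SPO2)
    assert detect_abnormal_days(desat, direction="directional").abnormal_days == {-3}


def test_consecutive_day_requirement():
    zs = _zs({-9: 2.5, -5: 2.5, -4: 2.5, 2: 3.0})
    det = detect_abnormal_days(zs, consecutive=2)
    assert det.abnormal_days == {-5, -4}
    assert det.first_abnormal_day == -5


@given(
    st.dictionaries(
        st.integers(min_value=-14, max_value=13),
        st.floats(-6, 6, allow_nan=False),
        max_size=28,
    ),
    st.sampled_from([1.5, 1.96, 2.5]),
)
def test_detection_matches_brute_force_scan(zmap, threshold):
    det = detect_abnormal_days(_zs(zmap), threshold=threshold)
    brute = {d for d, v in zmap.items() if abs(v) >= threshold}
    assert det.abnormal_days == brute
    pre = [d for d in brute if -14 <= d <= 0]
    assert det.first_abnormal_day == (min(pre) if pre else None)


def test_time_to_treatment_edges():
    assert time_to_treatment(detect_abnormal_days(_zs({0: 2.0}))) == 0
    assert time_to_treatment(detect_abnormal_days(_zs({-5: 2.0}))) == 5


def test_lead_time_summaries_median_iqr():
    times = {"composite": {"P1": 5.0, "P2": 5.0, "P3": 5.0, "P4": None}}
    arms = {f"P{i}": "overnight" for i in range(1, 5)}
    table = summarize_lead_times(times, arms)
    row = table.iloc[0]
    assert (row["median_days"], row["iqr_low"], row["iqr_high"]) == (5.0, 5.0, 5.0)
    assert (row["n_detected"], row["n_censored"]) == (3, 1)

    assert format_median_iqr([0, 2, 10]) == "2 (0-10)"


def test_identical_groups_compare_as_null():
    times = {f"P{i}": 5.0 for i in range(6)}
    arms = {f"P{i}": ("overnight" if i < 3 else "once_daily") for i in range(6)}
    assert unpaired_lead_comparison(times, arms) > 0.99
    assert paired_lead_comparison(times, dict(times)) > 0.99


def test_all_censored_group_is_undefined():
    times = {"P1": None, "P2": None}
    arms = {"P1": "overnight", "P2": "once_daily"}
    assert unpaired_lead_comparison(times, arms) is None
    table = summarize_lead_times({"HR": times}, arms)
    assert table["n_detected"].sum() == 0
    assert np.isnan(table["median_days"]).all()


def test_event_performance_from_reported_counts():
    perf = PerformanceTable.from_counts(tp=11, fp=3, tn=8, fn=2)
    assert perf.sensitivity == pytest.approx(11 / 13)
    assert perf.specificity == pytest.approx(8 / 11)
    assert perf.ppv == pytest.approx(11 / 14)
    # complements close under the standard definitions
    assert perf.sensitivity + perf.fn / (perf.tp + perf.fn) == pytest.approx(1.0)
    assert perf.specificity + perf.fp / (perf.tn + perf.fp) == pytest.approx(1.0)


def test_event_performance_flag_counting_and_edge_cases():
    perf = event_performance(
        event_detections={"A": True, "B": False, "C": True},
        stable_detections={"A": False, "B": False, "C": True},
    )
    assert (perf.tp, perf.fn, perf.fp, perf.tn) == (2, 1, 1, 2)

    undefined = PerformanceTable.from_counts(tp=0, fp=0, tn=3, fn=2)
    assert undefined.ppv is None

    with pytest.raises(DataError):
        event_performance({}, {})


def test_phase_summaries_identical_values():
    ps = phase_summaries([5.0] * 10, [5.0] * 10, [5.0] * 10)
    assert ps.pvalue > 0.99
    assert ps.means["stable"] == ps.means["pre"] == 5.0


def test_phase_summaries_detects_symptom_elevation():
    """Stable vs pre-exacerbation vs recovery CAT levels separate cleanly."""
    rng = np.random.default_rng(8)
    stable = rng.normal(15.6, 1.46, 200)
    pre = rng.normal(17.4, 2.34, 200)
    post = rng.normal(19.7, 2.0, 200)
    ps = phase_summaries(stable, pre, post, variable=CAT)
    assert ps.pvalue < 0.001
    assert ps.means["stable"] < ps.means["pre"] < ps.means["post"]
    # variability also rises before the event
    assert ps.var_ratio > 1.0
    assert ps.var_pvalue < 0.01


def test_phase_summaries_variance_only_difference():
    rng = np.random.default_rng(15)
    stable = rng.normal(10.0, 1.0, 200)
    pre = rng.normal(10.0, 2.0, 200)
    post = rng.normal(10.0, 1.0, 200)
    ps = phase_summaries(stable, pre, post, force_nonparametric=False)
    assert ps.var_pvalue < 1e-6
    assert ps.pvalue > 0.01  # means indistinguishable at this seed
    for pair, p in ps.pairwise.items():
        assert p > 0.001, pair


def test_phase_summaries_small_phase_undefined():
    ps = phase_summaries([1.0, 2.0], [1.5], [2.5, 3.5])
    assert ps.test is None and ps.pvalue is None


def test_group_trajectory_averages_patients():
    a = ZSeries("P1", HR, {-15: 0.0, -1: 1.0, 0: 2.0})
    b = ZSeries("P2", HR, {-15: 0.0, -1: -1.0, 0: 4.0})
    traj = group_z_trajectory([a, b])
    assert traj[-1] == 0.0
    assert traj[0] == 3.0
    single = group_z_trajectory([a])
    assert dict(single) == a.z
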