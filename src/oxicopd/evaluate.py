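"""Threshold-crossing detection and event-level evaluation.

A day is abnormal when its Z score lies outside the nominal 95% band of the
stable state (|Z| >= 1.96 by default).  Per patient, the first abnormal day
inside the pre-event window yields the detection lead time (days of warning
before treatment started).  Event-level performance contrasts crossings in
the pre-event fortnight (sensitivity) with crossings in a second, disjoint
stable fortnight (specificity), mirroring how a telehealth alarm would be
judged.  Phase comparisons (stable / pre-exacerbation / recovery) use
standard omnibus and variance-ratio tests from scipy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .errors import DataError
from .io import CAT, COMPOSITE, HR, PEF, SPO2
from .scoring import STABLE_MEAN_INDEX, ZSeries

#: sign of the physiologically expected excursion, for directional detection
EXPECTED_SIGN = {HR: +1, CAT: +1, COMPOSITE: +1, SPO2: -1, PEF: -1}


@dataclass
class DetectionResult:
    patient_id: str
    variable: str
    abnormal_days: set[int] = field(default_factory=set)
    first_abnormal_day: Optional[int] = None


@dataclass(frozen=True)
class PerformanceTable:
    """Event-level 2x2 counts and derived fractions (standard definitions)."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> Optional[float]:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else None

    @property
    def specificity(self) -> Optional[float]:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else None

    @property
    def ppv(self) -> Optional[float]:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else None

    @classmethod
    def from_counts(cls, tp: int, fp: int, tn: int, fn: int) -> "PerformanceTable":
        return cls(tp=tp, fp=fp, tn=tn, fn=fn)


@dataclass
class PhaseSummary:
    """Stable / pre-exacerbation / post-exacerbation comparison for one variable."""

    variable: str
    means: dict[str, float]
    sds: dict[str, float]
    ns: dict[str, int]
    day0_mean: Optional[float]
    test: Optional[str]  # "anova" or "kruskal"
    statistic: Optional[float]
    pvalue: Optional[float]
    pairwise: dict[tuple[str, str], float]
    var_ratio: Optional[float]  # pre-vs-stable variance ratio (F)
    var_pvalue: Optional[float]


def _is_abnormal(z: float, variable: str, threshold: float, direction: str) -> bool:
    if direction == "directional":
        return z * EXPECTED_SIGN[variable] >= threshold
    return abs(z) >= threshold


def _consecutive_filter(flagged: set[int], k: int) -> set[int]:
    """Keep only days belonging to a run of >= k consecutive flagged days."""
    if k <= 1 or not flagged:
        return flagged
    keep: set[int] = set()
    days = sorted(flagged)
    run = [days[0]]
    for d in days[1:] + [None]:
        if d is not None and d == run[-1] + 1:
            run.append(d)
        else:
            if len(run) >= k:
                keep.update(run)
            if d is not None:
                run = [d]
    return keep


def detect_abnormal_days(
    z: ZSeries,
    threshold: float = 1.96,
    direction: str = "two_sided",
    pre_window: tuple[int, int] = (-14, 0),
    consecutive: int = 1,
) -> DetectionResult:
    """Scan a Z series for days outside the significance band.

    ``first_abnormal_day`` is the earliest abnormal day inside
    ``pre_window`` (days -14..0 by default); the display index -15 never
    participates.
    """
    flagged = {
        d
        for d, v in z.data_days().items()
        if _is_abnormal(v, z.variable, threshold, direction)
    }
    flagged = _consecutive_filter(flagged, consecutive)
    in_window = [d for d in flagged if pre_window[0] <= d <= pre_window[1]]
    return DetectionResult(
        patient_id=z.patient_id,
        variable=z.variable,
        abnormal_days=flagged,
        first_abnormal_day=min(in_window) if in_window else None,
    )


def time_to_treatment(detection: DetectionResult) -> Optional[int]:
    """Days of warning: 0 - first_abnormal_day; ``None`` when censored."""
    if detection.first_abnormal_day is None:
        return None
    return -detection.first_abnormal_day


def summarize_lead_times(
    lead_times: Mapping[str, Mapping[str, Optional[float]]],
    arms: Mapping[str, str],
) -> pd.DataFrame:
    """Median (IQR) detection lead time per arm and variable.

    ``lead_times[variable][patient_id]`` is the per-patient lead in days or
    ``None`` when the variable never crossed before treatment (censored;
    excluded from the median, counted separately).
    """
    rows = []
    for variable, times in lead_times.items():
        by_arm: dict[str, list[float]] = {}
        censored: dict[str, int] = {}
        for pid, t in times.items():
            arm = arms[pid]
            if t is None:
                censored[arm] = censored.get(arm, 0) + 1
            else:
                by_arm.setdefault(arm, []).append(float(t))
        for arm in sorted(set(by_arm) | set(censored)):
            vals = np.array(by_arm.get(arm, []), dtype=float)
            if len(vals):
                med = float(np.median(vals))
                # (n+1)-position quartiles, the convention of clinical tables
                q1, q3 = (
                    float(q) for q in np.percentile(vals, [25, 75], method="weibull")
                )
            else:
                med = q1 = q3 = float("nan")
            rows.append(
                {
                    "arm": arm,
                    "variable": variable,
                    "n_detected": len(vals),
                    "n_censored": censored.get(arm, 0),
                    "median_days": med,
                    "iqr_low": q1,
                    "iqr_high": q3,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "arm",
            "variable",
            "n_detected",
            "n_censored",
            "median_days",
            "iqr_low",
            "iqr_high",
        ],
    )


def format_median_iqr(values: Sequence[float]) -> str:
    """Render lead times in the conventional ``median (q1-q3)`` style."""
    vals = np.asarray(list(values), dtype=float)
    med = np.median(vals)
    q1, q3 = np.percentile(vals, [25, 75], method="weibull")
    return f"{med:g} ({q1:g}-{q3:g})"


def _rank_p(x: np.ndarray, y: np.ndarray, paired: bool) -> Optional[float]:
    if len(x) == 0 or len(y) == 0:
        return None
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0  # identical constant groups: no evidence of a difference
    try:
        if paired:
            diffs = x - y
            if np.all(diffs == 0):
                return 1.0
            return float(stats.wilcoxon(x, y).pvalue)
        return float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
    except ValueError:
        return None


def paired_lead_comparison(
    times_a: Mapping[str, Optional[float]],
    times_b: Mapping[str, Optional[float]],
) -> Optional[float]:
    """Within-patient rank test (Wilcoxon) between two variables' lead times."""
    common = [
        p
        for p in times_a.keys() & times_b.keys()
        if times_a[p] is not None and times_b[p] is not None
    ]
    x = np.array([times_a[p] for p in common], dtype=float)
    y = np.array([times_b[p] for p in common], dtype=float)
    return _rank_p(x, y, paired=True)


def unpaired_lead_comparison(
    times: Mapping[str, Optional[float]], arms: Mapping[str, str]
) -> Optional[float]:
    """Between-arm rank test (Mann-Whitney U) on uncensored lead times."""
    groups: dict[str, list[float]] = {}
    for pid, t in times.items():
        if t is not None:
            groups.setdefault(arms[pid], []).append(float(t))
    if len(groups) != 2:
        return None
    (x, y) = (np.array(v, dtype=float) for v in groups.values())
    return _rank_p(x, y, paired=False)


def event_performance(
    event_detections: Mapping[str, bool],
    stable_detections: Mapping[str, bool],
) -> PerformanceTable:
    """2x2 table: pre-event crossings vs crossings in a second stable fortnight.

    ``event_detections`` flags each event patient's pre-event window
    (days -14..0); ``stable_detections`` flags a disjoint stable comparison
    fortnight per patient.
    """
    if not event_detections and not stable_detections:
        raise DataError("event_performance needs at least one patient flag")
    tp = sum(1 for v in event_detections.values() if v)
    fn = len(event_detections) - tp
    fp = sum(1 for v in stable_detections.values() if v)
    tn = len(stable_detections) - fp
    return PerformanceTable(tp=tp, fp=fp, tn=tn, fn=fn)


def _normalish(samples: list[np.ndarray]) -> bool:
    for arr in samples:
        if len(arr) < 3:
            continue
        sub = arr if len(arr) <= 500 else arr[:: max(1, len(arr) // 500)]
        if np.ptp(sub) == 0:
            continue
        if stats.shapiro(sub).pvalue < 0.05:
            return False
    return True


def phase_summaries(
    stable,
    pre,
    post,
    day0=None,
    variable: str = "",
    force_nonparametric: bool = False,
) -> PhaseSummary:
    """Compare the stable, pre-exacerbation and recovery phases.

    Means and SDs per phase; an omnibus test across the three phases (ANOVA,
    or Kruskal-Wallis when a normality check fails or when forced); unadjusted
    pairwise comparisons; and a variance-ratio F test of whether day-to-day
    variability rises before the exacerbation (pre vs stable).  Day 0 is
    summarized separately, not inside any phase.
    """
    phases = {
        "stable": np.asarray(list(stable), dtype=float),
        "pre": np.asarray(list(pre), dtype=float),
        "post": np.asarray(list(post), dtype=float),
    }
    means = {k: float(v.mean()) if len(v) else float("nan") for k, v in phases.items()}
    sds = {
        k: float(v.std(ddof=1)) if len(v) > 1 else float("nan")
        for k, v in phases.items()
    }
    ns = {k: int(len(v)) for k, v in phases.items()}
    day0_mean = (
        float(np.mean(np.asarray(list(day0), dtype=float)))
        if day0 is not None and len(list(day0))
        else None
    )

    test = statistic = pvalue = None
    pairwise: dict[tuple[str, str], float] = {}
    groups = list(phases.values())
    if all(len(g) >= 2 for g in groups):
        pooled = np.concatenate(groups)
        if np.ptp(pooled) == 0:
            test, statistic, pvalue = "anova", 0.0, 1.0
        else:
            parametric = not force_nonparametric and _normalish(groups)
            if parametric:
                res = stats.f_oneway(*groups)
                test, statistic, pvalue = "anova", float(res.statistic), float(res.pvalue)
            else:
                res = stats.kruskal(*groups)
                test, statistic, pvalue = (
                    "kruskal",
                    float(res.statistic),
                    float(res.pvalue),
                )
            for a, b in (("stable", "pre"), ("stable", "post"), ("pre", "post")):
                x, y = phases[a], phases[b]
                if np.ptp(np.concatenate([x, y])) == 0:
                    pairwise[(a, b)] = 1.0
                elif parametric:
                    pairwise[(a, b)] = float(stats.ttest_ind(x, y).pvalue)
                else:
                    pairwise[(a, b)] = float(
                        stats.mannwhitneyu(x, y, alternative="two-sided").pvalue
                    )

    var_ratio = var_p = None
    if ns["stable"] >= 2 and ns["pre"] >= 2 and sds["stable"] > 0:
        var_ratio = float((sds["pre"] ** 2) / (sds["stable"] ** 2))
        dfn, dfd = ns["pre"] - 1, ns["stable"] - 1
        tail = stats.f.sf(var_ratio, dfn, dfd)
        var_p = float(min(1.0, 2.0 * min(tail, 1.0 - tail)))

    return PhaseSummary(
        variable=variable,
        means=means,
        sds=sds,
        ns=ns,
        day0_mean=day0_mean,
        test=test,
        statistic=statistic,
        pvalue=pvalue,
        pairwise=pairwise,
        var_ratio=var_ratio,
        var_pvalue=var_p,
    )


def group_z_trajectory(zseries_list: Sequence[ZSeries]) -> pd.Series:
    """Mean Z per event-aligned day across patients (figure-style trajectory).

    Day -15 (the stable-period mean, 0 by construction) is included for
    display; days observed in no patient are omitted.
    """
    acc: dict[int, list[float]] = {}
    for zs in zseries_list:
        for d, v in zs.z.items():
            acc.setdefault(d, []).append(v)
    days = sorted(acc)
    return pd.Series(
        [float(np.mean(acc[d])) for d in days], index=days, name="mean_z"
    )


def detect_with_config(z: ZSeries, config: AnalysisConfig) -> DetectionResult:
    """Convenience wrapper applying an :class:`AnalysisConfig`."""
    return detect_abnormal_days(
        z,
        threshold=config.threshold,
        direction=config.direction,
        pre_window=config.pre_window,
        consecutive=config.consecutive_days_required,
    )
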