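"""End-to-end orchestration: records -> daily series -> Z scores -> detection.

:func:`analyze_patient` runs the per-patient chain (daily aggregation,
run-in removal, eligibility, baseline calibration, Z transformation,
threshold detection, second-stable-window flags).  :func:`analyze_cohort`
streams over any iterable of records — including the synthetic generator —
keeping only compact per-patient results, and exposes cohort-level tables:
lead times, event-level performance, group mean-Z trajectories and phase
comparisons.  :func:`run_pipeline` adds file output (CSV tables with a
config-hash provenance line, figures, a run log).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .config import AnalysisConfig, SimConfig, config_hash, dump_config
from .daily import (
    AlignedSeries,
    EligibilityResult,
    align_to_event,
    build_daily_series,
    check_eligibility,
    find_stable_window,
    second_stable_window,
)
from .errors import DegenerateBaselineError, OxiCopdError
from .evaluate import (
    DetectionResult,
    PerformanceTable,
    PhaseSummary,
    detect_with_config,
    event_performance,
    group_z_trajectory,
    phase_summaries,
    summarize_lead_times,
    time_to_treatment,
    unpaired_lead_comparison,
)
from .io import CAT, COMPOSITE, HR, PEF, SPO2, VARIABLES, PatientRecord
from .scoring import (
    BaselineStats,
    ZSeries,
    baseline_stats,
    composite_zseries,
    mcid_flags,
    zscore,
    zseries,
)

REASON_DEGENERATE_BASELINE = "degenerate_baseline"

#: variables carried through detection (the four monitored + the composite)
DETECTION_VARIABLES = (HR, SPO2, CAT, PEF, COMPOSITE)


@dataclass
class PatientAnalysis:
    """Compact per-patient analysis output."""

    patient_id: str
    arm: str
    has_event: bool
    eligible: bool
    exclusion_reasons: list[str] = field(default_factory=list)
    stable_window: Optional[list[date]] = None
    second_window: Optional[list[date]] = None
    baselines: dict[str, BaselineStats] = field(default_factory=dict)
    stable_values: dict[str, list[float]] = field(default_factory=dict)
    aligned: dict[str, AlignedSeries] = field(default_factory=dict)
    z_event: dict[str, ZSeries] = field(default_factory=dict)
    detections: dict[str, DetectionResult] = field(default_factory=dict)
    lead_times: dict[str, Optional[int]] = field(default_factory=dict)
    #: any crossing inside the second stable fortnight (None: window unusable)
    stable_flags: dict[str, Optional[bool]] = field(default_factory=dict)
    second_z: dict[str, dict[int, float]] = field(default_factory=dict)
    mcid_days: set[int] = field(default_factory=set)


def _second_window_z(
    daily, window_days: list[date], baselines: dict[str, BaselineStats]
) -> dict[str, dict[int, float]]:
    """Z per observed day of the comparison window, indexed 0..13."""
    out: dict[str, dict[int, float]] = {}
    for v in VARIABLES:
        out[v] = {
            k: zscore(daily[v].values[d], baselines[v])
            for k, d in enumerate(window_days)
            if d in daily[v].values
        }
    out[COMPOSITE] = {
        k: out[HR][k] - out[SPO2][k] for k in out[HR].keys() & out[SPO2].keys()
    }
    return out


def analyze_patient(record: PatientRecord, config: AnalysisConfig) -> PatientAnalysis:
    daily = build_daily_series(record, nightly_statistic=config.nightly_statistic)
    elig = check_eligibility(daily, record.monitoring_start, record.treatment_day)
    pa = PatientAnalysis(
        patient_id=record.patient_id,
        arm=record.arm,
        has_event=record.treatment_day is not None,
        eligible=elig.eligible,
        exclusion_reasons=list(elig.reasons),
    )
    if not elig.eligible:
        return pa
    window = find_stable_window(daily, record.monitoring_start, record.treatment_day)
    assert window is not None  # guaranteed by eligibility
    pa.stable_window = window
    try:
        pa.baselines = {v: baseline_stats(daily[v], window) for v in VARIABLES}
    except DegenerateBaselineError:
        pa.eligible = False
        pa.exclusion_reasons.append(REASON_DEGENERATE_BASELINE)
        return pa
    pa.stable_values = {
        v: [daily[v].values[d] for d in window] for v in VARIABLES
    }

    second = second_stable_window(window, record.treatment_day)
    pa.second_window = second
    pa.second_z = _second_window_z(daily, second, pa.baselines)
    for v in DETECTION_VARIABLES:
        zmap = pa.second_z.get(v, {})
        if not zmap:
            pa.stable_flags[v] = None
            continue
        pseudo = ZSeries(record.patient_id, v, dict(zmap))
        det = detect_with_config(pseudo, config)
        pa.stable_flags[v] = bool(det.abnormal_days)

    if record.treatment_day is not None:
        for v in VARIABLES:
            pa.aligned[v] = align_to_event(daily[v], record.treatment_day)
            pa.z_event[v] = zseries(pa.aligned[v], pa.baselines[v])
        pa.z_event[COMPOSITE] = composite_zseries(
            pa.z_event[HR], pa.z_event[SPO2]
        )
        for v in DETECTION_VARIABLES:
            det = detect_with_config(pa.z_event[v], config)
            pa.detections[v] = det
            pa.lead_times[v] = time_to_treatment(det)
        pa.mcid_days = mcid_flags(
            pa.aligned[CAT], pa.baselines[CAT], mcid=config.mcid_cat
        )
    return pa


@dataclass
class CohortAnalysis:
    """Cohort-level view over per-patient analyses."""

    config: AnalysisConfig
    patients: list[PatientAnalysis] = field(default_factory=list)

    # -- accounting ---------------------------------------------------------
    @property
    def eligible(self) -> list[PatientAnalysis]:
        return [p for p in self.patients if p.eligible]

    @property
    def excluded(self) -> list[PatientAnalysis]:
        return [p for p in self.patients if not p.eligible]

    @property
    def event_patients(self) -> list[PatientAnalysis]:
        return [p for p in self.eligible if p.has_event]

    @property
    def arms(self) -> dict[str, str]:
        return {p.patient_id: p.arm for p in self.patients}

    # -- lead times ---------------------------------------------------------
    def lead_times(self, variable: str) -> dict[str, Optional[int]]:
        return {
            p.patient_id: p.lead_times.get(variable) for p in self.event_patients
        }

    def lead_table(self) -> pd.DataFrame:
        times = {v: self.lead_times(v) for v in DETECTION_VARIABLES}
        return summarize_lead_times(times, self.arms)

    def median_lead(self, variable: str, arm: Optional[str] = None) -> float:
        vals = [
            t
            for p in self.event_patients
            if (arm is None or p.arm == arm)
            and (t := p.lead_times.get(variable)) is not None
        ]
        return float(np.median(vals)) if vals else float("nan")

    def arm_comparison(self, variable: str) -> Optional[float]:
        return unpaired_lead_comparison(self.lead_times(variable), self.arms)

    # -- event-level performance -------------------------------------------
    def performance(self, variable: str) -> Optional[PerformanceTable]:
        event_flags = {
            p.patient_id: p.lead_times.get(variable) is not None
            for p in self.event_patients
        }
        stable_flags = {
            p.patient_id: p.stable_flags[variable]
            for p in self.eligible
            if p.stable_flags.get(variable) is not None
        }
        if not event_flags and not stable_flags:
            return None
        return event_performance(event_flags, stable_flags)

    # -- figure-style output -------------------------------------------------
    def trajectory(self, variable: str, arm: Optional[str] = None) -> pd.Series:
        zs = [
            p.z_event[variable]
            for p in self.event_patients
            if (arm is None or p.arm == arm) and variable in p.z_event
        ]
        return group_z_trajectory(zs)

    # -- phase comparisons ---------------------------------------------------
    def phase_summary(
        self,
        variable: str,
        arm: Optional[str] = None,
        force_nonparametric: bool = False,
    ) -> PhaseSummary:
        stable: list[float] = []
        pre: list[float] = []
        post: list[float] = []
        day0: list[float] = []
        post_start = 0 if self.config.post_phase_includes_day0 else 1
        for p in self.event_patients:
            if arm is not None and p.arm != arm:
                continue
            stable.extend(p.stable_values.get(variable, []))
            aligned = p.aligned.get(variable)
            if aligned is None:
                continue
            for idx, v in aligned.values.items():
                if idx <= -1:
                    pre.append(v)
                elif idx >= post_start:
                    post.append(v)
                if idx == 0:
                    day0.append(v)
        return phase_summaries(
            stable,
            pre,
            post,
            day0=day0,
            variable=variable,
            force_nonparametric=force_nonparametric,
        )

    # -- stable-state variability --------------------------------------------
    def stable_sd(self, variable: str, arm: Optional[str] = None) -> float:
        """Mean per-patient stable-window SD (day-to-day variability)."""
        sds = [
            p.baselines[variable].sd
            for p in self.eligible
            if variable in p.baselines and (arm is None or p.arm == arm)
        ]
        return float(np.mean(sds)) if sds else float("nan")

    # -- long-format frames --------------------------------------------------
    def zscores_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.eligible:
            for v, zs in p.z_event.items():
                for idx in sorted(zs.z):
                    rows.append((p.patient_id, v, "event", idx, zs.z[idx]))
            for v, zmap in p.second_z.items():
                for idx in sorted(zmap):
                    rows.append((p.patient_id, v, "stable2", idx, zmap[idx]))
        return pd.DataFrame(
            rows, columns=["patient_id", "variable", "window", "day_index", "z"]
        )

    def detections_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.eligible:
            for v in DETECTION_VARIABLES:
                det = p.detections.get(v)
                flag = p.stable_flags.get(v)
                rows.append(
                    {
                        "patient_id": p.patient_id,
                        "variable": v,
                        "abnormal_days": ";".join(
                            str(d) for d in sorted(det.abnormal_days)
                        )
                        if det
                        else "",
                        "first_abnormal_day": det.first_abnormal_day
                        if det
                        else None,
                        "lead_time_days": p.lead_times.get(v),
                        "stable_window_flag": flag,
                    }
                )
        return pd.DataFrame(rows)

    def performance_frame(self) -> pd.DataFrame:
        rows = []
        for v in DETECTION_VARIABLES:
            perf = self.performance(v)
            if perf is None:
                continue
            rows.append(
                {
                    "variable": v,
                    "tp": perf.tp,
                    "fp": perf.fp,
                    "tn": perf.tn,
                    "fn": perf.fn,
                    "sensitivity": perf.sensitivity,
                    "specificity": perf.specificity,
                    "ppv": perf.ppv,
                }
            )
        return pd.DataFrame(rows)

    def trajectories_frame(self) -> pd.DataFrame:
        rows = []
        for v in DETECTION_VARIABLES:
            for arm in sorted({p.arm for p in self.event_patients}):
                traj = self.trajectory(v, arm=arm)
                for idx, z in traj.items():
                    rows.append(
                        {"variable": v, "arm": arm, "day_index": idx, "mean_z": z}
                    )
        return pd.DataFrame(rows)

    def exclusions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "patient_id": p.patient_id,
                    "arm": p.arm,
                    "has_event": p.has_event,
                    "reasons": ";".join(p.exclusion_reasons),
                }
                for p in self.excluded
            ],
            columns=["patient_id", "arm", "has_event", "reasons"],
        )


def analyze_cohort(
    records: Iterable[PatientRecord], config: Optional[AnalysisConfig] = None
) -> CohortAnalysis:
    """Analyze any iterable of patient records (streams lazily)."""
    config = config or AnalysisConfig()
    analysis = CohortAnalysis(config=config)
    for record in records:
        try:
            analysis.patients.append(analyze_patient(record, config))
        except OxiCopdError as exc:
            raise OxiCopdError(
                f"analysis failed for patient {record.patient_id}: {exc}"
            ) from exc
    return analysis


def _write_frame(df: pd.DataFrame, path: Path, run_hash: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# oxicopd config_hash={run_hash}\n")
        df.to_csv(fh, index=False)


def run_pipeline(
    sim_config: SimConfig,
    analysis_config: Optional[AnalysisConfig] = None,
    outdir=None,
    make_plots: bool = True,
    write_raw: bool = False,
) -> CohortAnalysis:
    """simulate -> score -> detect -> evaluate, writing a reproducible run dir.

    Deterministic given ``sim_config.seed``; every CSV carries a provenance
    comment naming the resolved-config hash.
    """
    from .cohort import iter_cohort, simulate_cohort, write_cohort

    analysis_config = analysis_config or AnalysisConfig()
    run_hash = config_hash(sim_config, analysis_config)

    if write_raw and outdir is not None:
        write_cohort(sim_config, Path(outdir) / "raw")

    analysis = analyze_cohort(
        (record for record, _ in iter_cohort(sim_config)), analysis_config
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        dump_config(sim_config, analysis_config, outdir / "config.yaml")
        _write_frame(analysis.zscores_frame(), outdir / "zscores.csv", run_hash)
        _write_frame(analysis.detections_frame(), outdir / "detections.csv", run_hash)
        _write_frame(analysis.lead_table(), outdir / "lead_times.csv", run_hash)
        _write_frame(
            analysis.performance_frame(), outdir / "performance.csv", run_hash
        )
        _write_frame(
            analysis.trajectories_frame(), outdir / "trajectories.csv", run_hash
        )
        _write_frame(analysis.exclusions_frame(), outdir / "exclusions.csv", run_hash)
        log_lines = [
            f"config_hash={run_hash}",
            f"patients={len(analysis.patients)}",
            f"eligible={len(analysis.eligible)}",
            f"events={len(analysis.event_patients)}",
        ]
        for p in analysis.excluded:
            log_lines.append(
                f"excluded {p.patient_id} ({p.arm}): "
                + (";".join(p.exclusion_reasons) or "unspecified")
            )
        if not analysis.event_patients:
            log_lines.append("no events: lead-time and performance tables are empty")
        (outdir / "run.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
        if make_plots and analysis.event_patients:
            from .plots import plot_trajectories

            plot_trajectories(
                analysis, outdir / "figures", threshold=analysis_config.threshold
            )
    return analysis
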