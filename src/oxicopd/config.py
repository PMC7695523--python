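"""Run configuration for simulation and analysis.

Two pydantic models hold every tunable of the pipeline: :class:`SimConfig`
parameterizes the synthetic monitoring cohort (baseline levels, day-to-day
variability per monitoring arm, prodromal drift, sampling design, missingness)
and :class:`AnalysisConfig` parameterizes the detection analysis (threshold,
direction, window conventions).  Validation errors name the offending field.
"""

from __future__ import annotations

import hashlib
import json
from datetime import date
from typing import Literal

import yaml
from pydantic import BaseModel, Field, model_validator


class SimConfig(BaseModel):
    """Synthetic-cohort settings.

    Defaults encode the stable-state statistics of a home-monitored COPD
    cohort: overnight averaging yields a markedly smaller day-to-day SD than a
    single morning spot reading (heart rate 1.8 vs 3.6 beats/min, SpO2 0.36 vs
    0.81 %), and an exacerbation is preceded by a roughly linear prodromal
    drift peaking on the day treatment starts (heart rate +10 beats/min
    overnight / +7 once-daily, SpO2 -1.2 % / -2.0 %, CAT +7 points, PEF
    -34 L/min), followed by a linear recovery.
    """

    model_config = {"extra": "forbid"}

    n_patients: int = Field(default=83, ge=0)
    #: fraction of patients assigned to the overnight-monitoring arm
    arm_split: float = Field(default=0.5, ge=0.0, le=1.0)
    #: fraction of patients (per arm) whose monitoring ends in an exacerbation
    exacerbation_fraction: float = Field(default=0.325, ge=0.0, le=1.0)

    # stable-state levels and day-to-day SDs, per arm where the measurement
    # design differs (units: beats/min, %, CAT points, L/min)
    baseline_hr_overnight: float = 70.0
    sd_hr_overnight: float = Field(default=1.8, ge=0.0)
    baseline_hr_once_daily: float = 77.1
    sd_hr_once_daily: float = Field(default=3.6, ge=0.0)
    baseline_spo2_overnight: float = 91.0
    sd_spo2_overnight: float = Field(default=0.36, ge=0.0)
    baseline_spo2_once_daily: float = 94.0
    sd_spo2_once_daily: float = Field(default=0.81, ge=0.0)
    baseline_cat: float = 15.6
    sd_cat: float = Field(default=1.46, ge=0.0)
    baseline_pef: float = 214.0
    sd_pef: float = Field(default=13.8, ge=0.0)

    # maximal prodromal effects, reached on the day treatment starts
    delta_hr_overnight: float = 10.0
    delta_hr_once_daily: float = 7.0
    delta_spo2_overnight: float = -1.2
    delta_spo2_once_daily: float = -2.0
    delta_cat: float = 7.0
    delta_pef: float = -34.0
    prodrome_days: int = Field(default=7, ge=1)
    recovery_days: int = Field(default=13, ge=0)

    # overnight sampling design and measurement noise
    night_length_h: float = Field(default=7.0, gt=0.0)
    sample_interval_s: int = Field(default=4, gt=0)
    within_night_sd_hr: float = Field(default=8.0, ge=0.0)
    within_night_sd_spo2: float = Field(default=2.0, ge=0.0)
    #: extra measurement noise on the once-daily spot reading, on top of the
    #: day-to-day physiological variation already carried by sd_*_once_daily
    spot_noise_sd_hr: float = Field(default=0.0, ge=0.0)
    spot_noise_sd_spo2: float = Field(default=0.0, ge=0.0)

    #: correlation between day-level heart-rate and SpO2 fluctuations in the
    #: stable state; governs the composite score's false-alarm behaviour
    stable_corr_hr_spo2: float = Field(default=0.72, ge=-1.0, le=1.0)

    missing_day_prob: float = Field(default=0.03, ge=0.0, le=1.0)
    #: probability that an event patient loses a 2-day run inside the
    #: pre-exacerbation fortnight (exercises the exclusion rule)
    consecutive_miss_prob: float = Field(default=0.05, ge=0.0, le=1.0)

    #: monitoring span for patients who never exacerbate
    monitoring_days_no_event: int = Field(default=56, ge=35)
    monitoring_start: date = date(2017, 1, 1)
    seed: int = Field(default=0, ge=0, lt=2**31)

    @model_validator(mode="after")
    def _check_sampling_grid(self) -> "SimConfig":
        night_s = self.night_length_h * 3600.0
        n = night_s / self.sample_interval_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                "sample_interval_s must divide night_length_h * 3600 "
                f"(got {self.sample_interval_s} s over {night_s:g} s)"
            )
        return self

    @property
    def samples_per_night(self) -> int:
        return int(round(self.night_length_h * 3600.0 / self.sample_interval_s))


class AnalysisConfig(BaseModel):
    """Detection-analysis settings.

    ``threshold`` is in baseline-SD units; 1.96 corresponds to the nominal
    95% band of the stable-state distribution.  ``direction`` chooses between
    flagging any excursion (``two_sided``) or only the physiologically
    expected one (``directional``: up for heart rate, CAT and the composite
    score, down for SpO2 and PEF).
    """

    model_config = {"extra": "forbid"}

    threshold: float = Field(default=1.96, gt=0.0)
    direction: Literal["two_sided", "directional"] = "two_sided"
    #: number of consecutive abnormal days required to flag (false-alarm control)
    consecutive_days_required: int = Field(default=1, ge=1)
    pre_window_start: int = Field(default=-14, ge=-14, le=0)
    pre_window_end: int = Field(default=0, ge=-14, le=0)
    post_phase_includes_day0: bool = False
    nightly_statistic: Literal["mean", "median"] = "mean"
    mcid_cat: float = Field(default=2.0, gt=0.0)
    seed: int = Field(default=0, ge=0, lt=2**31)

    @model_validator(mode="after")
    def _check_window(self) -> "AnalysisConfig":
        if self.pre_window_start > self.pre_window_end:
            raise ValueError("pre_window_start must be <= pre_window_end")
        return self

    @property
    def pre_window(self) -> tuple[int, int]:
        return (self.pre_window_start, self.pre_window_end)


def load_config(path) -> tuple[SimConfig, AnalysisConfig]:
    """Read a YAML file with optional ``simulate:`` and ``analysis:`` sections."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    sim = SimConfig(**(raw.get("simulate") or {}))
    ana = AnalysisConfig(**(raw.get("analysis") or {}))
    return sim, ana


def dump_config(sim: SimConfig, ana: AnalysisConfig, path) -> None:
    """Write the fully resolved configuration back to YAML."""
    payload = {
        "simulate": json.loads(sim.model_dump_json()),
        "analysis": json.loads(ana.model_dump_json()),
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def config_hash(sim: SimConfig, ana: AnalysisConfig) -> str:
    """Short stable hash of the resolved configuration, for provenance lines."""
    payload = json.dumps(
        {
            "simulate": json.loads(sim.model_dump_json()),
            "analysis": json.loads(ana.model_dump_json()),
        },
        sort_keys=True,
    )
    return hashlib.sha1(payload.encode()).hexdigest()[:12]
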