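"""Baseline calibration and Z-score machinery.

Each patient's stable fortnight defines a per-variable baseline mean ``x̄``
and sample SD ``s`` (n-1 denominator).  A daily value ``X`` is expressed in
baseline-SD units as ``Z = (X - x̄) / s``, so the same ±1.96 band applies to
every variable and every patient.  The composite oximetry score
``Z_HR - Z_SpO2`` rises with tachycardia and/or desaturation, the two
unidirectional physiological signatures of an exacerbation.
"""

from __future__ import annotations

from datetime import date
from typing import Optional

import numpy as np

from .daily import AlignedSeries, DailySeries
from .errors import DataError, DegenerateBaselineError
from .io import COMPOSITE

#: display-only index holding the stable-period mean (Z = 0 by construction)
STABLE_MEAN_INDEX = -15


class BaselineStats:
    """Per-patient, per-variable stable-window mean and SD."""

    __slots__ = ("patient_id", "variable", "mean", "sd", "n_days")

    def __init__(
        self, patient_id: str, variable: str, mean: float, sd: float, n_days: int
    ):
        if sd <= 0:
            raise DegenerateBaselineError(
                f"zero-variance stable window for {patient_id}/{variable}: "
                "Z scores are undefined"
            )
        self.patient_id = patient_id
        self.variable = variable
        self.mean = float(mean)
        self.sd = float(sd)
        self.n_days = int(n_days)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"BaselineStats({self.patient_id}/{self.variable}: "
            f"mean={self.mean:.3g}, sd={self.sd:.3g}, n={self.n_days})"
        )


class ZSeries:
    """Event-aligned Z scores for one patient and variable.

    ``z`` maps day indices (-15..+13) to dimensionless values; index -15 is
    the stable-period mean, stored as 0 for display and excluded from all
    statistics and detection.
    """

    __slots__ = ("patient_id", "variable", "z")

    def __init__(self, patient_id: str, variable: str, z: dict[int, float]):
        self.patient_id = patient_id
        self.variable = variable
        self.z = z

    def data_days(self) -> dict[int, float]:
        """Z values on real data days (the display index removed)."""
        return {d: v for d, v in self.z.items() if d != STABLE_MEAN_INDEX}


def baseline_stats(series: DailySeries, stable_window: list[date]) -> BaselineStats:
    """Mean and sample SD (n-1) over the 14-day stable window.

    Every window day must be observed; the window search is responsible for
    guaranteeing that.  A zero SD raises :class:`DegenerateBaselineError`
    rather than flooring the denominator: a fortnight with no variation at
    all indicates broken input, not a quiet patient.
    """
    missing = [d for d in stable_window if d not in series.values]
    if missing:
        raise DataError(
            f"stable window has missing days for {series.patient_id}/"
            f"{series.variable}: {missing[0].isoformat()}"
        )
    vals = np.array([series.values[d] for d in stable_window], dtype=float)
    return BaselineStats(
        patient_id=series.patient_id,
        variable=series.variable,
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=1)),
        n_days=len(vals),
    )


def zscore(x: float, baseline: BaselineStats) -> float:
    """``(X - x̄) / s`` in baseline-SD units."""
    return (float(x) - baseline.mean) / baseline.sd


def composite_score(z_hr: Optional[float], z_spo2: Optional[float]) -> Optional[float]:
    """Composite oximetry score ``Z_HR - Z_SpO2``; missing if either input is."""
    if z_hr is None or z_spo2 is None:
        return None
    return z_hr - z_spo2


def zseries(aligned: AlignedSeries, baseline: BaselineStats) -> ZSeries:
    """Z-transform an event-aligned series; adds the day -15 display value."""
    z = {idx: zscore(v, baseline) for idx, v in aligned.values.items()}
    z[STABLE_MEAN_INDEX] = 0.0
    return ZSeries(patient_id=aligned.patient_id, variable=aligned.variable, z=z)


def composite_zseries(z_hr: ZSeries, z_spo2: ZSeries) -> ZSeries:
    """Per-day composite score wherever both HR and SpO2 Z exist."""
    hr, sp = z_hr.data_days(), z_spo2.data_days()
    z = {d: hr[d] - sp[d] for d in hr.keys() & sp.keys()}
    z[STABLE_MEAN_INDEX] = 0.0
    return ZSeries(patient_id=z_hr.patient_id, variable=COMPOSITE, z=z)


def baseline_window_z(
    series: DailySeries, stable_window: list[date], baseline: BaselineStats
) -> np.ndarray:
    """Z of the stable-window days themselves (mean 0, sample SD 1 exactly)."""
    return np.array(
        [zscore(series.values[d], baseline) for d in stable_window], dtype=float
    )


def mcid_flags(
    cat_series: AlignedSeries, baseline: BaselineStats, mcid: float = 2.0
) -> set[int]:
    """Day indices where CAT exceeds the baseline mean by at least the MCID.

    The minimal clinically important difference for the CAT questionnaire is
    2 points, a raw-points criterion deliberately separate from the SD-based
    statistical threshold.
    """
    return {
        idx for idx, v in cat_series.values.items() if v - baseline.mean >= mcid
    }
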