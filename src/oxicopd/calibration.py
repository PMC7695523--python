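"""False-alarm calibration of the ±threshold detection band.

If daily values were exactly Gaussian and the baseline mean/SD were known,
|Z| >= 1.96 would flag 5% of stable patient-days by construction.  In
practice the baseline is estimated from a single fortnight, which inflates
the rate (the estimated mean and SD are themselves noisy — a Student-t
effect).  :func:`false_alarm_rates` measures both rates on a no-event
simulation, using the overnight arm's nightly means, whose within-night
averaging makes the daily values effectively continuous Gaussian.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .config import AnalysisConfig, SimConfig
from .daily import build_daily_series, find_stable_window
from .errors import DataError
from .io import ARM_OVERNIGHT, HR, SPO2
from .scoring import baseline_stats


def false_alarm_rates(
    sim_config: SimConfig, analysis_config: Optional[AnalysisConfig] = None
) -> dict[str, float]:
    """Per-day two-sided flag rates on stable (no-event) overnight data.

    Returns rates (fractions) and patient-day counts for Z computed with the
    generator's true mean/SD over all post-run-in days, and with the
    estimated 14-day baseline over the days outside the baseline window.
    """
    from .cohort import iter_cohort

    if sim_config.exacerbation_fraction != 0.0:
        raise DataError("false-alarm calibration requires a no-event simulation")
    cfg = analysis_config or AnalysisConfig()
    thr = cfg.threshold

    flags_true = days_true = 0
    flags_est = days_est = 0
    for record, truth in iter_cohort(sim_config):
        if record.arm != ARM_OVERNIGHT:
            continue
        daily = build_daily_series(record, nightly_statistic=cfg.nightly_statistic)
        for v in (HR, SPO2):
            vals = np.array(list(daily[v].values.values()), dtype=float)
            z_true = (vals - truth.true_baselines[v]) / truth.true_sds[v]
            flags_true += int((np.abs(z_true) >= thr).sum())
            days_true += len(vals)
        window = find_stable_window(daily, record.monitoring_start, None)
        if window is None:
            continue
        in_window = set(window)
        for v in (HR, SPO2):
            baseline = baseline_stats(daily[v], window)
            out_vals = np.array(
                [x for d, x in daily[v].values.items() if d not in in_window],
                dtype=float,
            )
            z_est = (out_vals - baseline.mean) / baseline.sd
            flags_est += int((np.abs(z_est) >= thr).sum())
            days_est += len(out_vals)

    return {
        "rate_true_baseline": flags_true / days_true if days_true else float("nan"),
        "rate_estimated_baseline": flags_est / days_est
        if days_est
        else float("nan"),
        "n_patient_days_true": days_true,
        "n_patient_days_estimated": days_est,
    }
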