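"""Independent brute-force recomputation of the Z pipeline, for oracle tests.

Deliberately written with plain Python containers, the ``statistics`` module
and per-sample loops/vector casts — no reuse of the package's aggregation,
baselining or detection code — so agreement is evidence, not tautology.
"""

from __future__ import annotations

import csv
import statistics
from datetime import date, datetime, timedelta

import numpy as np

VARS = ("HR", "SpO2", "CAT", "PEF")


def _sample_day(ts: np.datetime64, overnight: bool):
    # overnight sessions end by 06:00, so shifting 18 h lands every sample
    # on the waking morning's date; spot readings keep their own date
    if overnight:
        ts = ts + np.timedelta64(18 * 3600, "s")
    return ts.astype("datetime64[D]").astype(object)


def oracle_daily(record) -> dict[str, dict[date, float]]:
    """Daily values from raw samples/diary, run-in week removed.

    Works per sample (day assignment by a fixed clock shift), not per
    session, so its grouping logic shares nothing with the package's.
    """
    overnight = record.arm == "overnight"
    shift = np.timedelta64(18 * 3600 if overnight else 0, "s")
    day_chunks, hr_chunks, sp_chunks = [], [], []
    for rec in record.recordings:
        hr = np.asarray(rec.heart_rate, dtype=float)
        sp = np.asarray(rec.spo2, dtype=float)
        ok = (hr >= 20) & (hr <= 250) & (sp >= 50) & (sp <= 100)
        day_chunks.append((rec.timestamps[ok] + shift).astype("datetime64[D]"))
        hr_chunks.append(hr[ok])
        sp_chunks.append(sp[ok])
    daily: dict[str, dict[date, float]] = {v: {} for v in VARS}
    if day_chunks:
        days = np.concatenate(day_chunks)
        hr = np.concatenate(hr_chunks)
        sp = np.concatenate(sp_chunks)
        uniq, inverse = np.unique(days, return_inverse=True)
        counts = np.bincount(inverse)
        hr_means = np.bincount(inverse, weights=hr) / counts
        sp_means = np.bincount(inverse, weights=sp) / counts
        for d, mh, ms in zip(uniq.astype(object), hr_means, sp_means):
            daily["HR"][d] = float(mh)
            daily["SpO2"][d] = float(ms)
    for entry in record.diary:
        daily["CAT"][entry.date] = float(entry.cat)
        daily["PEF"][entry.date] = float(entry.pef)
    cutoff = record.monitoring_start + timedelta(days=7)
    return {
        v: {d: x for d, x in series.items() if d >= cutoff}
        for v, series in daily.items()
    }


def oracle_stable_window(daily, monitoring_start, treatment_day):
    last = max(d for series in daily.values() for d in series)
    end = (
        treatment_day - timedelta(days=15) if treatment_day is not None else last
    )
    day = monitoring_start + timedelta(days=7)
    while day + timedelta(days=13) <= end:
        window = [day + timedelta(days=k) for k in range(14)]
        if all(d in daily[v] for v in VARS for d in window):
            return window
        day += timedelta(days=1)
    return None


def oracle_zseries(record) -> dict[str, dict[int, float]] | None:
    """Event-aligned Z per variable (plus composite); None if not computable."""
    if record.treatment_day is None:
        return None
    daily = oracle_daily(record)
    window = oracle_stable_window(
        daily, record.monitoring_start, record.treatment_day
    )
    if window is None:
        return None
    z: dict[str, dict[int, float]] = {}
    for v in VARS:
        mean = statistics.fmean(daily[v][d] for d in window)
        sd = statistics.stdev(daily[v][d] for d in window)
        z[v] = {}
        for idx in range(-14, 14):
            d = record.treatment_day + timedelta(days=idx)
            if d in daily[v]:
                z[v][idx] = (daily[v][d] - mean) / sd
    z["composite"] = {
        idx: z["HR"][idx] - z["SpO2"][idx]
        for idx in z["HR"]
        if idx in z["SpO2"]
    }
    return z


def oracle_detect(zmap: dict[int, float], threshold: float = 1.96):
    """Brute scan: abnormal days and first abnormal day in -14..0."""
    abnormal = set()
    for d, v in zmap.items():
        if v >= threshold or v <= -threshold:
            abnormal.add(d)
    in_pre = [d for d in abnormal if -14 <= d <= 0]
    return abnormal, (min(in_pre) if in_pre else None)


# -- CSV-level variant -------------------------------------------------------


def oracle_zseries_from_csv(outdir, patient_id) -> dict[str, dict[int, float]] | None:
    """Same recomputation straight from the written CSV files."""
    with open(outdir / "manifest.csv", newline="") as fh:
        manifest = {r["patient_id"]: r for r in csv.DictReader(fh)}
    arm = manifest[patient_id]["arm"]
    tday_raw = manifest[patient_id]["treatment_day"]
    if not tday_raw:
        return None
    treatment_day = date.fromisoformat(tday_raw)

    daily: dict[str, dict[date, float]] = {v: {} for v in VARS}
    acc: dict[date, list[tuple[float, float]]] = {}
    min_day = None
    with open(outdir / "oximetry.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            if row["patient_id"] != patient_id:
                continue
            ts = datetime.fromisoformat(row["timestamp"])
            if arm == "overnight":
                d = (ts + timedelta(hours=18)).date()
            else:
                d = ts.date()
            hr, sp = float(row["heart_rate"]), float(row["spo2"])
            if min_day is None or ts.date() < min_day:
                min_day = ts.date()
            if 20 <= hr <= 250 and 50 <= sp <= 100:
                acc.setdefault(d, []).append((hr, sp))
    for d, pairs in acc.items():
        daily["HR"][d] = statistics.fmean(p[0] for p in pairs)
        daily["SpO2"][d] = statistics.fmean(p[1] for p in pairs)
    with open(outdir / "diary.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            if row["patient_id"] != patient_id:
                continue
            d = date.fromisoformat(row["date"])
            if min_day is None or d < min_day:
                min_day = d
            daily["CAT"][d] = float(row["cat"])
            daily["PEF"][d] = float(row["pef"])
    cutoff = min_day + timedelta(days=7)
    daily = {
        v: {d: x for d, x in series.items() if d >= cutoff}
        for v, series in daily.items()
    }
    window = oracle_stable_window(daily, min_day, treatment_day)
    if window is None:
        return None
    z: dict[str, dict[int, float]] = {}
    for v in VARS:
        mean = statistics.fmean(daily[v][d] for d in window)
        sd = statistics.stdev(daily[v][d] for d in window)
        z[v] = {
            idx: (daily[v][treatment_day + timedelta(days=idx)] - mean) / sd
            for idx in range(-14, 14)
            if treatment_day + timedelta(days=idx) in daily[v]
        }
    z["composite"] = {
        idx: z["HR"][idx] - z["SpO2"][idx]
        for idx in z["HR"]
        if idx in z["SpO2"]
    }
    return z
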