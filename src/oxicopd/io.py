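"""Reading and writing the pipeline's plain-CSV monitoring formats.

Three schemas move data in and out of the pipeline:

``oximetry.csv``
    ``patient_id,timestamp,heart_rate,spo2`` — one row per pulse-oximeter
    sample.  Overnight-arm patients contribute a 4-second sample stream per
    night; once-daily patients a single morning spot reading per day.
``diary.csv``
    ``patient_id,date,cat,pef`` — one diary-card row per patient-day with the
    CAT symptom score (0-40) and peak expiratory flow (L/min).
``manifest.csv``
    ``patient_id,arm,treatment_day`` — cohort metadata; ``treatment_day`` is
    the date exacerbation treatment started, empty for non-event patients.

Timestamps are ISO-8601; files are UTF-8, comma-separated.  Physiologically
impossible oximetry readings (heart rate outside 20-250 beats/min, SpO2
outside 50-100 %) are retained on read but flagged invalid so that downstream
QC counts remain auditable.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from datetime import date, datetime
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .errors import DataError, FormatError

ARM_ONCE_DAILY = "once_daily"
ARM_OVERNIGHT = "overnight"
ARMS = (ARM_ONCE_DAILY, ARM_OVERNIGHT)

HR = "HR"
SPO2 = "SpO2"
CAT = "CAT"
PEF = "PEF"
COMPOSITE = "composite"
#: the four directly monitored variables (the composite score is derived)
VARIABLES = (HR, SPO2, CAT, PEF)

HR_RANGE = (20.0, 250.0)
SPO2_RANGE = (50.0, 100.0)

_OXI_COLUMNS = ("patient_id", "timestamp", "heart_rate", "spo2")
_DIARY_COLUMNS = ("patient_id", "date", "cat", "pef")
_MANIFEST_COLUMNS = ("patient_id", "arm", "treatment_day")


@dataclass
class OximetryRecording:
    """A contiguous run of pulse-oximeter samples for one patient.

    For the overnight arm this is one night's 4-second stream; for the
    once-daily arm a single morning reading.  Timestamps are strictly
    increasing ``datetime64[s]``.
    """

    patient_id: str
    timestamps: np.ndarray
    heart_rate: np.ndarray
    spo2: np.ndarray

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def valid(self) -> np.ndarray:
        """Mask of samples inside the physiologic ranges."""
        hr = np.asarray(self.heart_rate, dtype=float)
        sp = np.asarray(self.spo2, dtype=float)
        return (
            (hr >= HR_RANGE[0])
            & (hr <= HR_RANGE[1])
            & (sp >= SPO2_RANGE[0])
            & (sp <= SPO2_RANGE[1])
        )

    @property
    def morning_date(self) -> date:
        """Calendar date of the final sample (the waking morning)."""
        last = self.timestamps[-1].astype("datetime64[D]")
        return last.astype(object)

    @property
    def start_date(self) -> date:
        first = self.timestamps[0].astype("datetime64[D]")
        return first.astype(object)


@dataclass(frozen=True)
class DiaryEntry:
    """One diary-card day: CAT symptom score and peak expiratory flow."""

    date: date
    cat: int
    pef: float


@dataclass(frozen=True)
class ManifestEntry:
    patient_id: str
    arm: str
    treatment_day: Optional[date]


@dataclass
class PatientRecord:
    """Everything monitored for one patient, before daily aggregation."""

    patient_id: str
    arm: str
    recordings: list[OximetryRecording] = field(default_factory=list)
    diary: list[DiaryEntry] = field(default_factory=list)
    treatment_day: Optional[date] = None
    monitoring_start: Optional[date] = None

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise DataError(f"unknown arm '{self.arm}' for patient {self.patient_id}")
        if (
            self.treatment_day is not None
            and self.monitoring_start is not None
            and self.treatment_day <= self.monitoring_start
        ):
            raise DataError(
                f"treatment_day must fall after monitoring_start for {self.patient_id}"
            )


def parse_arm(label: str, patient_id: str = "?") -> str:
    label = str(label).strip()
    if label not in ARMS:
        raise DataError(f"unknown arm '{label}' for patient {patient_id}")
    return label


def _require_columns(df: pd.DataFrame, required: tuple[str, ...], what: str) -> None:
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{what} file is missing column '{col}'")


def read_oximetry(path) -> list[OximetryRecording]:
    """Read raw pulse-oximetry samples, one recording per patient.

    Samples are grouped by patient and sorted by timestamp; out-of-range
    values are retained (the :attr:`OximetryRecording.valid` mask flags
    them).  Use :func:`split_sessions` to cut a patient's stream into
    per-night recordings.
    """
    df = pd.read_csv(path, comment="#", dtype={"patient_id": str})
    _require_columns(df, _OXI_COLUMNS, "oximetry")
    if df.empty:
        return []
    ts = pd.to_datetime(df["timestamp"], errors="coerce")
    bad = ts.isna()
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
        raise FormatError(
            f"unparseable timestamp {df['timestamp'].iloc[line - 2]!r} "
            f"at line {line}"
        )
    df = df.assign(_ts=ts.to_numpy().astype("datetime64[s]"))
    out: list[OximetryRecording] = []
    for pid, grp in df.groupby("patient_id", sort=True):
        grp = grp.sort_values("_ts", kind="mergesort")
        stamps = grp["_ts"].to_numpy()
        if len(stamps) > 1 and (np.diff(stamps).astype(int) <= 0).any():
            raise DataError(f"duplicate timestamps for patient {pid}")
        out.append(
            OximetryRecording(
                patient_id=str(pid),
                timestamps=stamps,
                heart_rate=grp["heart_rate"].to_numpy(dtype=float),
                spo2=grp["spo2"].to_numpy(dtype=float),
            )
        )
    return out


def split_sessions(
    recording: OximetryRecording, max_gap_s: float = 3600.0
) -> list[OximetryRecording]:
    """Cut a sample stream into contiguous sessions (nights or spot readings).

    A new session starts wherever consecutive samples are separated by more
    than ``max_gap_s`` seconds.
    """
    if len(recording) == 0:
        return []
    gaps = np.diff(recording.timestamps).astype("timedelta64[s]").astype(float)
    cuts = np.flatnonzero(gaps > max_gap_s) + 1
    if len(cuts) == 0:
        return [recording]
    pieces = []
    for lo, hi in zip(np.r_[0, cuts], np.r_[cuts, len(recording)]):
        pieces.append(
            OximetryRecording(
                patient_id=recording.patient_id,
                timestamps=recording.timestamps[lo:hi],
                heart_rate=recording.heart_rate[lo:hi],
                spo2=recording.spo2[lo:hi],
            )
        )
    return pieces


def read_diary(path) -> dict[str, list[DiaryEntry]]:
    """Read diary-card entries; at most one entry per patient-date."""
    df = pd.read_csv(path, comment="#", dtype={"patient_id": str})
    _require_columns(df, _DIARY_COLUMNS, "diary")
    out: dict[str, list[DiaryEntry]] = {}
    if df.empty:
        return out
    dates = pd.to_datetime(df["date"], errors="coerce")
    if dates.isna().any():
        line = int(np.flatnonzero(dates.isna().to_numpy())[0]) + 2
        raise FormatError(f"unparseable date at line {line} of diary file")
    df = df.assign(_date=dates.dt.date)
    dup = df.duplicated(subset=["patient_id", "_date"], keep=False)
    if dup.any():
        first = df.loc[dup].iloc[0]
        raise DataError(
            f"duplicate diary entry for patient {first['patient_id']} "
            f"on {first['_date'].isoformat()}"
        )
    cat = pd.to_numeric(df["cat"], errors="coerce")
    if cat.isna().any() or (cat < 0).any() or (cat > 40).any():
        idx = int(
            np.flatnonzero((cat.isna() | (cat < 0) | (cat > 40)).to_numpy())[0]
        )
        raise DataError(
            f"CAT score {df['cat'].iloc[idx]!r} out of range 0-40 at line {idx + 2}"
        )
    pef = pd.to_numeric(df["pef"], errors="coerce")
    if pef.isna().any() or (pef < 0).any():
        idx = int(np.flatnonzero((pef.isna() | (pef < 0)).to_numpy())[0])
        raise DataError(f"invalid PEF {df['pef'].iloc[idx]!r} at line {idx + 2}")
    for pid, grp in df.groupby("patient_id", sort=True):
        grp = grp.sort_values("_date")
        out[str(pid)] = [
            DiaryEntry(date=d, cat=int(c), pef=float(p))
            for d, c, p in zip(grp["_date"], cat[grp.index], pef[grp.index])
        ]
    return out


def read_manifest(path) -> dict[str, ManifestEntry]:
    """Read cohort metadata (arm and, if an event occurred, treatment date)."""
    df = pd.read_csv(path, comment="#", dtype={"patient_id": str})
    _require_columns(df, _MANIFEST_COLUMNS, "manifest")
    out: dict[str, ManifestEntry] = {}
    for i, row in df.iterrows():
        pid = str(row["patient_id"])
        if pid in out:
            raise DataError(f"duplicate manifest row for patient {pid}")
        arm = parse_arm(row["arm"], pid)
        raw = row["treatment_day"]
        tday: Optional[date] = None
        if not (pd.isna(raw) or str(raw).strip() == ""):
            parsed = pd.to_datetime(raw, errors="coerce")
            if pd.isna(parsed):
                raise FormatError(
                    f"unparseable treatment_day {raw!r} at line {int(i) + 2}"
                )
            tday = parsed.date()
        out[pid] = ManifestEntry(patient_id=pid, arm=arm, treatment_day=tday)
    return out


def assemble_records(
    oximetry_path, diary_path, manifest_path
) -> list[PatientRecord]:
    """Join the three CSVs into per-patient records.

    The monitoring start is taken as the earliest date observed for the
    patient across oximetry and diary data.
    """
    manifest = read_manifest(manifest_path)
    streams = {r.patient_id: r for r in read_oximetry(oximetry_path)}
    diaries = read_diary(diary_path)
    records = []
    for pid, entry in sorted(manifest.items()):
        sessions = (
            split_sessions(streams[pid]) if pid in streams else []
        )
        diary = diaries.get(pid, [])
        starts = [s.start_date for s in sessions] + [d.date for d in diary]
        if not starts:
            continue
        records.append(
            PatientRecord(
                patient_id=pid,
                arm=entry.arm,
                recordings=sessions,
                diary=diary,
                treatment_day=entry.treatment_day,
                monitoring_start=min(starts),
            )
        )
    return records


# ---------------------------------------------------------------------------
# writers


def write_oximetry(records: Iterable[PatientRecord], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_OXI_COLUMNS)
        for record in records:
            for rec in record.recordings:
                stamps = np.datetime_as_string(rec.timestamps, unit="s")
                for t, hr, sp in zip(stamps, rec.heart_rate, rec.spo2):
                    writer.writerow([record.patient_id, t, hr, sp])


def write_diary(records: Iterable[PatientRecord], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_DIARY_COLUMNS)
        for record in records:
            for entry in record.diary:
                writer.writerow(
                    [record.patient_id, entry.date.isoformat(), entry.cat, entry.pef]
                )


def write_manifest(records: Iterable[PatientRecord], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_MANIFEST_COLUMNS)
        for record in records:
            tday = (
                record.treatment_day.isoformat() if record.treatment_day else ""
            )
            writer.writerow([record.patient_id, record.arm, tday])
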