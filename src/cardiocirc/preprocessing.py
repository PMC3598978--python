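"""I/O and preprocessing for RR and ambulatory heart-rate series.

Two kinds of input are supported, mirroring how circadian heart-rate
data are typically collected:

* dense beat-to-beat RR streams (one row per beat, ~1e5 beats per
  subject per 24 h), which are thinned to one value per minute before
  modelling;
* sparse ambulatory monitor readings (heart rate in beats/min on a
  clinic schedule, e.g. every 15 min by day and every 30 min by night),
  converted to RR via RR = 60000 / HR.

CSV is the canonical interchange format: comma-separated, header row,
UTF-8, '.' decimal separator.  Beat-annotation files from archival ECG
databases are ingested via pre-exported text RR lists in this CSV form;
no binary parsing is done here.

Recordings that cross midnight carry a monotone ``elapsed_hours`` axis
internally; clock hour (mod 24) is only taken at model evaluation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_core import SubjectProfile

__all__ = [
    "RRSeries",
    "AmbulatoryHRSeries",
    "CSVFormatError",
    "SeriesValidationError",
    "read_rr_csv",
    "read_ambulatory_csv",
    "hr_to_rr",
    "resample_every_minute",
]


class CSVFormatError(ValueError):
    """The file does not have the expected columns/layout."""


class SeriesValidationError(ValueError):
    """Rows violate a series invariant (e.g. non-positive RR)."""


@dataclass
class RRSeries:
    """Time-stamped RR intervals for one subject.

    ``hours`` are clock times reduced into [0, 24); ``elapsed_hours``,
    when present, is the monotone acquisition axis (may exceed 24 for
    recordings crossing midnight).  ``rr_ms`` must be strictly positive.
    """

    subject: SubjectProfile
    hours: np.ndarray
    rr_ms: np.ndarray
    elapsed_hours: np.ndarray | None = field(default=None)

    def __post_init__(self):
        self.hours = np.mod(np.asarray(self.hours, dtype=float), 24.0)
        self.rr_ms = np.asarray(self.rr_ms, dtype=float)
        if self.hours.shape != self.rr_ms.shape:
            raise SeriesValidationError("hours and rr_ms must have equal length")
        if self.rr_ms.size and not np.all(self.rr_ms > 0):
            bad = np.flatnonzero(~(self.rr_ms > 0))
            raise SeriesValidationError(f"rr_ms must be > 0 (bad indices: {bad[:10].tolist()})")
        if self.elapsed_hours is not None:
            self.elapsed_hours = np.asarray(self.elapsed_hours, dtype=float)
            if self.elapsed_hours.shape != self.rr_ms.shape:
                raise SeriesValidationError("elapsed_hours must match rr_ms length")
            if self.elapsed_hours.size > 1 and np.any(np.diff(self.elapsed_hours) < 0):
                raise SeriesValidationError("elapsed_hours must be non-decreasing")

    def __len__(self) -> int:
        return self.rr_ms.size

    def log_rr(self) -> np.ndarray:
        return np.log(self.rr_ms)


@dataclass
class AmbulatoryHRSeries:
    """Sparse ambulatory heart-rate readings (beats/min) for one subject.

    The typical monitor schedule is every 15 min from 08:00 to 22:00 and
    every 30 min from 22:00 to 08:00 (documented, not enforced).
    """

    subject: SubjectProfile
    hours: np.ndarray
    hr_bpm: np.ndarray
    elapsed_hours: np.ndarray | None = field(default=None)

    def __post_init__(self):
        self.hours = np.mod(np.asarray(self.hours, dtype=float), 24.0)
        self.hr_bpm = np.asarray(self.hr_bpm, dtype=float)
        if self.hours.shape != self.hr_bpm.shape:
            raise SeriesValidationError("hours and hr_bpm must have equal length")
        if self.hr_bpm.size and not np.all(self.hr_bpm > 0):
            bad = np.flatnonzero(~(self.hr_bpm > 0))
            raise SeriesValidationError(f"hr_bpm must be > 0 (bad indices: {bad[:10].tolist()})")
        if self.elapsed_hours is not None:
            self.elapsed_hours = np.asarray(self.elapsed_hours, dtype=float)

    def __len__(self) -> int:
        return self.hr_bpm.size

    def to_rr_series(self) -> RRSeries:
        """Convert readings to an RR series via RR = 60000 / HR."""
        return RRSeries(self.subject, self.hours, hr_to_rr(self.hr_bpm),
                        elapsed_hours=self.elapsed_hours)


def hr_to_rr(hr_bpm):
    """RR interval (ms) from heart rate (beats/min): RR = 60000 / HR."""
    hr = np.asarray(hr_bpm, dtype=float)
    if hr.size and not np.all(hr > 0):
        raise ValueError("heart rate must be > 0 beats/min")
    rr = 60000.0 / hr
    return float(rr) if np.ndim(hr_bpm) == 0 else rr


def _load_csv(path, value_col: str):
    required = ["subject_id", "sex", "age", "hour", value_col]
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise CSVFormatError(f"{path}: empty file without header") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CSVFormatError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        warnings.warn(f"{path}: no data rows (header only)", stacklevel=3)
        return df
    # line numbers: header is line 1, first data row line 2
    lines = df.index.to_numpy() + 2
    numeric = df[["sex", "age", "hour", value_col]].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1).to_numpy()
    if bad.any():
        raise SeriesValidationError(
            f"{path}: malformed/non-numeric rows at lines {lines[bad][:10].tolist()}")
    nonpos = (numeric[value_col] <= 0).to_numpy()
    if nonpos.any():
        raise SeriesValidationError(
            f"{path}: non-positive {value_col} at lines {lines[nonpos][:10].tolist()}")
    df[["sex", "age", "hour", value_col]] = numeric
    return df


def _split_subjects(df, value_col, cls):
    out = []
    for sid, grp in df.groupby("subject_id", sort=False):
        subject = SubjectProfile(str(sid), int(grp["sex"].iloc[0]), float(grp["age"].iloc[0]))
        elapsed = grp["elapsed_hour"].to_numpy(float) if "elapsed_hour" in grp else None
        out.append(cls(subject, grp["hour"].to_numpy(float),
                       grp[value_col].to_numpy(float), elapsed_hours=elapsed))
    return out


def read_rr_csv(path) -> list[RRSeries]:
    """Read an RR CSV (columns subject_id, sex, age, hour, rr_ms).

    Multi-subject files are split on ``subject_id``; an optional
    ``elapsed_hour`` column carries the monotone time axis for
    recordings crossing midnight.  Returns one :class:`RRSeries` per
    subject (empty list for a header-only file, with a warning).
    """
    df = _load_csv(path, "rr_ms")
    return _split_subjects(df, "rr_ms", RRSeries)


def read_ambulatory_csv(path) -> list[AmbulatoryHRSeries]:
    """Read an ambulatory HR CSV (columns subject_id, sex, age, hour, hr_bpm).

    Duplicate (subject, hour) rows are kept, with a warning.
    """
    df = _load_csv(path, "hr_bpm")
    if not df.empty and df.duplicated(subset=["subject_id", "hour"]).any():
        warnings.warn(f"{path}: duplicate (subject_id, hour) rows kept", stacklevel=2)
    return _split_subjects(df, "hr_bpm", AmbulatoryHRSeries)


def resample_every_minute(dense: RRSeries) -> RRSeries:
    """Thin a beat-level RR stream to one value per whole minute.

    For each minute tick after the start of the recording, keep the RR
    interval whose onset time is nearest the tick (earlier beat on a
    tie).  The output is stamped at the tick times; every output RR
    value appears in the input.  A recording of d minutes yields
    floor(d) samples; an empty input yields an empty series.
    """
    if len(dense) == 0:
        return RRSeries(dense.subject, np.array([]), np.array([]), elapsed_hours=np.array([]))
    t = dense.elapsed_hours
    if t is None:
        t = np.asarray(dense.hours, dtype=float)
        if t.size > 1 and np.any(np.diff(t) < 0):
            raise SeriesValidationError(
                "beat-level resampling needs a monotone time axis; "
                "provide elapsed_hours for recordings crossing midnight")
    duration_min = (t[-1] - t[0]) * 60.0
    n_ticks = int(np.floor(duration_min + 1e-9))
    if n_ticks < 1:
        return RRSeries(dense.subject, np.array([]), np.array([]), elapsed_hours=np.array([]))
    ticks = t[0] + np.arange(1, n_ticks + 1) / 60.0
    right = np.searchsorted(t, ticks)  # first onset >= tick (ties -> earlier kept below)
    left = np.clip(right - 1, 0, t.size - 1)
    right = np.clip(right, 0, t.size - 1)
    # earlier beat wins ties: strict '<' keeps the left beat when distances equal
    pick = np.where(np.abs(t[right] - ticks) < np.abs(t[left] - ticks), right, left)
    return RRSeries(dense.subject, np.mod(ticks, 24.0), dense.rr_ms[pick],
                    elapsed_hours=ticks)
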