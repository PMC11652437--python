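"""Hip-accelerometer count processing: non-wear, validity, and MVPA minutes.

Counts arrive in 10-s epochs. Non-wear is any run of zero counts
lasting strictly more than 60 min; a day is valid with at least 10 h
of wear. Epoch intensity is classified with the Freedson MET
prediction equation (METs = 1.439008 + 0.000795 x counts/min), an
epoch counting as MVPA at >= 4 METs, and daily MVPA minutes are the
MVPA epoch count / 6.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .config import FreedsonParams
from .gps import EPOCH_S, _day_type

NONWEAR_MINUTES = 60.0  # zero-count runs strictly longer than this are non-wear
VALID_WEAR_HOURS = 10.0  # days with < 10 h wear are invalid

__all__ = [
    "AccelSeries",
    "DayActivityRecord",
    "read_accel_csv",
    "detect_nonwear",
    "accel_day_valid",
    "counts_to_mets",
    "epoch_mvpa_mask",
    "day_mvpa_minutes",
    "process_accel_day",
]


@dataclass
class AccelSeries:
    """One participant-day of 10-s activity counts."""

    participant_id: str
    wave: str
    date: dt.date
    t: np.ndarray  # seconds since local midnight, strictly increasing
    counts: np.ndarray  # non-negative integers

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.t) != len(self.counts):
            raise ValueError("timestamp/count arrays differ in length")
        if len(self.t) and np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if len(self.counts) and self.counts.min() < 0:
            raise ValueError("counts must be non-negative")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def day_type(self) -> str:
        return _day_type(self.date)


@dataclass
class DayActivityRecord:
    participant_id: str
    wave: str
    date: dt.date
    day_type: str
    mvpa_minutes: float
    wear_hours: float
    valid: bool


def read_accel_csv(path, participant_id: str | None = None, wave: str | None = None) -> AccelSeries:
    """Read a one-day accelerometer CSV (columns timestamp_iso, counts)."""
    path = Path(path)
    if participant_id is None or wave is None:
        parts = path.stem.split("_")
        participant_id = participant_id or (parts[0] if len(parts) >= 2 else path.stem)
        wave = wave or (parts[1] if len(parts) >= 2 else "NA")
    times: list[dt.datetime] = []
    counts: list[int] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is not None and header[:2] != ["timestamp_iso", "counts"]:
            raise ValueError(f"{path}: expected header timestamp_iso,counts, got {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                times.append(dt.datetime.fromisoformat(row[0]))
                counts.append(int(row[1]))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: unparseable row at line {lineno}: {row!r}") from exc
    if not times:
        return AccelSeries(participant_id, wave, dt.date(1970, 1, 1), np.empty(0), np.empty(0))
    date = min(times).date()
    secs = np.array(
        [(ts - dt.datetime.combine(date, dt.time())).total_seconds() for ts in times], dtype=np.int64
    )
    order = np.argsort(secs, kind="stable")
    return AccelSeries(participant_id, wave, date, secs[order], np.asarray(counts)[order])


def detect_nonwear(series: AccelSeries, nonwear_minutes: float = NONWEAR_MINUTES) -> np.ndarray:
    """Per-epoch wear mask (True = worn).

    An epoch is non-wear iff it belongs to a maximal run of
    consecutive zero-count epochs lasting strictly more than
    ``nonwear_minutes`` (> 360 zero epochs at 10 s). A run of exactly
    60 min stays wear; any nonzero epoch restarts the run.
    """
    n = len(series)
    wear = np.ones(n, dtype=bool)
    if n == 0:
        return wear
    zero = series.counts == 0
    max_epochs = nonwear_minutes * 60.0 / EPOCH_S
    # maximal runs of zeros; a "run" only spans contiguous 10-s epochs
    boundaries = np.flatnonzero(
        np.diff(zero.astype(int)) != 0
    )
    starts = np.concatenate([[0], boundaries + 1])
    ends = np.concatenate([boundaries + 1, [n]])
    for s, e in zip(starts, ends):
        if zero[s] and (e - s) > max_epochs:
            wear[s:e] = False
    return wear


def accel_day_valid(series: AccelSeries, wear_mask: np.ndarray) -> tuple[bool, float]:
    """Day validity from wear time: valid iff wear >= 10 h (exactly 10 h passes)."""
    wear_hours = float(np.sum(wear_mask)) * EPOCH_S / 3600.0
    return wear_hours >= VALID_WEAR_HOURS, wear_hours


def counts_to_mets(cpm, params: FreedsonParams | None = None):
    """Freedson MET prediction from counts per minute."""
    params = params or FreedsonParams()
    cpm = np.asarray(cpm, dtype=float)
    if np.any(cpm < 0):
        raise ValueError("counts per minute must be non-negative")
    mets = params.intercept + params.slope * cpm
    return float(mets) if mets.ndim == 0 else mets


def epoch_mvpa_mask(
    series: AccelSeries, wear_mask: np.ndarray, params: FreedsonParams | None = None
) -> np.ndarray:
    """MVPA flag per epoch: worn and predicted METs >= 4.

    10-s counts scale by 6 to a per-minute rate before the MET
    equation; non-wear epochs are never MVPA.
    """
    params = params or FreedsonParams()
    mets = counts_to_mets(series.counts * (60 // EPOCH_S), params)
    return np.asarray(wear_mask, dtype=bool) & (mets >= params.mvpa_threshold)


def day_mvpa_minutes(mvpa_mask: np.ndarray) -> float:
    """Daily MVPA minutes: the number of 10-s MVPA epochs divided by 6."""
    return float(np.sum(mvpa_mask)) / (60 // EPOCH_S)


def process_accel_day(series: AccelSeries, params: FreedsonParams | None = None) -> DayActivityRecord:
    """Full day-level processing: non-wear, validity, MVPA minutes."""
    wear = detect_nonwear(series)
    valid, wear_hours = accel_day_valid(series, wear)
    mvpa = day_mvpa_minutes(epoch_mvpa_mask(series, wear, params))
    return DayActivityRecord(
        participant_id=series.participant_id,
        wave=series.wave,
        date=series.date,
        day_type=series.day_type,
        mvpa_minutes=mvpa,
        wear_hours=wear_hours,
        valid=valid,
    )
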