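"""Reading, gap imputation and validity flagging for 10-s GPS streams.

One file/track is one participant-day. Positions are planar metres;
timestamps are seconds since local midnight on a 10-s lattice. Days
with less than 6 h of data after imputation are invalid and excluded
from exposure assessment.
"""

from __future__ import annotations

import csv
import datetime as dt
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .config import ImputationParams

log = logging.getLogger(__name__)

EPOCH_S = 10  # GPS and accelerometer epoch length, seconds
VALID_GPS_HOURS = 6.0  # days with < 6 h of (post-imputation) data are invalid

__all__ = ["GpsTrack", "read_gps_csv", "impute_gaps", "gps_day_valid", "EPOCH_S"]


@dataclass
class GpsTrack:
    """One participant-day of timestamped planar positions at 10-s epochs."""

    participant_id: str
    wave: str  # T1 | T3 | PP
    date: dt.date
    day_type: str  # weekday | weekend
    t: np.ndarray  # seconds since local midnight, int, strictly increasing
    x: np.ndarray  # metres
    y: np.ndarray
    imputed: np.ndarray  # bool, per epoch

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.imputed = np.asarray(self.imputed, dtype=bool)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.imputed) == n):
            raise ValueError("epoch arrays have mismatched lengths")
        if n and np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if n and np.any(self.t % EPOCH_S != 0):
            raise ValueError("timestamps must lie on the 10-s lattice")
        if n and not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.t)


def _day_type(date: dt.date) -> str:
    return "weekend" if date.weekday() >= 5 else "weekday"


def read_gps_csv(path, participant_id: str | None = None, wave: str | None = None) -> GpsTrack:
    """Read a one-day GPS CSV (columns timestamp_iso, x_m, y_m).

    Rows are sorted by time; duplicate timestamps collapse to the first
    occurrence and off-lattice timestamps snap down, both with a logged
    warning. An empty file yields an empty track. Participant/wave
    default to the ``<pid>_<wave>_<day>.csv`` filename convention.
    """
    path = Path(path)
    if participant_id is None or wave is None:
        parts = path.stem.split("_")
        if len(parts) >= 2:
            participant_id = participant_id or parts[0]
            wave = wave or parts[1]
        else:
            participant_id = participant_id or path.stem
            wave = wave or "NA"

    times: list[dt.datetime] = []
    xs: list[float] = []
    ys: list[float] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is not None and header[:3] != ["timestamp_iso", "x_m", "y_m"]:
            raise ValueError(f"{path}: expected header timestamp_iso,x_m,y_m, got {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                times.append(dt.datetime.fromisoformat(row[0]))
                xs.append(float(row[1]))
                ys.append(float(row[2]))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: unparseable row at line {lineno}: {row!r}") from exc

    if not times:
        today = dt.date(1970, 1, 1)
        empty = np.empty(0)
        return GpsTrack(participant_id, wave, today, _day_type(today), empty, empty, empty, empty)

    date = min(times).date()
    secs = np.array(
        [(ts - dt.datetime.combine(date, dt.time())).total_seconds() for ts in times]
    )
    if np.any(secs % EPOCH_S != 0):
        log.warning("%s: %d timestamps off the 10-s lattice; snapped down", path,
                    int(np.sum(secs % EPOCH_S != 0)))
        secs = np.floor(secs / EPOCH_S) * EPOCH_S
    order = np.argsort(secs, kind="stable")
    secs, xs, ys = secs[order], np.asarray(xs)[order], np.asarray(ys)[order]
    keep = np.concatenate([[True], np.diff(secs) > 0])
    if not keep.all():
        log.warning("%s: %d duplicate timestamps collapsed to first occurrence",
                    path, int((~keep).sum()))
    secs, xs, ys = secs[keep], xs[keep], ys[keep]
    return GpsTrack(
        participant_id, wave, date, _day_type(date),
        secs.astype(np.int64), xs, ys, np.zeros(len(secs), dtype=bool),
    )


def impute_gaps(track: GpsTrack, params: ImputationParams | None = None) -> GpsTrack:
    """Fill internal gaps of a sorted track.

    For each gap between consecutive observed epochs: if the bounding
    positions are within ``stationary_radius`` of each other and the gap
    is at most ``stationary_gap_max`` minutes, the missing epochs take
    the earlier position (a dwell); otherwise if the gap is at most
    ``moving_gap_max`` minutes, positions are linearly interpolated.
    Longer gaps stay missing; leading/trailing missingness is never
    filled; observed epochs are untouched.
    """
    params = params or ImputationParams()
    n = len(track)
    if n < 2:
        return replace(track)
    if np.any(np.diff(track.t) <= 0):
        raise ValueError("track must be sorted with unique timestamps")

    t_out = [track.t]
    x_out = [track.x]
    y_out = [track.y]
    imp_out = [track.imputed]
    gaps = np.flatnonzero(np.diff(track.t) > EPOCH_S)
    for i in gaps:
        t0, t1 = track.t[i], track.t[i + 1]
        gap_min = (t1 - t0) / 60.0
        dx = track.x[i + 1] - track.x[i]
        dy = track.y[i + 1] - track.y[i]
        dist = float(np.hypot(dx, dy))
        t_fill = np.arange(t0 + EPOCH_S, t1, EPOCH_S, dtype=np.int64)
        if dist <= params.stationary_radius and gap_min <= params.stationary_gap_max:
            x_fill = np.full(t_fill.shape, track.x[i])
            y_fill = np.full(t_fill.shape, track.y[i])
        elif gap_min <= params.moving_gap_max:
            frac = (t_fill - t0) / (t1 - t0)
            x_fill = track.x[i] + frac * dx
            y_fill = track.y[i] + frac * dy
        else:
            continue
        t_out.append(t_fill)
        x_out.append(x_fill)
        y_out.append(y_fill)
        imp_out.append(np.ones(t_fill.shape, dtype=bool))

    t_all = np.concatenate(t_out)
    order = np.argsort(t_all, kind="stable")
    return replace(
        track,
        t=t_all[order],
        x=np.concatenate(x_out)[order],
        y=np.concatenate(y_out)[order],
        imputed=np.concatenate(imp_out)[order],
    )


def gps_day_valid(track: GpsTrack) -> tuple[bool, float]:
    """Day validity and coverage hours after imputation.

    Coverage counts every epoch (observed + imputed) at 10 s each; a
    day is valid iff coverage is at least 6 h (strictly-less-than-6-h
    days are invalid, so exactly 6 h passes).
    """
    coverage_hours = len(track) * EPOCH_S / 3600.0
    return coverage_hours >= VALID_GPS_HOURS, coverage_hours
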