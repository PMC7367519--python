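"""Minute-epoch wearable data I/O, validation, and wear-day segmentation.

The epoch CSV dialect is one row per participant-minute::

    participant_id,date,minute_of_day,met,steps,on_body,asleep
    P001,2020-01-06,0,0.900,0,1,1

UTF-8, mandatory header, comma-separated, MET printed with three decimals.
Missing minutes within a day are treated as off-body (never as zero-MET, which
would manufacture phantom sedentary bouts).  Days are calendar days
(midnight-to-midnight); a day is a valid wear day when its on-body minutes
reach a configurable minimum (default 1140 = 19 h of a 24-h wear protocol),
and an assessment is valid when at least 4 of its days are valid.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .bouts import MINUTES_PER_DAY

__all__ = [
    "EpochFormatError",
    "WearDay",
    "DEFAULT_MIN_ON_BODY_MINUTES",
    "DEFAULT_MIN_VALID_DAYS",
    "read_epoch_frame",
    "write_epoch_frame",
    "read_epochs",
    "frame_to_weardays",
    "validate_assessment",
]

EPOCH_COLUMNS = [
    "participant_id",
    "date",
    "minute_of_day",
    "met",
    "steps",
    "on_body",
    "asleep",
]

#: near-complete-day on-body criterion for a valid wear day (19 of 24 h)
DEFAULT_MIN_ON_BODY_MINUTES = 1140
#: minimum valid days for a reliable assessment
DEFAULT_MIN_VALID_DAYS = 4


class EpochFormatError(ValueError):
    """Raised when an epoch file violates the dialect or its invariants."""


@dataclass
class WearDay:
    """One participant calendar day expanded to 1440 minute slots.

    Missing minutes are filled as off-body with MET 0 and 0 steps.
    """

    participant_id: str
    date: str
    met: np.ndarray
    steps: np.ndarray
    on_body: np.ndarray
    asleep: np.ndarray
    min_on_body_minutes: int = DEFAULT_MIN_ON_BODY_MINUTES

    @property
    def on_body_minutes(self) -> int:
        return int(self.on_body.sum())

    @property
    def waking_minutes(self) -> int:
        return int((self.on_body & ~self.asleep).sum())

    @property
    def valid(self) -> bool:
        return self.on_body_minutes >= self.min_on_body_minutes


def _fail(line: int | None, field: str, message: str) -> None:
    where = f"line {line}: " if line is not None else ""
    raise EpochFormatError(f"{where}field '{field}': {message}")


def read_epoch_frame(path) -> pd.DataFrame:
    """Read and validate one epoch CSV, returning the sorted canonical frame.

    Errors name the offending line (1-based, counting the header as line 1)
    and field.  Duplicate (participant, date, minute) rows are rejected.
    """
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise EpochFormatError(f"cannot parse {path}: {exc}") from exc
    if list(df.columns) != EPOCH_COLUMNS:
        raise EpochFormatError(
            f"header mismatch: expected {EPOCH_COLUMNS}, got {list(df.columns)}"
        )
    out = pd.DataFrame(index=df.index)
    out["participant_id"] = df["participant_id"]
    out["date"] = df["date"]
    for i, pid in enumerate(df["participant_id"]):
        if not pid:
            _fail(i + 2, "participant_id", "empty")

    def _num(col: str, kind: str, lo=None, hi=None):
        vals = []
        for i, raw in enumerate(df[col]):
            try:
                v = int(raw) if kind == "int" else float(raw)
            except ValueError:
                _fail(i + 2, col, f"not a valid {kind}: {raw!r}")
            if lo is not None and v < lo:
                _fail(i + 2, col, f"value {v} below minimum {lo}")
            if hi is not None and v > hi:
                _fail(i + 2, col, f"value {v} above maximum {hi}")
            vals.append(v)
        return vals

    out["minute_of_day"] = _num("minute_of_day", "int", 0, MINUTES_PER_DAY - 1)
    out["met"] = _num("met", "float", 0.0)
    out["steps"] = _num("steps", "int", 0)
    out["on_body"] = _num("on_body", "int", 0, 1)
    out["asleep"] = _num("asleep", "int", 0, 1)

    bad_sleep = (out["asleep"] == 1) & (out["on_body"] == 0)
    if bad_sleep.any():
        line = int(bad_sleep.idxmax()) + 2
        _fail(line, "asleep", "asleep=1 requires on_body=1 (off-body minutes carry no sleep classification)")

    key = ["participant_id", "date", "minute_of_day"]
    dup = out.duplicated(subset=key)
    if dup.any():
        line = int(dup.idxmax()) + 2
        _fail(line, "minute_of_day", "duplicate (participant, date, minute)")

    return out.sort_values(key, kind="mergesort").reset_index(drop=True)


def write_epoch_frame(df: pd.DataFrame, path) -> None:
    """Write an epoch frame in the canonical dialect (MET with 3 decimals)."""
    out = df.loc[:, EPOCH_COLUMNS].copy()
    out = out.sort_values(["participant_id", "date", "minute_of_day"], kind="mergesort")
    buf = io.StringIO()
    buf.write(",".join(EPOCH_COLUMNS) + "\n")
    for row in out.itertuples(index=False):
        buf.write(
            f"{row.participant_id},{row.date},{int(row.minute_of_day)},"
            f"{float(row.met):.3f},{int(row.steps)},{int(row.on_body)},{int(row.asleep)}\n"
        )
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def frame_to_weardays(
    df: pd.DataFrame,
    min_on_body_minutes: int = DEFAULT_MIN_ON_BODY_MINUTES,
) -> list[WearDay]:
    """Expand a validated epoch frame into per-(participant, date) WearDays."""
    days: list[WearDay] = []
    for (pid, date), grp in df.groupby(["participant_id", "date"], sort=True):
        met = np.zeros(MINUTES_PER_DAY)
        steps = np.zeros(MINUTES_PER_DAY, dtype=int)
        on_body = np.zeros(MINUTES_PER_DAY, dtype=bool)
        asleep = np.zeros(MINUTES_PER_DAY, dtype=bool)
        idx = grp["minute_of_day"].to_numpy(dtype=int)
        met[idx] = grp["met"].to_numpy(dtype=float)
        steps[idx] = grp["steps"].to_numpy(dtype=int)
        on_body[idx] = grp["on_body"].to_numpy(dtype=int).astype(bool)
        asleep[idx] = grp["asleep"].to_numpy(dtype=int).astype(bool)
        days.append(
            WearDay(str(pid), str(date), met, steps, on_body, asleep, min_on_body_minutes)
        )
    return days


def read_epochs(
    path,
    min_on_body_minutes: int = DEFAULT_MIN_ON_BODY_MINUTES,
) -> list[WearDay]:
    """Read one epoch CSV and return its wear days."""
    return frame_to_weardays(read_epoch_frame(path), min_on_body_minutes)


def validate_assessment(
    days: Sequence[WearDay],
    min_valid_days: int = DEFAULT_MIN_VALID_DAYS,
    min_on_body_minutes: int | None = None,
) -> dict:
    """Flag valid wear days and decide whether the assessment is usable.

    An empty day list yields an invalid assessment, not an exception.  The
    on-body bound is inclusive: a day exactly at the minimum is valid.
    """
    if min_on_body_minutes is not None:
        days = [
            WearDay(d.participant_id, d.date, d.met, d.steps, d.on_body, d.asleep,
                    min_on_body_minutes)
            for d in days
        ]
    valid_days = [d for d in days if d.valid]
    return {
        "valid_days": valid_days,
        "n_valid_days": len(valid_days),
        "assessment_valid": len(valid_days) >= min_valid_days,
    }
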