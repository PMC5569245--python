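"""Readers and writers for the package's plain-text data dialects.

Three CSV layouts are used throughout:

* epoch log — ``participant_id, date, epoch_start_hhmm, behavior`` with one
  row per 5-minute epoch (288 per participant-day); the diary side.
* device events — ``participant_id, start_datetime, duration_s, event,
  cadence_steps_per_min`` with ISO-8601 start times; the criterion side,
  modeled on inclinometer event exports.
* paired-day table — one row per participant-day x behavior with minutes
  from each method plus validity metadata (see preprocessing).
"""
from __future__ import annotations

import pandas as pd

from .config import EPOCH_LABELS, EVENT_CLASSES, LPA

EPOCH_COLUMNS = ["participant_id", "date", "epoch_start_hhmm", "behavior"]
EVENT_COLUMNS = ["participant_id", "start_datetime", "duration_s", "event",
                 "cadence_steps_per_min"]
PAIRED_COLUMNS = ["participant_id", "date", "period", "behavior", "app_minutes",
                  "device_minutes", "app_completion", "device_wear_hours", "valid"]

#: diary labels folded into the analysis vocabulary at parse time
LABEL_ALIASES = {"other": LPA, "other_activities": LPA}


class SchemaError(ValueError):
    """A CSV file does not match the expected dialect."""


def _require_columns(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing columns {missing}")


def read_epoch_log(path) -> pd.DataFrame:
    """Read an epoch-log CSV, folding label aliases and validating labels."""
    df = pd.read_csv(path, dtype={"participant_id": str, "behavior": str})
    _require_columns(df, EPOCH_COLUMNS, "epoch log")
    df["behavior"] = df["behavior"].str.lower().replace(LABEL_ALIASES)
    bad = ~df["behavior"].isin(EPOCH_LABELS)
    if bad.any():
        row = df.index[bad][0]
        raise SchemaError(
            f"epoch log row {row}: unknown behavior {df.loc[row, 'behavior']!r} "
            f"(column 'behavior')"
        )
    return df


def write_epoch_log(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=EPOCH_COLUMNS)


def read_device_events(path) -> pd.DataFrame:
    """Read a device event CSV and validate classes and durations."""
    df = pd.read_csv(path, dtype={"participant_id": str, "event": str})
    _require_columns(df, EVENT_COLUMNS, "device events")
    df["event"] = df["event"].str.lower()
    bad = ~df["event"].isin(EVENT_CLASSES)
    if bad.any():
        row = df.index[bad][0]
        raise SchemaError(
            f"device events row {row}: unknown event {df.loc[row, 'event']!r} "
            f"(column 'event')"
        )
    if (df["duration_s"] <= 0).any():
        row = df.index[df["duration_s"] <= 0][0]
        raise SchemaError(f"device events row {row}: nonpositive duration_s")
    df["start_datetime"] = pd.to_datetime(df["start_datetime"])
    return df


def write_device_events(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=EVENT_COLUMNS)


def read_paired_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str})
    _require_columns(df, PAIRED_COLUMNS, "paired-day table")
    return df


def write_paired_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=[c for c in PAIRED_COLUMNS if c in df.columns])


def write_ground_truth(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
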