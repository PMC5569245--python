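"""From raw epoch logs and event streams to a cleaned paired-day table.

Classification and exclusion rules implemented here:

* diary daily totals sum 5-minute epochs per behavior, excluding reported
  sleep; completion = annotated epochs / 288;
* device daily totals classify seated/lying outside the diary-reported sleep
  window as sedentary, standing or stepping at <= the cadence threshold
  (default 100 steps/min) as LPA, and faster stepping as MVPA;
* continuous seated runs strictly longer than the nonwear bout threshold
  (default 10 h) are nonwear and removed before totals; a run of exactly
  10 h is wear;
* a day is valid when diary completion exceeds 80% (strict) and — in the
  validity context — device wear reaches the wear-hour threshold;
* weekly averages use valid days only, and weeks with fewer than 3 valid
  days are dropped.
"""
from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

from .config import (
    EPOCH_LABELS,
    EPOCH_MINUTES,
    EPOCHS_PER_DAY,
    LPA,
    MINUTES_PER_DAY,
    MVPA,
    SEATED,
    SEDENTARY,
    SLEEP,
    STANDING,
    STEPPING,
    UNANNOTATED,
    WAKING_BEHAVIORS,
    ClassifierConfig,
    period_of_date,
)
from .io import LABEL_ALIASES, SchemaError

_CLASS_CODE = {SEATED: 0, STANDING: 1, STEPPING: 2}


class PreprocessingError(ValueError):
    """Raised for malformed inputs or empty results during preprocessing."""


# -- diary side ---------------------------------------------------------------

def app_daily_totals(labels) -> dict:
    """Daily behavior minutes and completion fraction from one day's epochs.

    ``labels`` is the day's 288 epoch labels.  Sleep epochs are excluded from
    the three waking behaviors; each counted epoch contributes 5 minutes.
    """
    labels = [str(l).lower() for l in labels]
    labels = [LABEL_ALIASES.get(l, l) for l in labels]
    if len(labels) != EPOCHS_PER_DAY:
        raise PreprocessingError(
            f"expected {EPOCHS_PER_DAY} epochs per day, got {len(labels)}"
        )
    bad = [l for l in labels if l not in EPOCH_LABELS]
    if bad:
        raise PreprocessingError(f"unknown epoch label {bad[0]!r}")
    arr = np.asarray(labels)
    out = {b: int((arr == b).sum()) * EPOCH_MINUTES for b in WAKING_BEHAVIORS}
    out["sleep_minutes"] = int((arr == SLEEP).sum()) * EPOCH_MINUTES
    out["completion"] = float((arr != UNANNOTATED).sum()) / EPOCHS_PER_DAY
    return out


def _sleep_mask(labels: np.ndarray) -> np.ndarray:
    """Per-minute sleep mask (1440 bool) from a day's epoch labels."""
    return np.repeat(np.asarray(labels) == SLEEP, EPOCH_MINUTES)


# -- device side --------------------------------------------------------------

def rasterize_events(day_events: pd.DataFrame, date: dt.date):
    """Per-minute (covered, class_code, cadence) arrays for one day's events.

    Events must be whole-minute aligned, chronologically ordered,
    non-overlapping and contained within the calendar day.
    """
    covered = np.zeros(MINUTES_PER_DAY, dtype=bool)
    cls = np.full(MINUTES_PER_DAY, -1, dtype=np.int8)
    cadence = np.full(MINUTES_PER_DAY, np.nan)
    midnight = dt.datetime.combine(date, dt.time())
    for row in day_events.itertuples(index=True):
        offset = (pd.Timestamp(row.start_datetime) - midnight).total_seconds()
        if offset % 60 or row.duration_s % 60:
            raise SchemaError(
                f"device events row {row.Index}: events must be whole-minute aligned"
            )
        s = int(offset // 60)
        e = s + int(row.duration_s // 60)
        if s < 0 or e > MINUTES_PER_DAY:
            raise SchemaError(
                f"device events row {row.Index}: event extends outside {date}"
            )
        if covered[s:e].any():
            raise PreprocessingError(
                f"device events row {row.Index}: overlapping events on {date}"
            )
        covered[s:e] = True
        cls[s:e] = _CLASS_CODE[row.event]
        if row.event == STEPPING:
            if not np.isfinite(row.cadence_steps_per_min):
                raise SchemaError(
                    f"device events row {row.Index}: stepping event without cadence"
                )
            cadence[s:e] = row.cadence_steps_per_min
    return covered, cls, cadence


def detect_nonwear(day_events: pd.DataFrame, date: dt.date,
                   config: ClassifierConfig,
                   sleep_mask: np.ndarray | None = None) -> list[tuple[int, int]]:
    """Maximal sedentary (waking seated) runs strictly longer than the
    nonwear threshold.

    Returns ``(start_minute, end_minute)`` half-open intervals.  Runs are
    broken by any non-seated event, a coverage gap, or — when a sleep window
    is supplied — the reported sleep period (the device records sleep as
    seated, but the nonwear rule concerns sedentary behavior, which is by
    definition waking time).  A run of exactly the threshold is wear.
    """
    covered, cls, _ = rasterize_events(day_events, date)
    return _nonwear_from_raster(covered, cls, config, sleep_mask)


def _nonwear_from_raster(covered, cls, config: ClassifierConfig, sleep_mask=None):
    seated = covered & (cls == _CLASS_CODE[SEATED])
    if sleep_mask is not None:
        seated &= ~np.asarray(sleep_mask, dtype=bool)
    limit = config.nonwear_bout_hours * 60.0
    intervals = []
    padded = np.concatenate(([False], seated, [False]))
    edges = np.nonzero(np.diff(padded.astype(np.int8)))[0]
    for s, e in zip(edges[::2], edges[1::2]):
        if e - s > limit:
            intervals.append((int(s), int(e)))
    return intervals


def device_daily_totals(day_events: pd.DataFrame, date: dt.date,
                        sleep_mask: np.ndarray, config: ClassifierConfig) -> dict:
    """Daily device minutes per behavior, wear hours and nonwear minutes.

    Nonwear bouts are removed before totals; wear hours count minutes that
    are covered, outside the sleep window and outside nonwear.
    """
    covered, cls, cadence = rasterize_events(day_events, date)
    nonwear = np.zeros(MINUTES_PER_DAY, dtype=bool)
    for s, e in _nonwear_from_raster(covered, cls, config, sleep_mask):
        nonwear[s:e] = True
    wear = covered & ~np.asarray(sleep_mask, dtype=bool) & ~nonwear
    stepping = cls == _CLASS_CODE[STEPPING]
    fast = stepping & (cadence > config.cadence_threshold)
    slow_step = stepping & ~fast
    return {
        SEDENTARY: int((wear & (cls == _CLASS_CODE[SEATED])).sum()),
        LPA: int((wear & ((cls == _CLASS_CODE[STANDING]) | slow_step)).sum()),
        MVPA: int((wear & fast).sum()),
        "wear_hours": float(wear.sum()) / 60.0,
        "nonwear_minutes": int(nonwear.sum()),
    }


# -- paired table -------------------------------------------------------------

def build_paired_day_table(epoch_log: pd.DataFrame, device_events: pd.DataFrame,
                           config: ClassifierConfig,
                           study_start: dt.date) -> pd.DataFrame:
    """Join diary and device daily totals into the paired-day table.

    One row per participant-day x waking behavior; only days present in both
    sources are paired.  Validity flags are not set here (see
    :func:`flag_valid_days`).
    """
    if epoch_log.empty:
        raise PreprocessingError("epoch log is empty")
    events = device_events.copy()
    events["start_datetime"] = pd.to_datetime(events["start_datetime"])
    events["_date"] = events["start_datetime"].dt.date
    events_by_day = {k: g.sort_values("start_datetime")
                     for k, g in events.groupby(["participant_id", "_date"])}

    rows = []
    for (pid, date_str), day_log in epoch_log.groupby(["participant_id", "date"]):
        date = dt.date.fromisoformat(str(date_str))
        day_log = day_log.sort_values("epoch_start_hhmm")
        labels = day_log["behavior"].str.lower().replace(LABEL_ALIASES).to_numpy()
        app = app_daily_totals(labels)
        key = (pid, date)
        if key not in events_by_day:
            continue
        dev = device_daily_totals(events_by_day[key], date, _sleep_mask(labels), config)
        period = period_of_date(date, study_start)
        for b in WAKING_BEHAVIORS:
            rows.append((pid, date.isoformat(), period, b, float(app[b]),
                         float(dev[b]), app["completion"], dev["wear_hours"]))
    if not rows:
        raise PreprocessingError("no participant-days present in both sources")
    return pd.DataFrame(rows, columns=[
        "participant_id", "date", "period", "behavior", "app_minutes",
        "device_minutes", "app_completion", "device_wear_hours",
    ])


def flag_valid_days(table: pd.DataFrame, config: ClassifierConfig,
                    context: str = "validity") -> pd.DataFrame:
    """Attach the ``valid`` flag.

    ``validity`` context requires diary completion strictly above the
    completion threshold and device wear at or above the wear-hour
    threshold; ``reliability`` context is a diary-only analysis and applies
    the completion rule alone.
    """
    if context not in ("validity", "reliability"):
        raise PreprocessingError(f"unknown context {context!r}")
    out = table.copy()
    valid = out["app_completion"] > config.app_min_completion
    if context == "validity":
        valid &= out["device_wear_hours"] >= config.wear_min_hours
    out["valid"] = valid
    return out


def weekly_average(table: pd.DataFrame, config: ClassifierConfig) -> pd.DataFrame:
    """Per participant-week mean minutes per behavior per method.

    Uses valid days only; weeks with fewer than
    ``config.min_valid_days_per_week`` valid days are dropped entirely.
    """
    if table.empty:
        raise PreprocessingError("paired-day table is empty")
    if "valid" not in table.columns:
        raise PreprocessingError("valid flags not set; call flag_valid_days first")
    valid = table[table["valid"]]
    if valid.empty:
        raise PreprocessingError("no valid days after exclusion rules")
    out = (
        valid.groupby(["participant_id", "period", "behavior"], as_index=False)
        .agg(app_minutes=("app_minutes", "mean"),
             device_minutes=("device_minutes", "mean"),
             n_valid_days=("date", "nunique"))
    )
    return out[out["n_valid_days"] >= config.min_valid_days_per_week].reset_index(drop=True)


# -- hour-of-day stratification ----------------------------------------------

def build_hourly_table(epoch_log: pd.DataFrame, device_events: pd.DataFrame,
                       config: ClassifierConfig) -> pd.DataFrame:
    """Per-hour minutes in each behavior from both methods, sleep excluded.

    One row per participant-day x hour x behavior, for exploring whether
    reporting accuracy varies across the day.
    """
    events = device_events.copy()
    events["start_datetime"] = pd.to_datetime(events["start_datetime"])
    events["_date"] = events["start_datetime"].dt.date
    events_by_day = {k: g for k, g in events.groupby(["participant_id", "_date"])}

    rows = []
    for (pid, date_str), day_log in epoch_log.groupby(["participant_id", "date"]):
        date = dt.date.fromisoformat(str(date_str))
        key = (pid, date)
        if key not in events_by_day:
            continue
        day_log = day_log.sort_values("epoch_start_hhmm")
        labels = day_log["behavior"].str.lower().replace(LABEL_ALIASES).to_numpy()
        sleep = _sleep_mask(labels)
        covered, cls, cadence = rasterize_events(events_by_day[key], date)
        nonwear = np.zeros(MINUTES_PER_DAY, dtype=bool)
        for s, e in _nonwear_from_raster(covered, cls, config, sleep):
            nonwear[s:e] = True
        wear = covered & ~sleep & ~nonwear
        stepping = cls == _CLASS_CODE[STEPPING]
        fast = stepping & (cadence > config.cadence_threshold)
        dev_min = {
            SEDENTARY: wear & (cls == _CLASS_CODE[SEATED]),
            LPA: wear & ((cls == _CLASS_CODE[STANDING]) | (stepping & ~fast)),
            MVPA: wear & fast,
        }
        app_min = {b: np.repeat(np.asarray(labels) == b, EPOCH_MINUTES)
                   for b in WAKING_BEHAVIORS}
        for hour in range(24):
            sl = slice(hour * 60, (hour + 1) * 60)
            for b in WAKING_BEHAVIORS:
                rows.append((pid, date.isoformat(), hour, b,
                             float(app_min[b][sl].sum()),
                             float(dev_min[b][sl].sum())))
    return pd.DataFrame(rows, columns=[
        "participant_id", "date", "hour", "behavior", "app_minutes", "device_minutes",
    ])
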