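"""Responsiveness to change: stability, RS and mean percentage error.

Participants are classified as *stable* per behavior when their
criterion-measured change between the two periods is strictly below the
behavior's threshold in magnitude (defaults 30/30/10 min/day for
sedentary/LPA/MVPA).  The responsiveness statistic is

    RS = |mean change| / SD(change among stable participants)

and indexes the minimal clinically important difference against the noise
of stable scores.  *Substantial change* uses the complementary inclusive
directional rule: sedentary decreased by >= 30, LPA increased by >= 30, or
MVPA increased by >= 10 min/day on the criterion.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import LPA, MVPA, SEDENTARY, WAKING_BEHAVIORS

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = {SEDENTARY: 30.0, LPA: 30.0, MVPA: 10.0}
#: direction of substantial change per behavior: -1 decrease, +1 increase
SUBSTANTIAL_DIRECTION = {SEDENTARY: -1, LPA: +1, MVPA: +1}


class ResponsivenessError(ValueError):
    """Raised when a responsiveness statistic is undefined for the input."""


def change_scores(weekly: pd.DataFrame, t1: str, t2: str) -> pd.DataFrame:
    """Per-participant change (period-2 mean − period-1 mean) for both methods.

    ``weekly`` is a weekly-average table with columns participant_id,
    period, behavior, app_minutes, device_minutes.  Only participants with
    valid weekly averages in both periods contribute.
    """
    w1 = weekly[weekly["period"] == t1]
    w2 = weekly[weekly["period"] == t2]
    if w1.empty or w2.empty:
        raise ResponsivenessError(f"no weekly averages for period {t1 if w1.empty else t2!r}")
    merged = w1.merge(w2, on=["participant_id", "behavior"], suffixes=("_t1", "_t2"))
    if merged.empty:
        raise ResponsivenessError("no participants with both periods")
    merged["app_change"] = merged["app_minutes_t2"] - merged["app_minutes_t1"]
    merged["device_change"] = merged["device_minutes_t2"] - merged["device_minutes_t1"]
    return merged[["participant_id", "behavior", "app_change", "device_change"]]


def classify_stable(changes: pd.DataFrame,
                    thresholds: dict[str, float] | None = None) -> pd.Series:
    """Stable iff |criterion change| is strictly below the behavior threshold."""
    thresholds = thresholds or DEFAULT_THRESHOLDS
    unknown = set(changes["behavior"]) - set(thresholds)
    if unknown:
        raise ResponsivenessError(f"no stability threshold for behaviors {sorted(unknown)}")
    limits = changes["behavior"].map(thresholds)
    return changes["device_change"].abs() < limits


def responsiveness_statistic(mean_change: float, sd_stable: float) -> float:
    """RS = |mean change| / SD of stable participants, rounded to 2 decimals."""
    if not np.isfinite(sd_stable) or sd_stable <= 0:
        raise ResponsivenessError("SD of stable participants must be positive")
    return round(abs(mean_change) / sd_stable, 2)


def mean_percentage_error(app_changes, device_changes,
                          mode: str = "aggregate") -> float:
    """Relative over/underestimation of change by the diary, in percent.

    ``aggregate`` (default): 100 * (mean app Δ − mean device Δ) / |mean
    device Δ|.  ``per_participant``: mean over participants of the
    per-participant percentage errors, excluding (with a logged count)
    participants whose criterion change is zero.
    """
    app = np.asarray(app_changes, dtype=float)
    dev = np.asarray(device_changes, dtype=float)
    if app.shape != dev.shape:
        raise ResponsivenessError(f"length mismatch: {app.shape} vs {dev.shape}")
    if app.size == 0:
        raise ResponsivenessError("empty change scores")
    if mode == "aggregate":
        denom = dev.mean()
        if denom == 0:
            raise ResponsivenessError("mean criterion change is zero: MPE undefined")
        return float(100.0 * (app.mean() - denom) / abs(denom))
    if mode == "per_participant":
        nonzero = dev != 0
        if (~nonzero).any():
            logger.info("mpe: excluded %d participants with zero criterion change",
                        int((~nonzero).sum()))
        if not nonzero.any():
            raise ResponsivenessError("all criterion changes are zero: MPE undefined")
        return float(np.mean(100.0 * (app[nonzero] - dev[nonzero]) / np.abs(dev[nonzero])))
    raise ResponsivenessError(f"unknown MPE mode {mode!r}")


def pct_substantial_change(changes: pd.DataFrame, behavior: str,
                           thresholds: dict[str, float] | None = None
                           ) -> tuple[float, int, int]:
    """Percent (and count/n) of participants with substantial criterion change.

    The rule is directional and inclusive: sedentary Δ <= −threshold, LPA
    Δ >= +threshold, MVPA Δ >= +threshold.
    """
    thresholds = thresholds or DEFAULT_THRESHOLDS
    if behavior not in thresholds or behavior not in SUBSTANTIAL_DIRECTION:
        raise ResponsivenessError(f"unknown behavior {behavior!r}")
    sub = changes[changes["behavior"] == behavior]
    n = len(sub)
    if n == 0:
        raise ResponsivenessError(f"no change scores for behavior {behavior!r}")
    signed = SUBSTANTIAL_DIRECTION[behavior] * sub["device_change"]
    count = int((signed >= thresholds[behavior]).sum())
    return 100.0 * count / n, count, n
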