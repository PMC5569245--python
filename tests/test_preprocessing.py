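"""Classification, exclusion and aggregation rules on constructed fixtures."""
import datetime as dt

import numpy as np
import pandas as pd
import pytest

import actvalid as av
from actvalid.preprocessing import PreprocessingError, _sleep_mask

DATE = dt.date(2017, 1, 16)


def epochs(**counts):
    """Build a 288-epoch label list, e.g. epochs(sleep=96, sedentary=192)."""
    out = []
    for label, n in counts.items():
        out += [label] * n
    assert len(out) == 288
    return out


def events_df(*spec, pid="P001"):
    """Build a day's event frame from (start_minute, minutes, class, cadence)."""
    midnight = dt.datetime.combine(DATE, dt.time())
    return pd.DataFrame({
        "participant_id": pid,
        "start_datetime": [midnight + dt.timedelta(minutes=s) for s, *_ in spec],
        "duration_s": [m * 60 for _, m, *_ in spec],
        "event": [c for _, _, c, _ in spec],
        "cadence_steps_per_min": [cad for *_, cad in spec],
    })


# -- diary totals -------------------------------------------------------------

def test_app_daily_totals_all_sedentary():
    t = av.app_daily_totals(epochs(sedentary=288))
    assert t["sedentary"] == 1440 and t["completion"] == 1.0


def test_app_daily_totals_hand_count():
    t = av.app_daily_totals(epochs(sleep=96, sedentary=150, lpa=30, mvpa=12))
    assert (t["sedentary"], t["lpa"], t["mvpa"]) == (750, 150, 60)
    assert t["sleep_minutes"] == 480 and t["completion"] == 1.0


def test_app_daily_totals_completion_below_threshold(classifier):
    t = av.app_daily_totals(epochs(sedentary=230, unannotated=58))
    assert t["completion"] == pytest.approx(230 / 288)
    assert t["completion"] <= classifier.app_min_completion  # -> invalid day


def test_other_label_maps_to_lpa():
    t = av.app_daily_totals(["other"] * 288)
    assert t["lpa"] == 1440


def test_app_daily_totals_rejects_bad_input():
    with pytest.raises(PreprocessingError):
        av.app_daily_totals(epochs(sedentary=287, unannotated=1)[:-1] + ["napping"])
    with pytest.raises(PreprocessingError):
        av.app_daily_totals(["sedentary"] * 100)


# -- device totals ------------------------------------------------------------

def test_cadence_threshold_splits_lpa_mvpa(classifier):
    ev = events_df((0, 1350, "seated", np.nan),
                   (1350, 30, "stepping", 110.0),
                   (1380, 60, "standing", np.nan))
    no_sleep = np.zeros(1440, bool)
    t = av.device_daily_totals(ev, DATE, no_sleep, classifier)
    assert t["mvpa"] == 30 and t["lpa"] == 60
    # cadence exactly at the threshold is LPA (strict > rule for MVPA)
    ev2 = events_df((0, 1410, "seated", np.nan), (1410, 30, "stepping", 100.0))
    t2 = av.device_daily_totals(ev2, DATE, no_sleep, classifier)
    assert t2["mvpa"] == 0 and t2["lpa"] == 30


def test_seated_inside_sleep_window_not_sedentary(classifier):
    ev = events_df((0, 1000, "seated", np.nan), (1000, 440, "standing", np.nan))
    sleep = _sleep_mask(np.array(epochs(sleep=96, sedentary=192)))
    t = av.device_daily_totals(ev, DATE, sleep, classifier)
    assert t["sedentary"] == 1000 - 480  # waking seated only
    ev2 = events_df((0, 480, "seated", np.nan), (480, 960, "standing", np.nan))
    t2 = av.device_daily_totals(ev2, DATE, sleep, classifier)
    assert t2["sedentary"] == 0


def test_overlapping_events_rejected(classifier):
    ev = events_df((0, 100, "seated", np.nan), (50, 100, "standing", np.nan))
    with pytest.raises(PreprocessingError, match="overlap"):
        av.device_daily_totals(ev, DATE, np.zeros(1440, bool), classifier)


# -- nonwear ------------------------------------------------------------------

def test_nonwear_strictly_greater_than_10h(classifier):
    eleven = events_df((0, 660, "seated", np.nan), (660, 780, "standing", np.nan))
    assert av.detect_nonwear(eleven, DATE, classifier) == [(0, 660)]
    ten = events_df((0, 600, "seated", np.nan), (600, 840, "standing", np.nan))
    assert av.detect_nonwear(ten, DATE, classifier) == []


def test_nonwear_requires_continuity(classifier):
    split = events_df((0, 360, "seated", np.nan), (360, 30, "standing", np.nan),
                      (390, 360, "seated", np.nan), (750, 690, "standing", np.nan))
    assert av.detect_nonwear(split, DATE, classifier) == []


def test_sleep_window_breaks_nonwear_runs(classifier):
    ev = events_df((0, 1440, "seated", np.nan))
    sleep = np.zeros(1440, bool)
    sleep[400:900] = True  # 8.3 h sleep splits the day into <10 h seated runs
    assert av.detect_nonwear(ev, DATE, classifier, sleep_mask=sleep) == []
    assert av.detect_nonwear(ev, DATE, classifier) == [(0, 1440)]


def test_nonwear_removed_before_totals(classifier):
    ev = events_df((0, 661, "seated", np.nan), (661, 779, "standing", np.nan))
    t = av.device_daily_totals(ev, DATE, np.zeros(1440, bool), classifier)
    assert t["sedentary"] == 0 and t["nonwear_minutes"] == 661
    assert t["wear_hours"] == pytest.approx(779 / 60)


# -- valid days and weekly averages -------------------------------------------

def _day_row(pid, date, completion, wear, period="week3"):
    return [(pid, date, period, b, 100.0, 100.0, completion, wear)
            for b in ("sedentary", "lpa", "mvpa")]


def paired_table(rows):
    return pd.DataFrame(rows, columns=[
        "participant_id", "date", "period", "behavior", "app_minutes",
        "device_minutes", "app_completion", "device_wear_hours"])


def test_flag_valid_days_thresholds(classifier):
    table = paired_table(
        _day_row("P1", "2017-01-16", 0.90, 12.0)
        + _day_row("P1", "2017-01-17", 0.75, 12.0)
        + _day_row("P1", "2017-01-18", 0.90, 9.0)
        + _day_row("P1", "2017-01-19", 0.80, 12.0)  # boundary: strictly > 0.80
    )
    out = av.flag_valid_days(table, classifier, context="validity")
    by_date = out.drop_duplicates("date").set_index("date")["valid"]
    assert by_date.to_dict() == {"2017-01-16": True, "2017-01-17": False,
                                 "2017-01-18": False, "2017-01-19": False}
    # reliability context is diary-only: low wear does not invalidate
    rel = av.flag_valid_days(table, classifier, context="reliability")
    assert rel.drop_duplicates("date").set_index("date")["valid"]["2017-01-18"]


def test_exclusion_monotone_in_thresholds(noisy_cohort):
    _, _, paired = noisy_cohort
    base = av.flag_valid_days(paired, av.ClassifierConfig(), "validity")["valid"].sum()
    for wear, comp in [(8.0, 0.80), (10.0, 0.85), (12.0, 0.80), (12.0, 0.95)]:
        cfg = av.ClassifierConfig(wear_min_hours=wear, app_min_completion=comp)
        n = av.flag_valid_days(paired, cfg, "validity")["valid"].sum()
        if wear >= 10.0 and comp >= 0.80:
            assert n <= base
        if wear <= 10.0 and comp <= 0.80:
            assert n >= base


def test_weekly_average_rules(classifier):
    rows = []
    for d, m in zip(range(16, 19), (500.0, 600.0, 700.0)):
        rows += [("P1", f"2017-01-{d}", "week3", b, m, m, 0.9, 12.0)
                 for b in ("sedentary", "lpa", "mvpa")]
    rows += _day_row("P2", "2017-01-16", 0.9, 12.0)
    rows += _day_row("P2", "2017-01-17", 0.9, 12.0)  # only 2 valid days
    table = av.flag_valid_days(paired_table(rows), classifier, "validity")
    weekly = av.weekly_average(table, classifier)
    assert set(weekly["participant_id"]) == {"P1"}
    sed = weekly[weekly["behavior"] == "sedentary"].iloc[0]
    assert sed["app_minutes"] == pytest.approx(600.0)
    assert sed["n_valid_days"] == 3


def test_weekly_average_identical_days(classifier):
    rows = []
    for d in range(16, 23):
        rows += [("P1", f"2017-01-{d}", "week3", b, 600.0, 600.0, 1.0, 14.0)
                 for b in ("sedentary", "lpa", "mvpa")]
    table = av.flag_valid_days(paired_table(rows), classifier, "validity")
    weekly = av.weekly_average(table, classifier)
    assert (weekly["app_minutes"] == 600.0).all()


def test_weekly_average_empty_inputs(classifier):
    with pytest.raises(PreprocessingError):
        av.weekly_average(paired_table([]), classifier)
    table = av.flag_valid_days(paired_table(_day_row("P1", "2017-01-16", 0.5, 12.0)),
                               classifier, "validity")
    with pytest.raises(PreprocessingError, match="no valid days"):
        av.weekly_average(table, classifier)


# -- conservation on synthetic data -------------------------------------------

def test_app_minutes_conservation(noisy_cohort):
    _, sim, _ = noisy_cohort
    log = sim.epoch_log
    for (_, _), day in log.groupby(["participant_id", "date"]):
        counts = day["behavior"].value_counts()
        assert counts.sum() == 288  # 5-min epochs partition the 24 h


def test_device_totals_plus_sleep_plus_nonwear_cover_day(noise_free_cohort, classifier):
    cfg, sim, paired = noise_free_cohort
    tr = sim.ground_truth.true_day_minutes
    day = paired.drop_duplicates(["participant_id", "date"]).iloc[0]
    sub = paired[(paired["participant_id"] == day["participant_id"])
                 & (paired["date"] == day["date"])]
    sleep_min = tr[(tr["participant_id"] == day["participant_id"])
                   & (tr["date"] == day["date"])
                   & (tr["behavior"] == "sleep")]["true_minutes"].iloc[0]
    total = sub["device_minutes"].sum() + sleep_min
    assert total == 1440  # no nonwear in the noise-free cohort


def test_noise_free_methods_agree_exactly(noise_free_cohort):
    _, sim, paired = noise_free_cohort
    assert (paired["app_minutes"] == paired["device_minutes"]).all()
    merged = paired.merge(sim.ground_truth.true_day_minutes,
                          on=["participant_id", "date", "behavior"])
    assert (merged["app_minutes"] == merged["true_minutes"]).all()


def test_hourly_table_sums_to_daily_totals(noise_free_cohort, classifier):
    cfg, sim, paired = noise_free_cohort
    hourly = av.build_hourly_table(sim.epoch_log, sim.device_events, classifier)
    daily = (hourly.groupby(["participant_id", "date", "behavior"], as_index=False)
             [["app_minutes", "device_minutes"]].sum())
    merged = daily.merge(paired, on=["participant_id", "date", "behavior"],
                         suffixes=("_h", ""))
    assert np.allclose(merged["app_minutes_h"], merged["app_minutes"])
    assert np.allclose(merged["device_minutes_h"], merged["device_minutes"])
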