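"""Synthetic paired diary/posture-sensor cohorts with known ground truth.

The generator emulates the measurement structure this package analyses:
each participant-day is a latent per-minute behavior sequence (one
contiguous sleep block, then alternating sedentary/LPA/MVPA bouts from a
first-order bout chain), observed twice —

* by a 5-minute-epoch self-report diary, which passes each epoch's label
  through a misclassification matrix, adds method-level and day-level
  reporting shifts, and leaves a fraction of epochs unannotated; and
* by a posture-sensor event stream (seated / standing / stepping with
  cadence), which records the truth exactly apart from optionally injected
  nonwear blocks (>10 h seated runs).

Variance-component semantics: between-participant effects (``sigma_participant``)
live in the latent truth; the method bias (``sigma_method``) and day-level
residual (``sigma_residual``) are reporting errors carried by the diary for
LPA and MVPA, with sedentary taking the balancing epochs.  The population
single-measures absolute-agreement ICC implied by the components,
``sigma_p^2 / (sigma_p^2 + sigma_m^2 + sigma_e^2)``, is exact for the
directly emitted participant x method table and approximate for the
event-level pipeline (see docs/methods.md).
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (
    CODE_LABELS,
    EPOCH_MINUTES,
    EPOCHS_PER_DAY,
    LABEL_CODES,
    LPA,
    MINUTES_PER_DAY,
    MVPA,
    SEATED,
    SEDENTARY,
    SLEEP,
    STANDING,
    STEPPING,
    TRUE_LABELS,
    UNANNOTATED,
    UNANNOTATED_CODE,
    WAKING_BEHAVIORS,
    SimulationConfig,
    week_number,
)

#: mean bout lengths, in 5-minute epochs, of the latent bout chain
MEAN_BOUT_EPOCHS = {SEDENTARY: 6, LPA: 3, MVPA: 2}
#: minimum sleep left after clamping waking targets, minutes
MIN_SLEEP_MINUTES = 60
#: injected nonwear block: target length and margin after wake, minutes
NONWEAR_BLOCK_MINUTES = 660
_LPA_CADENCE = (55.0, 95.0)
_MVPA_CADENCE = (105.0, 135.0)


@dataclass
class GroundTruth:
    """Latent per-day behavior minutes and the ICC implied by the components."""

    true_day_minutes: pd.DataFrame  # participant_id, date, period, behavior, true_minutes
    true_icc: dict[str, float]


@dataclass
class SimulationOutput:
    epoch_log: pd.DataFrame
    device_events: pd.DataFrame
    ground_truth: GroundTruth
    twoway_table: pd.DataFrame = field(repr=False, default=None)


# -- latent day ---------------------------------------------------------------

def _epoch_budgets(minutes: dict[str, float]) -> dict[str, int]:
    """Quantize per-behavior minutes to whole 5-min epochs (largest remainder)."""
    raw = {b: minutes[b] / EPOCH_MINUTES for b in TRUE_LABELS}
    floors = {b: int(np.floor(raw[b])) for b in TRUE_LABELS}
    short = EPOCHS_PER_DAY - sum(floors.values())
    order = sorted(TRUE_LABELS, key=lambda b: raw[b] - floors[b], reverse=True)
    for b in order[:short]:
        floors[b] += 1
    return floors


def _day_targets(
    config: SimulationConfig,
    participant_effects: np.ndarray,
    period: str,
    rng: np.random.Generator,
) -> dict[str, float]:
    """Latent true minutes for one day; sleep is the complementary filler."""
    targets: dict[str, float] = {}
    apply_effect = week_number(period) >= config.intervention_from_week
    for j, b in enumerate(WAKING_BEHAVIORS):
        t = config.mean_minutes[b] + participant_effects[j]
        if config.sigma_true_day > 0:
            t += rng.normal(0.0, config.sigma_true_day * config.behavior_scale(b))
        if apply_effect:
            t += config.intervention_effect.get(b, 0.0)
        targets[b] = max(t, 0.0)
    waking = sum(targets.values())
    max_waking = MINUTES_PER_DAY - MIN_SLEEP_MINUTES
    if waking > max_waking:
        scale = max_waking / waking
        targets = {b: t * scale for b, t in targets.items()}
        waking = max_waking
    targets[SLEEP] = MINUTES_PER_DAY - waking
    return targets


def _layout_day(budgets: dict[str, int], rng: np.random.Generator) -> np.ndarray:
    """Place the sleep block then alternate waking bouts; returns 288 codes."""
    seq = np.empty(EPOCHS_PER_DAY, dtype=np.int8)
    pos = budgets[SLEEP]
    seq[:pos] = LABEL_CODES[SLEEP]
    rem = {b: budgets[b] for b in WAKING_BEHAVIORS if budgets[b] > 0}
    prev = None
    while pos < EPOCHS_PER_DAY:
        choices = [b for b in rem if b != prev] or list(rem)
        weights = np.array([rem[b] for b in choices], dtype=float)
        b = choices[int(rng.choice(len(choices), p=weights / weights.sum()))]
        bout = min(rem[b], int(rng.geometric(1.0 / MEAN_BOUT_EPOCHS[b])))
        seq[pos:pos + bout] = LABEL_CODES[b]
        pos += bout
        rem[b] -= bout
        if rem[b] == 0:
            del rem[b]
        prev = b
    return seq


def generate_day_sequence(
    config: SimulationConfig, participant: int, day: int
) -> np.ndarray:
    """Latent per-minute behavior codes (length 1440) for one participant-day.

    Deterministic in ``(config.seed, participant, day)``.  Expected daily
    totals equal ``mean_minutes`` plus the participant's random effects,
    quantized to the 5-minute reporting grid.
    """
    effects = _participant_effects(config, participant)
    rng = np.random.default_rng([config.seed, 7919, participant, day])
    targets = _day_targets(config, effects, config.periods[0], rng)
    epochs = _layout_day(_epoch_budgets(targets), rng)
    return np.repeat(epochs, EPOCH_MINUTES)


def _participant_effects(config: SimulationConfig, participant: int) -> np.ndarray:
    rng = np.random.default_rng([config.seed, 104729, participant])
    scales = np.array([config.behavior_scale(b) for b in WAKING_BEHAVIORS])
    return rng.normal(0.0, config.sigma_participant * scales)


# -- diary observation --------------------------------------------------------

def _epoch_majority(sequence: np.ndarray) -> np.ndarray:
    """Majority label per 5-minute window; ties go to the earlier minute."""
    if sequence.shape[0] != MINUTES_PER_DAY:
        raise ValueError("sequence must contain 1440 per-minute labels")
    windows = sequence.reshape(EPOCHS_PER_DAY, EPOCH_MINUTES)
    counts = (windows[:, :, None] == np.arange(len(TRUE_LABELS))).sum(axis=1)
    winners = counts.argmax(axis=1).astype(np.int8)
    maxima = counts.max(axis=1)
    tied = (counts == maxima[:, None]).sum(axis=1) > 1
    for i in np.nonzero(tied)[0]:
        cands = set(np.nonzero(counts[i] == maxima[i])[0])
        for lab in windows[i]:
            if lab in cands:
                winners[i] = lab
                break
    return winners


def _apply_shifts(
    epochs: np.ndarray, shifts: dict[str, float], rng: np.random.Generator
) -> np.ndarray:
    """Relabel epochs between sedentary and LPA/MVPA to realize reporting shifts.

    A positive shift for behavior ``b`` converts sedentary epochs to ``b``
    (over-reported activity comes out of sitting); negative converts ``b``
    epochs to sedentary.
    """
    out = epochs.copy()
    sed = LABEL_CODES[SEDENTARY]
    for b in (LPA, MVPA):
        delta = int(np.round(shifts.get(b, 0.0) / EPOCH_MINUTES))
        if delta == 0:
            continue
        src, dst = (sed, LABEL_CODES[b]) if delta > 0 else (LABEL_CODES[b], sed)
        pool = np.nonzero(out == src)[0]
        take = min(abs(delta), pool.size)
        if take:
            out[rng.choice(pool, size=take, replace=False)] = dst
    return out


def _apply_misclassification(
    epochs: np.ndarray, matrix: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    if np.array_equal(matrix, np.eye(len(TRUE_LABELS))):
        return epochs
    cum = np.cumsum(matrix, axis=1)
    u = rng.random(epochs.shape[0])
    new = (u[:, None] > cum[epochs]).sum(axis=1).astype(np.int8)
    return np.minimum(new, len(TRUE_LABELS) - 1)


def observe_app(
    sequence: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    shifts: dict[str, float] | None = None,
    completeness: float | None = None,
) -> np.ndarray:
    """Diary observation of a latent day: 288 epoch codes (incl. unannotated).

    With the identity misclassification matrix, full completeness and no
    shifts, epoch totals equal the true totals rounded to the 5-min grid.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    epochs = _epoch_majority(np.asarray(sequence))
    if shifts:
        epochs = _apply_shifts(epochs, shifts, rng)
    epochs = _apply_misclassification(
        epochs, np.asarray(config.misclassification, dtype=float), rng
    )
    c = config.annotation_completeness if completeness is None else completeness
    if c < 1.0:
        mask = rng.random(EPOCHS_PER_DAY) >= c
        epochs = epochs.copy()
        epochs[mask] = UNANNOTATED_CODE
    return epochs


def _day_completeness(config: SimulationConfig, rng: np.random.Generator) -> float:
    """Per-day completeness, Beta-distributed around the configured mean."""
    c, k = config.annotation_completeness, config.completeness_concentration
    if c in (0.0, 1.0) or k == 0:
        return c
    return float(rng.beta(c * k, (1.0 - c) * k))


# -- device observation -------------------------------------------------------

def observe_device(
    sequence: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    inject_nonwear: bool = False,
) -> list[tuple[int, int, str, float]]:
    """Posture-sensor events for one latent day.

    Returns ``(start_minute, duration_minutes, event_class, cadence)`` tuples
    covering all 1440 minutes.  Sleep and sedentary minutes appear as seated
    events (adjacent runs merged); LPA as standing or slow stepping
    (cadence <= 100); MVPA as fast stepping (cadence > 100).  When
    ``inject_nonwear`` is set, a >10 h seated block is overlaid at the end of
    the day to mimic the device being taken off.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    minutes = np.asarray(sequence).copy()
    if minutes.shape[0] != MINUTES_PER_DAY:
        raise ValueError("sequence must contain 1440 per-minute labels")
    if inject_nonwear:
        sleep_len = int(np.argmax(minutes != LABEL_CODES[SLEEP])) \
            if (minutes != LABEL_CODES[SLEEP]).any() else MINUTES_PER_DAY
        block = min(NONWEAR_BLOCK_MINUTES, MINUTES_PER_DAY - sleep_len - 30)
        if block > 600:
            minutes[MINUTES_PER_DAY - block:] = LABEL_CODES[SEDENTARY]
    # run-length encode
    changes = np.nonzero(np.diff(minutes))[0] + 1
    starts = np.concatenate(([0], changes))
    ends = np.concatenate((changes, [MINUTES_PER_DAY]))
    events: list[tuple[int, int, str, float]] = []
    for s, e in zip(starts, ends):
        code = int(minutes[s])
        dur = int(e - s)
        label = CODE_LABELS[code]
        if label in (SLEEP, SEDENTARY):
            if events and events[-1][2] == SEATED and events[-1][0] + events[-1][1] == s:
                prev = events.pop()
                events.append((prev[0], prev[1] + dur, SEATED, np.nan))
            else:
                events.append((s, dur, SEATED, np.nan))
        elif label == LPA:
            if rng.random() < 0.5:
                events.append((s, dur, STANDING, np.nan))
            else:
                events.append((s, dur, STEPPING, float(rng.uniform(*_LPA_CADENCE))))
        else:  # MVPA
            events.append((s, dur, STEPPING, float(rng.uniform(*_MVPA_CADENCE))))
    return events


# -- cohort -------------------------------------------------------------------

def simulate_paired_cohort(config: SimulationConfig) -> SimulationOutput:
    """Complete paired dataset plus ground truth and a two-way ICC table.

    The epoch log and event stream cover ``n_participants x len(periods) x
    n_days`` days.  The two-way table draws, per behavior, one cell per
    participant x method from ``mu + u_i + v_m + e_im`` with both method
    effects i.i.d. — a textbook two-way random-effects layout whose
    population ICC equals ``GroundTruth.true_icc`` exactly.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    scales = {b: config.behavior_scale(b) for b in WAKING_BEHAVIORS}

    u = np.column_stack([
        rng.normal(0.0, config.sigma_participant * scales[b], size=n)
        for b in WAKING_BEHAVIORS
    ])
    # diary method bias, constant across the cohort realization (LPA/MVPA carry
    # it; sedentary takes the balancing epochs)
    v_app = {b: rng.normal(0.0, config.sigma_method * scales[b]) for b in (LPA, MVPA)}

    # two-way random-effects table for ICC oracle testing
    tw_rows = []
    for b in WAKING_BEHAVIORS:
        v_m = rng.normal(0.0, config.sigma_method * scales[b], size=2)
        e = rng.normal(0.0, config.sigma_residual * scales[b], size=(n, 2))
        for i in range(n):
            for m, meth in enumerate(("app", "device")):
                tw_rows.append((
                    f"P{i + 1:03d}", meth, b,
                    config.mean_minutes[b] + u[i, WAKING_BEHAVIORS.index(b)]
                    + v_m[m] + e[i, m],
                ))
    twoway = pd.DataFrame(tw_rows, columns=["participant_id", "method", "behavior", "value"])

    total_days = n * len(config.periods) * config.n_days
    day_rngs = rng.spawn(total_days)

    epoch_rows: list[pd.DataFrame] = []
    event_rows: list[pd.DataFrame] = []
    truth_rows: list[tuple] = []
    hhmm = [f"{(e * EPOCH_MINUTES) // 60:02d}:{(e * EPOCH_MINUTES) % 60:02d}"
            for e in range(EPOCHS_PER_DAY)]
    label_arr = np.array([CODE_LABELS[i] for i in range(len(TRUE_LABELS) + 1)])

    k = 0
    for i in range(n):
        pid = f"P{i + 1:03d}"
        for period in config.periods:
            start = config.period_start(period)
            for d in range(config.n_days):
                date = start + dt.timedelta(days=d)
                drng = day_rngs[k]
                k += 1
                targets = _day_targets(config, u[i], period, drng)
                budgets = _epoch_budgets(targets)
                epochs_true = _layout_day(budgets, drng)
                minute_seq = np.repeat(epochs_true, EPOCH_MINUTES)

                shifts = {}
                for b in (LPA, MVPA):
                    scale = 1.0
                    if config.heteroscedastic and config.mean_minutes[b] > 0:
                        scale = budgets[b] * EPOCH_MINUTES / config.mean_minutes[b]
                    eta = drng.normal(0.0, config.sigma_residual * scales[b] * scale) \
                        if config.sigma_residual > 0 else 0.0
                    shifts[b] = v_app[b] + eta

                completeness = _day_completeness(config, drng)
                app = observe_app(minute_seq, config, drng, shifts, completeness)
                inject = bool(drng.random() < config.nonwear_prob)
                events = observe_device(minute_seq, config, drng, inject)

                epoch_rows.append(pd.DataFrame({
                    "participant_id": pid,
                    "date": date.isoformat(),
                    "epoch_start_hhmm": hhmm,
                    "behavior": label_arr[app],
                }))
                midnight = dt.datetime.combine(date, dt.time())
                event_rows.append(pd.DataFrame({
                    "participant_id": pid,
                    "start_datetime": [
                        (midnight + dt.timedelta(minutes=int(s))).isoformat()
                        for s, *_ in events
                    ],
                    "duration_s": [dur * 60 for _, dur, *_ in events],
                    "event": [cls for *_, cls, _ in events],
                    "cadence_steps_per_min": [cad for *_, cad in events],
                }))
                for b in TRUE_LABELS:
                    truth_rows.append(
                        (pid, date.isoformat(), period, b, budgets[b] * EPOCH_MINUTES)
                    )

    truth = pd.DataFrame(
        truth_rows,
        columns=["participant_id", "date", "period", "behavior", "true_minutes"],
    )
    return SimulationOutput(
        epoch_log=pd.concat(epoch_rows, ignore_index=True),
        device_events=pd.concat(event_rows, ignore_index=True),
        ground_truth=GroundTruth(true_day_minutes=truth, true_icc=config.true_icc),
        twoway_table=twoway,
    )
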