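"""End-to-end orchestration: simulate/load, clean, analyse, report.

``run_full_validation`` drives the whole pipeline from one declarative
:class:`~actvalid.config.RunConfig` and writes per-behavior reliability,
validity, Bland–Altman and responsiveness tables plus a run manifest that
accounts for every exclusion step (n excluded and % of initial days).
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import io as avio
from .config import RunConfig, WAKING_BEHAVIORS
from .models import MethodAgreementModel, ResponsivenessModel, TestRetestModel
from .preprocessing import (
    PreprocessingError,
    build_paired_day_table,
    flag_valid_days,
    weekly_average,
)
from .simulate import simulate_paired_cohort

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised when a pipeline stage cannot produce output."""


def exclusion_accounting(steps: list[tuple[str, int]], n_initial: int) -> pd.DataFrame:
    """Per-filter exclusion counts and percentages of the initial n.

    ``steps`` is an ordered list of (filter name, n excluded); percentages
    are reported to 1 decimal.
    """
    if n_initial <= 0:
        raise PipelineError("initial count must be positive")
    rows = [(name, n, round(100.0 * n / n_initial, 1)) for name, n in steps]
    return pd.DataFrame(rows, columns=["filter", "n_excluded", "pct_of_initial"])


def _day_count(table: pd.DataFrame) -> int:
    return table[["participant_id", "date"]].drop_duplicates().shape[0]


def run_full_validation(config: RunConfig, out_dir) -> dict:
    """Run the full validation pipeline and write its report bundle.

    Returns a dict with the fitted results objects and the manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO))

    sim_cfg = config.simulation
    if config.seed is not None:
        sim_cfg = sim_cfg.model_copy(update={"seed": config.seed})

    if config.app_csv:
        epoch_log = avio.read_epoch_log(config.app_csv)
        device_events = avio.read_device_events(config.device_csv)
        ground_truth = None
    else:
        simulated = simulate_paired_cohort(sim_cfg)
        epoch_log = simulated.epoch_log
        device_events = simulated.device_events
        ground_truth = simulated.ground_truth

    paired = build_paired_day_table(epoch_log, device_events, config.classifier,
                                    sim_cfg.study_start)
    n_initial = _day_count(paired)

    flagged = flag_valid_days(paired, config.classifier, context="validity")
    days = flagged.drop_duplicates(["participant_id", "date"])
    n_low_completion = int(
        (days["app_completion"] <= config.classifier.app_min_completion).sum())
    n_low_wear = int(
        ((days["app_completion"] > config.classifier.app_min_completion)
         & (days["device_wear_hours"] < config.classifier.wear_min_hours)).sum())
    n_valid = _day_count(flagged[flagged["valid"]])
    if n_valid == 0:
        raise PipelineError("no valid days remain after exclusion rules")
    accounting = exclusion_accounting(
        [("app_completion<=threshold", n_low_completion),
         ("device_wear<threshold", n_low_wear)],
        n_initial,
    )
    avio.write_paired_table(flagged, out / "paired_days.csv")

    # reliability: diary-only filtering, two baseline weeks as raters
    rel_flagged = flag_valid_days(paired, config.classifier, context="reliability")
    rel_weekly = weekly_average(rel_flagged, config.classifier)
    reliability = TestRetestModel(rel_weekly, *config.reliability_weeks).fit()
    reliability.to_frame().to_csv(out / "reliability.csv", index=False)

    # validity: paired filtering, ICC/delta/RMSE and Bland–Altman
    agreement_model = MethodAgreementModel(
        flagged, pool_periods=(config.icc_pooling == "pooled"))
    validity = agreement_model.fit()
    validity.to_frame().to_csv(out / "validity.csv", index=False)
    for b in WAKING_BEHAVIORS:
        keys = [k for k in validity.bland_altman
                if k == b or (isinstance(k, tuple) and k[0] == b)]
        for k in keys:
            ax = validity.plot_bland_altman(k)
            name = b if isinstance(k, str) else f"{k[0]}_{k[1]}"
            ax.figure.savefig(out / f"bland_altman_{name}.png", dpi=100)
            import matplotlib.pyplot as plt
            plt.close(ax.figure)

    # responsiveness: change between the two intervention-spanning periods
    weekly = weekly_average(flagged, config.classifier)
    responsiveness = ResponsivenessModel(
        weekly, *config.responsiveness_periods, config=config.responsiveness).fit()
    responsiveness.to_frame().to_csv(out / "responsiveness.csv", index=False)

    manifest = {
        "seed": sim_cfg.seed,
        "config": config.model_copy(
            update={"simulation": sim_cfg}).model_dump(mode="json"),
        "n_days_initial": n_initial,
        "n_days_valid": n_valid,
        "exclusions": accounting.to_dict(orient="records"),
        "n_weekly_rows": int(len(weekly)),
        "true_icc": ground_truth.true_icc if ground_truth is not None else None,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return {
        "paired": flagged,
        "weekly": weekly,
        "reliability": reliability,
        "validity": validity,
        "responsiveness": responsiveness,
        "manifest": manifest,
        "ground_truth": ground_truth,
    }
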