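"""Model / Results objects tying the statistics to paired activity data.

Three fitted-model entry points mirror the three questions asked of a
self-report instrument against a criterion device:

* :class:`MethodAgreementModel` — validity: ICC, mean difference, RMSE and
  Bland–Altman per behavior on paired participant-days;
* :class:`TestRetestModel` — reliability: ICC between two stable weeks of
  weekly averages;
* :class:`ResponsivenessModel` — responsiveness to change: stability
  classification, RS and MPE between two measurement periods.

Each ``fit()`` returns a Results object carrying estimates, intervals and a
``summary()`` table; plotting hangs off the results.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import agreement as agr
from . import responsiveness as resp
from .config import WAKING_BEHAVIORS, ResponsivenessConfig


def _fmt(x, nd=2):
    return "nan" if x is None or not np.isfinite(x) else f"{x:.{nd}f}"


# -- validity -----------------------------------------------------------------

class MethodAgreementModel:
    """Criterion-validity model for a paired-day table.

    Parameters
    ----------
    paired_table : DataFrame
        Long table with participant_id, date, period, behavior, app_minutes,
        device_minutes and (optionally) a ``valid`` flag; invalid rows are
        dropped before fitting.
    behaviors : sequence of str
        Behaviors to fit (default: sedentary, lpa, mvpa).
    pool_periods : bool
        Pool all measurement periods into one ICC (default) or fit each
        period separately.
    """

    def __init__(self, paired_table: pd.DataFrame,
                 behaviors=WAKING_BEHAVIORS, pool_periods: bool = True,
                 loa_multiplier: float = agr.LOA_MULTIPLIER):
        table = paired_table
        if "valid" in table.columns:
            table = table[table["valid"].astype(bool)]
        if table.empty:
            raise agr.AgreementError("no valid participant-days to fit")
        self.table = table.reset_index(drop=True)
        self.behaviors = tuple(behaviors)
        self.pool_periods = pool_periods
        self.loa_multiplier = loa_multiplier

    @classmethod
    def from_csv(cls, path, **kwargs) -> "MethodAgreementModel":
        from .io import read_paired_table
        return cls(read_paired_table(path), **kwargs)

    def fit(self, alpha: float = 0.05) -> "MethodAgreementResults":
        keys = ([(b, None) for b in self.behaviors] if self.pool_periods else
                [(b, p) for b in self.behaviors
                 for p in sorted(self.table["period"].unique())])
        results, ba = {}, {}
        for b, period in keys:
            sub = self.table[self.table["behavior"] == b]
            if period is not None:
                sub = sub[sub["period"] == period]
            a = sub["app_minutes"].to_numpy(dtype=float)
            d = sub["device_minutes"].to_numpy(dtype=float)
            key = b if period is None else (b, period)
            results[key] = agr.AgreementResult(
                behavior=b,
                icc=agr.icc_absolute_agreement(np.column_stack([a, d]), alpha=alpha),
                delta=agr.mean_difference(a, d, alpha=alpha),
                rmse=agr.rmse(a, d),
                n_days=a.size,
            )
            ba[key] = agr.bland_altman(a, d, loa_multiplier=self.loa_multiplier)
        return MethodAgreementResults(model=self, results=results, bland_altman=ba)


@dataclass
class MethodAgreementResults:
    model: MethodAgreementModel
    results: dict
    bland_altman: dict

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: behavior, statistic, estimate, ci_low, ci_high, n."""
        rows = []
        for key, r in self.results.items():
            b = key if isinstance(key, str) else f"{key[0]}:{key[1]}"
            ba = self.bland_altman[key]
            rows += [
                (b, "icc", r.icc.icc, r.icc.ci_low, r.icc.ci_high, r.icc.n_subjects),
                (b, "delta", r.delta.delta, r.delta.ci_low, r.delta.ci_high, r.delta.n),
                (b, "rmse", r.rmse, np.nan, np.nan, r.n_days),
                (b, "ba_bias", ba.bias, ba.loa_low, ba.loa_high, ba.n),
                (b, "ba_tau", ba.tau, np.nan, np.nan, ba.n),
                (b, "prop_bias_beta", ba.prop_bias_beta, np.nan, np.nan, ba.n),
            ]
        return pd.DataFrame(rows, columns=[
            "behavior", "statistic", "estimate", "ci_low", "ci_high", "n"])

    def summary(self) -> str:
        lines = ["Method agreement (diary vs criterion device)",
                 f"{'behavior':<16}{'ICC [95% CI]':<26}{'delta [95% CI]':<30}"
                 f"{'RMSE':>8}{'n':>6}  band"]
        for key, r in self.results.items():
            b = key if isinstance(key, str) else f"{key[0]}:{key[1]}"
            icc = f"{_fmt(r.icc.icc)} [{_fmt(r.icc.ci_low)}, {_fmt(r.icc.ci_high)}]"
            dl = (f"{_fmt(r.delta.delta, 1)} "
                  f"[{_fmt(r.delta.ci_low, 1)}, {_fmt(r.delta.ci_high, 1)}]")
            lines.append(f"{b:<16}{icc:<26}{dl:<30}{_fmt(r.rmse, 1):>8}"
                         f"{r.n_days:>6}  {r.icc.interpretation}")
        for key, ba in self.bland_altman.items():
            b = key if isinstance(key, str) else f"{key[0]}:{key[1]}"
            if ba.log_transformed:
                loa = (f"LoA halfwidth = {_fmt(ba.loa_halfwidth_per_mean, 3)} x mean "
                       f"(log10 path)")
            else:
                loa = f"LoA [{_fmt(ba.loa_low, 1)}, {_fmt(ba.loa_high, 1)}]"
            lines.append(f"  {b}: bias {_fmt(ba.bias, 1)}, tau {_fmt(ba.tau)} "
                         f"({'hetero' if ba.heteroscedastic else 'homo'}scedastic), {loa}")
        return "\n".join(lines)

    def plot_bland_altman(self, behavior, ax=None):
        from .plots import bland_altman_plot
        key = behavior
        sub = self.model.table[self.model.table["behavior"] ==
                               (behavior if isinstance(behavior, str) else behavior[0])]
        if not isinstance(behavior, str):
            sub = sub[sub["period"] == behavior[1]]
        return bland_altman_plot(
            sub["app_minutes"].to_numpy(float), sub["device_minutes"].to_numpy(float),
            self.bland_altman[key], ax=ax,
            title=str(key),
        )


# -- reliability --------------------------------------------------------------

class TestRetestModel:
    """Test–retest reliability between two weeks of weekly averages.

    ``weekly`` is a weekly-average table (participant_id, period, behavior,
    app_minutes, ...); the two weeks act as the raters of a two-way
    random-effects absolute-agreement ICC.
    """

    def __init__(self, weekly: pd.DataFrame, week_a: str, week_b: str,
                 value_col: str = "app_minutes"):
        self.weekly = weekly
        self.week_a = week_a
        self.week_b = week_b
        self.value_col = value_col

    def fit(self) -> "TestRetestResults":
        wa = self.weekly[self.weekly["period"] == self.week_a]
        wb = self.weekly[self.weekly["period"] == self.week_b]
        if wa.empty or wb.empty:
            raise agr.AgreementError(
                f"no weekly averages for {self.week_a!r} and/or {self.week_b!r}")
        iccs = agr.test_retest_reliability(wa, wb, value_col=self.value_col)
        return TestRetestResults(model=self, iccs=iccs)


@dataclass
class TestRetestResults:
    model: TestRetestModel
    iccs: dict[str, agr.ICCResult]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(b, r.icc, r.ci_low, r.ci_high, r.n_subjects, r.interpretation)
             for b, r in self.iccs.items()],
            columns=["behavior", "icc", "ci_low", "ci_high", "n", "interpretation"])

    def summary(self) -> str:
        lines = [f"Test–retest reliability ({self.model.week_a} vs {self.model.week_b})"]
        for b, r in self.iccs.items():
            lines.append(f"  {b:<12} ICC {_fmt(r.icc)} "
                         f"[{_fmt(r.ci_low)}, {_fmt(r.ci_high)}] "
                         f"(n={r.n_subjects}, {r.interpretation})")
        return "\n".join(lines)


# -- responsiveness -----------------------------------------------------------

@dataclass
class ResponsivenessRow:
    behavior: str
    method: str
    mean_change: float
    ci_low: float
    ci_high: float
    sd_stable: float
    rs: float
    n: int
    n_stable: int


class ResponsivenessModel:
    """Responsiveness to change between two measurement periods.

    Stability is classified from the criterion (device) change scores;
    each method's RS divides its |mean change| by the SD of that method's
    change among the stable participants.
    """

    def __init__(self, weekly: pd.DataFrame, t1: str, t2: str,
                 config: ResponsivenessConfig | None = None):
        self.weekly = weekly
        self.t1 = t1
        self.t2 = t2
        self.config = config or ResponsivenessConfig()

    def fit(self, alpha: float = 0.05) -> "ResponsivenessResults":
        cfg = self.config
        changes = resp.change_scores(self.weekly, self.t1, self.t2)
        stable = resp.classify_stable(changes, cfg.stability_thresholds)
        if cfg.stable_scope == "global":
            by_pid = pd.Series(stable.values, index=changes["participant_id"])
            all_stable = by_pid.groupby(level=0).all()
            stable = changes["participant_id"].map(all_stable)
        rows, substantial, mpe = [], {}, {}
        for b in sorted(changes["behavior"].unique()):
            mask = changes["behavior"] == b
            sub = changes[mask]
            sub_stable = sub[stable[mask].to_numpy(dtype=bool)]
            substantial[b] = resp.pct_substantial_change(
                changes, b, cfg.stability_thresholds)
            for method, col in (("app", "app_change"), ("device", "device_change")):
                vals = sub[col].to_numpy(dtype=float)
                mean_change = float(vals.mean())
                if vals.size >= 2:
                    half = (stats.t.ppf(1 - alpha / 2, vals.size - 1)
                            * vals.std(ddof=1) / np.sqrt(vals.size))
                    lo, hi = mean_change - half, mean_change + half
                else:
                    lo = hi = np.nan
                sv = sub_stable[col].to_numpy(dtype=float)
                sd_stable = float(sv.std(ddof=1)) if sv.size >= 2 else np.nan
                try:
                    rs = resp.responsiveness_statistic(mean_change, sd_stable)
                except resp.ResponsivenessError:
                    rs = np.nan
                rows.append(ResponsivenessRow(
                    behavior=b, method=method, mean_change=mean_change,
                    ci_low=lo, ci_high=hi, sd_stable=sd_stable, rs=rs,
                    n=vals.size, n_stable=sv.size))
            try:
                mpe[b] = round(resp.mean_percentage_error(
                    sub["app_change"], sub["device_change"], mode=cfg.mpe_mode), 1)
            except resp.ResponsivenessError:
                mpe[b] = np.nan
        return ResponsivenessResults(model=self, rows=rows,
                                     pct_substantial=substantial, mpe=mpe,
                                     changes=changes, stable=stable)


@dataclass
class ResponsivenessResults:
    model: ResponsivenessModel
    rows: list[ResponsivenessRow]
    pct_substantial: dict[str, tuple[float, int, int]]
    mpe: dict[str, float]
    changes: pd.DataFrame = field(repr=False, default=None)
    stable: pd.Series = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([vars(r) for r in self.rows])
        df["pct_substantial"] = df["behavior"].map(
            {b: v[0] for b, v in self.pct_substantial.items()})
        df["mpe_pct"] = df["behavior"].map(self.mpe)
        df["mpe_mode"] = self.model.config.mpe_mode
        return df

    def summary(self) -> str:
        lines = [f"Responsiveness to change ({self.model.t1} -> {self.model.t2})",
                 f"{'behavior':<12}{'method':<9}{'mean change [95% CI]':<30}"
                 f"{'SD stable':>10}{'RS':>7}"]
        for r in self.rows:
            mc = f"{_fmt(r.mean_change, 1)} [{_fmt(r.ci_low, 1)}, {_fmt(r.ci_high, 1)}]"
            lines.append(f"{r.behavior:<12}{r.method:<9}{mc:<30}"
                         f"{_fmt(r.sd_stable, 1):>10}{_fmt(r.rs):>7}")
        for b, (pct, count, n) in self.pct_substantial.items():
            lines.append(f"  {b}: substantial change {pct:.0f}% ({count}/{n}), "
                         f"MPE {_fmt(self.mpe.get(b, np.nan), 1)}%")
        return "\n".join(lines)
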