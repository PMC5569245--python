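"""Method-comparison statistics: ICC, bias estimates and Bland–Altman.

The intraclass correlation used throughout is the single-measures,
absolute-agreement form under a two-way random-effects ANOVA (ICC(A,1) in
McGraw & Wong's taxonomy): with between-subject, between-rater and error
mean squares MSR, MSC, MSE over n subjects and k raters,

    ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

with the F-distribution confidence bounds of the same construction.
Interpretation bands: poor < 0.4 <= moderate <= 0.8 < strong.

Bland–Altman limits of agreement use a multiplier of exactly 2 (not 1.96).
Heteroscedasticity is declared when Kendall's tau between the absolute
differences and the pair means exceeds 0.1; the analysis then moves to
log10 scale and the limits are back-transformed as a function of the mean,
half-width = 2 * mean * (10^SD - 1) / (10^SD + 1).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

ICC_MODEL = "two-way random, absolute agreement, single measures"
HETEROSCEDASTICITY_TAU = 0.1
LOA_MULTIPLIER = 2.0


class AgreementError(ValueError):
    """Raised when a statistic is undefined for the given input."""


def interpret_icc(icc: float) -> str:
    """Reliability band: poor (<0.4), moderate (0.4–0.8) or strong (>0.8)."""
    if icc < 0.4:
        return "poor"
    if icc <= 0.8:
        return "moderate"
    return "strong"


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    n_subjects: int
    k_raters: int = 2
    model: str = ICC_MODEL
    interpretation: str = ""

    def __post_init__(self):
        if not self.interpretation:
            self.interpretation = interpret_icc(self.icc)


@dataclass
class DeltaResult:
    delta: float
    ci_low: float
    ci_high: float
    n: int


@dataclass
class AgreementResult:
    behavior: str
    icc: ICCResult
    delta: DeltaResult
    rmse: float
    n_days: int


@dataclass
class BlandAltmanResult:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    tau: float
    heteroscedastic: bool
    log_transformed: bool
    prop_bias_beta: float
    prop_bias_p: float
    n: int
    # log-scale quantities, populated on the heteroscedastic path
    bias_log10: float = np.nan
    sd_log10: float = np.nan
    loa_halfwidth_per_mean: float = np.nan
    n_zero_adjusted: int = 0

    def loa_halfwidth(self, mean):
        """Half-width of the limits of agreement at a given pair mean."""
        if self.log_transformed:
            return self.loa_halfwidth_per_mean * np.asarray(mean, dtype=float)
        return np.full_like(np.asarray(mean, dtype=float),
                            LOA_MULTIPLIER * self.sd_diff)


# -- ICC ----------------------------------------------------------------------

def _two_way_mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    n, k = x.shape
    grand = x.mean()
    rows = x.mean(axis=1)
    cols = x.mean(axis=0)
    msr = k * ((rows - grand) ** 2).sum() / (n - 1)
    msc = n * ((cols - grand) ** 2).sum() / (k - 1)
    mse = ((x - rows[:, None] - cols[None, :] + grand) ** 2).sum() / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_absolute_agreement(values, alpha: float = 0.05) -> ICCResult:
    """Single-measures absolute-agreement ICC with its 95% F-based CI.

    ``values`` is an (n subjects) x (k raters) matrix; rows with missing
    cells are dropped with a logged count.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise AgreementError("need a 2-D subjects x raters matrix with >= 2 raters")
    complete = ~np.isnan(x).any(axis=1)
    dropped = int((~complete).sum())
    if dropped:
        logger.info("icc: dropped %d rows with missing cells", dropped)
    x = x[complete]
    n, k = x.shape
    if n < 2:
        raise AgreementError(f"need >= 2 complete subjects, got {n}")
    if np.ptp(x) == 0:
        raise AgreementError("zero total variance: ICC undefined")
    msr, msc, mse = _two_way_mean_squares(x)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0:
        raise AgreementError("degenerate mean squares: ICC undefined")
    icc = (msr - mse) / denom

    # McGraw & Wong F-based interval for ICC(A,1)
    with np.errstate(all="ignore"):
        a = (k * icc) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
        b = 1.0 + (k * icc * (n - 1.0)) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
        v_num = (a * msc + b * mse) ** 2
        v_den = (a * msc) ** 2 / (k - 1.0) + (b * mse) ** 2 / ((n - 1.0) * (k - 1.0))
        v = v_num / v_den if v_den > 0 else np.nan
        lo = hi = np.nan
        if np.isfinite(v) and v > 0:
            fl = stats.f.ppf(1.0 - alpha / 2.0, n - 1.0, v)
            fu = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1.0)
            lo = n * (msr - fl * mse) / (fl * (k * msc + (k * n - k - n) * mse) + n * msr)
            hi = n * (fu * msr - mse) / (k * msc + (k * n - k - n) * mse + n * fu * msr)
    if not (np.isfinite(lo) and np.isfinite(hi)):
        lo = hi = icc  # degenerate (e.g. perfect agreement): interval collapses
    lo, hi = min(lo, icc), max(hi, icc)
    return ICCResult(icc=float(icc), ci_low=float(lo), ci_high=float(hi),
                     n_subjects=n, k_raters=k)


# -- bias estimates -----------------------------------------------------------

def mean_difference(a, b, ci: bool = True, alpha: float = 0.05) -> DeltaResult:
    """Mean difference (a - b) with a t-based confidence interval."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise AgreementError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise AgreementError("empty input")
    d = a - b
    n = d.size
    delta = float(d.mean())
    if not ci:
        return DeltaResult(delta=delta, ci_low=np.nan, ci_high=np.nan, n=n)
    if n < 2:
        raise AgreementError("confidence interval undefined for n < 2")
    half = stats.t.ppf(1.0 - alpha / 2.0, n - 1) * d.std(ddof=1) / np.sqrt(n)
    return DeltaResult(delta=delta, ci_low=delta - half, ci_high=delta + half, n=n)


def rmse(a, b) -> float:
    """Root mean square error, sqrt(mean((a_i - b_i)^2))."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise AgreementError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise AgreementError("empty input")
    return float(np.sqrt(np.mean((a - b) ** 2)))


# -- Bland–Altman -------------------------------------------------------------

def assess_heteroscedasticity(a, b) -> tuple[float, bool]:
    """Kendall's tau between |a-b| and the pair means; flag when tau > 0.1."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3:
        raise AgreementError("need n >= 3 to assess heteroscedasticity")
    d = np.abs(a - b)
    m = (a + b) / 2.0
    tau = stats.kendalltau(d, m).statistic
    if not np.isfinite(tau):
        warnings.warn("Kendall tau undefined (tied input); treating as homoscedastic")
        return 0.0, False
    return float(tau), bool(tau > HETEROSCEDASTICITY_TAU)


def _adjust_zeros(x: np.ndarray, name: str) -> tuple[np.ndarray, int]:
    if (x < 0).any():
        raise AgreementError(f"log10 path requires nonnegative {name} values")
    zeros = x == 0
    if not zeros.any():
        return x, 0
    positive = x[x > 0]
    if positive.size == 0:
        raise AgreementError(f"log10 path impossible: all {name} values are zero")
    out = x.copy()
    out[zeros] = positive.min() / 2.0
    logger.info("bland_altman: replaced %d zero %s values by half the smallest "
                "positive value", int(zeros.sum()), name)
    return out, int(zeros.sum())


def bland_altman(a, b, loa_multiplier: float = LOA_MULTIPLIER) -> BlandAltmanResult:
    """Bland–Altman analysis with automatic heteroscedasticity handling.

    Homoscedastic data get limits of agreement bias ± 2 SD of the
    differences.  Heteroscedastic data (tau > 0.1) are log10-transformed and
    the limits are reported as a function of the mean with half-width
    2 * mean * (10^SD - 1) / (10^SD + 1).  Proportional bias is always the
    least-squares slope of the differences on the pair means.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise AgreementError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < 3:
        raise AgreementError("need n >= 3 for Bland–Altman analysis")
    d = a - b
    m = (a + b) / 2.0
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    tau, hetero = assess_heteroscedasticity(a, b)
    if np.ptp(m) == 0:
        beta, pval = 0.0, np.nan
    else:
        fit = stats.linregress(m, d)
        beta, pval = float(fit.slope), float(fit.pvalue)
    res = BlandAltmanResult(
        bias=bias, sd_diff=sd, loa_low=bias - loa_multiplier * sd,
        loa_high=bias + loa_multiplier * sd, tau=tau, heteroscedastic=hetero,
        log_transformed=False, prop_bias_beta=beta, prop_bias_p=pval, n=a.size,
    )
    if hetero:
        a_adj, na = _adjust_zeros(a, "first-method")
        b_adj, nb = _adjust_zeros(b, "second-method")
        dl = np.log10(a_adj) - np.log10(b_adj)
        sd_log = float(dl.std(ddof=1))
        res.log_transformed = True
        res.bias_log10 = float(dl.mean())
        res.sd_log10 = sd_log
        res.loa_halfwidth_per_mean = (
            loa_multiplier * (10.0 ** sd_log - 1.0) / (10.0 ** sd_log + 1.0)
        )
        res.loa_low = res.loa_high = np.nan  # function of the mean instead
        res.n_zero_adjusted = na + nb
    return res


# -- stratified analyses ------------------------------------------------------

def stratified_icc(table: pd.DataFrame, stratum: str,
                   value_cols: tuple[str, str] = ("app_minutes", "device_minutes"),
                   min_n: int = 2) -> tuple[dict, dict[object, int]]:
    """Per-stratum ICC between the two methods.

    ``stratum`` names a column of ``table`` (e.g. ``participant_id`` or
    ``hour``).  Strata with fewer than ``min_n`` complete pairs, or where the
    ICC is undefined, are reported in the second dict with their pair counts.
    """
    if stratum not in table.columns:
        raise AgreementError(f"no column {stratum!r} in table")
    results: dict = {}
    skipped: dict[object, int] = {}
    for key, grp in table.groupby(stratum):
        x = grp[list(value_cols)].dropna().to_numpy(dtype=float)
        if x.shape[0] < min_n:
            skipped[key] = x.shape[0]
            continue
        try:
            results[key] = icc_absolute_agreement(x)
        except AgreementError:
            skipped[key] = x.shape[0]
    return results, skipped


def test_retest_reliability(week_a: pd.DataFrame, week_b: pd.DataFrame,
                            value_col: str = "app_minutes") -> dict[str, ICCResult]:
    """Test–retest ICC per behavior, using the two weeks as raters.

    Inputs are weekly-average tables (participant_id, behavior, value
    column); only participants present in both weeks contribute.
    """
    out: dict[str, ICCResult] = {}
    for b in sorted(set(week_a["behavior"]) & set(week_b["behavior"])):
        a = week_a[week_a["behavior"] == b].set_index("participant_id")[value_col]
        c = week_b[week_b["behavior"] == b].set_index("participant_id")[value_col]
        merged = pd.concat({"w1": a, "w2": c}, axis=1, join="inner")
        out[b] = icc_absolute_agreement(merged.to_numpy(dtype=float))
    return out


def regress_on_covariates(values: pd.Series, covariates: pd.DataFrame):
    """Generic hook: OLS of per-stratum statistics on stratum covariates.

    ``values`` is indexed by stratum (e.g. per-participant ICCs), and
    ``covariates`` shares that index.  Returns a fitted statsmodels OLS
    results object.
    """
    import statsmodels.api as sm

    joined = covariates.join(values.rename("_y"), how="inner").dropna()
    if len(joined) <= covariates.shape[1] + 1:
        raise AgreementError("too few strata for covariate regression")
    X = sm.add_constant(joined[covariates.columns].astype(float))
    return sm.OLS(joined["_y"].astype(float), X).fit()
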