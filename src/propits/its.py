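"""Interrupted time-series analysis of monthly proportions.

The estimand is the *proportion difference*: the pandemic-period trend
slope minus the prepandemic trend slope of the monthly percentage of
hospitalizations carrying a mental-health diagnosis.  Each period's trend
is an unweighted ordinary-least-squares line fitted to the monthly
percentages against a within-period month index; the binomial sampling
uncertainty of each monthly proportion is propagated by a parametric
bootstrap that redraws every month's numerator from Binomial(n, k/n),
refits both lines, and records the resampled difference.

Slopes, differences and confidence limits are all in percentage points of
the monthly proportion per month, so a difference of 0.60 reads as "the
proportion grew 0.60 percentage points per month faster during the
pandemic than before it".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import ANY_MH, FEMALE_SHARE, pooled_series
from .errors import FitError
from .periods import N_PANDEMIC_MONTHS, N_PRE_MONTHS

logger = logging.getLogger(__name__)

MIN_MONTHS_PER_FIT = 3

#: The condition groups singled out for condition-specific analyses: the
#: three most prevalent groups plus eating disorders.
FEATURED_CONDITIONS = (
    "Anxiety disorders",
    "Depressive disorders",
    "Suicidality or self-injury",
    "Eating disorders",
)


@dataclass(frozen=True)
class PeriodFit:
    """OLS trend line for one period, in percentage points."""

    period: str
    slope: float  # percentage points per month
    intercept: float  # percentage points at the period's first month
    months_used: int


@dataclass(frozen=True)
class ITSResult:
    """Per-site (or pooled) ITS estimate with bootstrap inference."""

    site_id: str
    outcome: str
    slope_pre: float
    slope_pre_ci: tuple[float, float]
    slope_pre_p: float
    slope_pandemic: float
    slope_pandemic_ci: tuple[float, float]
    slope_pandemic_p: float
    delta: float  # proportion difference, pp/month
    ci_low: float
    ci_high: float
    p_delta: float
    delta_boot_sd: float
    B: int
    seed: int
    error: str | None = field(default=None)

    def as_row(self) -> dict:
        return {
            "site_id": self.site_id,
            "outcome": self.outcome,
            "slope_pre": self.slope_pre,
            "slope_pre_ci_low": self.slope_pre_ci[0],
            "slope_pre_ci_high": self.slope_pre_ci[1],
            "slope_pre_p": self.slope_pre_p,
            "slope_pandemic": self.slope_pandemic,
            "slope_pandemic_ci_low": self.slope_pandemic_ci[0],
            "slope_pandemic_ci_high": self.slope_pandemic_ci[1],
            "slope_pandemic_p": self.slope_pandemic_p,
            "delta": self.delta,
            "delta_ci_low": self.ci_low,
            "delta_ci_high": self.ci_high,
            "delta_p": self.p_delta,
            "delta_boot_sd": self.delta_boot_sd,
            "B": self.B,
            "seed": self.seed,
        }


def ols_slope_weights(t: np.ndarray) -> np.ndarray:
    """Weights w with slope = w @ y for OLS of y on t (closed form)."""
    t = np.asarray(t, dtype=float)
    tc = t - t.mean()
    return tc / (tc @ tc)


def fit_period_trend(t, proportions_pct, period: str = "") -> PeriodFit:
    """Fit the OLS trend of monthly percentages on a 0-based month index.

    ``t`` is the within-period month index of each usable month (months
    with a zero denominator are excluded before calling), and
    ``proportions_pct`` the corresponding percentages 100*k/n.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(proportions_pct, dtype=float)
    if t.size != y.size:
        raise FitError("month index and proportion vectors differ in length")
    if t.size < MIN_MONTHS_PER_FIT:
        raise FitError(
            f"period {period or '?'}: {t.size} usable months "
            f"(need at least {MIN_MONTHS_PER_FIT})"
        )
    slope = float(ols_slope_weights(t) @ y)
    intercept = float(y.mean() - slope * t.mean())
    return PeriodFit(period=period, slope=slope, intercept=intercept, months_used=int(t.size))


def proportion_difference(fit_pre: PeriodFit, fit_pandemic: PeriodFit) -> float:
    """Pandemic slope minus prepandemic slope; positive = faster growth
    during the pandemic."""
    return fit_pandemic.slope - fit_pre.slope


def _period_arrays(series: pd.DataFrame, period: str):
    sub = series[series["period"] == period].sort_values("month")
    n = sub["n"].to_numpy(dtype=np.int64)
    k = sub["k"].to_numpy(dtype=np.int64)
    t = np.arange(n.size, dtype=float)
    usable = n > 0
    if (~usable).any():
        logger.warning(
            "excluding %d zero-denominator months from the %s fit",
            int((~usable).sum()),
            period,
        )
    return t[usable], n[usable], k[usable]


def bootstrap_its(
    series: pd.DataFrame,
    B: int = 10_000,
    seed: int = 0,
    *,
    alpha: float = 0.05,
    p_method: str = "z",
) -> ITSResult:
    """Parametric-bootstrap ITS for one site/outcome monthly series.

    Per iteration, every usable month's numerator is redrawn independently
    from Binomial(n_m, k_m/n_m); both period trends are refitted and the
    resampled slopes and slope difference recorded.  Confidence limits are
    the empirical alpha/2 and 1-alpha/2 percentiles of the bootstrap
    distribution; the two-sided p-value is a z test of the bootstrap mean
    against zero using the bootstrap SD (``p_method="z"``), or the
    symmetric percentile p-value (``p_method="percentile"``).

    Draws are generated iteration-major from one seeded generator; output
    is bit-reproducible for a fixed seed and B.
    """
    site = str(series["site_id"].iloc[0])
    outcome = str(series["outcome"].iloc[0])
    t_pre, n_pre, k_pre = _period_arrays(series, "pre")
    t_pan, n_pan, k_pan = _period_arrays(series, "pandemic")

    fit_pre = fit_period_trend(t_pre, 100.0 * k_pre / n_pre, "pre")
    fit_pan = fit_period_trend(t_pan, 100.0 * k_pan / n_pan, "pandemic")
    delta_hat = proportion_difference(fit_pre, fit_pan)

    w_pre = ols_slope_weights(t_pre)
    w_pan = ols_slope_weights(t_pan)
    n_all = np.concatenate([n_pre, n_pan])
    p_all = np.concatenate([k_pre / n_pre, k_pan / n_pan])

    rng = np.random.default_rng(seed)
    # One call, shape (B, months), filled row by row: iteration-major order.
    k_star = rng.binomial(n_all, p_all, size=(B, n_all.size))
    p_star = 100.0 * k_star / n_all
    slopes_pre = p_star[:, : n_pre.size] @ w_pre
    slopes_pan = p_star[:, n_pre.size :] @ w_pan
    deltas = slopes_pan - slopes_pre

    lo, hi = 100 * alpha / 2.0, 100 * (1 - alpha / 2.0)
    ci = np.percentile(deltas, [lo, hi])
    return ITSResult(
        site_id=site,
        outcome=outcome,
        slope_pre=fit_pre.slope,
        slope_pre_ci=tuple(np.percentile(slopes_pre, [lo, hi])),
        slope_pre_p=_boot_p(slopes_pre, p_method),
        slope_pandemic=fit_pan.slope,
        slope_pandemic_ci=tuple(np.percentile(slopes_pan, [lo, hi])),
        slope_pandemic_p=_boot_p(slopes_pan, p_method),
        delta=delta_hat,
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p_delta=_boot_p(deltas, p_method),
        delta_boot_sd=float(deltas.std(ddof=1)),
        B=B,
        seed=seed,
    )


def _boot_p(draws: np.ndarray, method: str) -> float:
    sd = draws.std(ddof=1)
    if sd == 0:
        logger.warning("degenerate bootstrap distribution; p-value undefined")
        return float("nan")
    if method == "z":
        z = draws.mean() / sd
        return float(2.0 * stats.norm.sf(abs(z)))
    if method == "percentile":
        frac = min((draws <= 0).mean(), (draws >= 0).mean())
        return float(min(1.0, 2.0 * frac))
    raise ValueError(f"unknown p-value method {method!r}")


def run_all_its(
    series_by_outcome: dict[str, pd.DataFrame],
    *,
    B: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
    p_method: str = "z",
    conditions: tuple[str, ...] = FEATURED_CONDITIONS,
) -> list[ITSResult]:
    """Run the full ITS battery.

    ``series_by_outcome`` maps outcome labels to per-site monthly series
    frames.  Produces (a) one result per site for the primary any-MH
    outcome, (b) one pooled-across-sites result per featured condition
    group, and (c) one pooled result for the female share of MH
    hospitalizations.  Per-run seeds are derived deterministically from
    ``seed``; a failing outcome is recorded without aborting the batch.
    """
    results: list[ITSResult] = []
    ss = np.random.SeedSequence(seed)
    tasks: list[tuple[str, pd.DataFrame]] = []

    primary = series_by_outcome[ANY_MH]
    for site in sorted(primary["site_id"].unique()):
        tasks.append((f"site:{site}", primary[primary["site_id"] == site]))
    for cond in conditions:
        if cond in series_by_outcome:
            tasks.append((f"pooled:{cond}", pooled_series(series_by_outcome[cond])))
    if FEMALE_SHARE in series_by_outcome:
        tasks.append((f"pooled:{FEMALE_SHARE}", pooled_series(series_by_outcome[FEMALE_SHARE])))

    for (label, ser), child in zip(tasks, ss.spawn(len(tasks))):
        run_seed = int(child.generate_state(1)[0] % (2**31))
        try:
            results.append(
                bootstrap_its(ser, B=B, seed=run_seed, alpha=alpha, p_method=p_method)
            )
        except FitError as exc:
            logger.error("ITS failed for %s: %s", label, exc)
            site = str(ser["site_id"].iloc[0])
            outcome = str(ser["outcome"].iloc[0])
            nan = float("nan")
            results.append(
                ITSResult(
                    site_id=site,
                    outcome=outcome,
                    slope_pre=nan,
                    slope_pre_ci=(nan, nan),
                    slope_pre_p=nan,
                    slope_pandemic=nan,
                    slope_pandemic_ci=(nan, nan),
                    slope_pandemic_p=nan,
                    delta=nan,
                    ci_low=nan,
                    ci_high=nan,
                    p_delta=nan,
                    delta_boot_sd=nan,
                    B=B,
                    seed=run_seed,
                    error=str(exc),
                )
            )
    return results


def results_frame(results: list[ITSResult]) -> pd.DataFrame:
    """Tabulate ITS results, one row per site/outcome."""
    return pd.DataFrame([r.as_row() for r in results])


def expected_months() -> tuple[int, int]:
    """(prepandemic, pandemic) month counts of the full study window."""
    return N_PRE_MONTHS, N_PANDEMIC_MONTHS
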