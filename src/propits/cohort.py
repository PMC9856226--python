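"""Cohort construction: eligibility filtering, study-period assignment,
monthly proportion series, and the between-period characteristics table.

The analysis denominator is *all* adolescent hospitalizations in the study
window, mental-health–associated or not; the numerator of the primary
outcome is the subset carrying at least one mental-health diagnosis code.
Condition-group outcomes are multi-label: a hospitalization with codes in
two groups counts once in each group's numerator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .codemap import CodeMap, classify_codes
from .errors import ValidationError
from .periods import assign_period, month_period, study_months

logger = logging.getLogger(__name__)

AGE_MIN, AGE_MAX = 11, 17

#: Outcome label for the primary series (any mental-health diagnosis).
ANY_MH = "any_mh"
#: Outcome label for the sex-stratified series: share of mental-health
#: hospitalizations that are female (denominator = MH hospitalizations).
FEMALE_SHARE = "female_share_of_mh"


def filter_eligible(
    hospitalizations: pd.DataFrame,
    diagnoses: pd.DataFrame,
    codemap: CodeMap,
) -> pd.DataFrame:
    """Filter to eligible hospitalizations and annotate diagnosis groups.

    Keeps hospitalizations of 11–17-year-olds admitted inside the study
    window (both periods), whether or not they carry a mental-health code —
    non-MH hospitalizations form the proportion denominator.  Adds columns:
    ``period``, ``month`` (admission month), ``mh_flag`` and
    ``condition_groups`` (frozenset of group names).  Records with missing
    or unparseable admission dates are dropped with a warning.
    """
    df = hospitalizations.copy()
    df["admission_date"] = pd.to_datetime(df["admission_date"], errors="coerce")
    bad = df["admission_date"].isna()
    if bad.any():
        logger.warning("dropping %d records with missing admission date", int(bad.sum()))
        df = df[~bad]
    df["period"] = df["admission_date"].map(assign_period)
    df = df[df["period"] != "excluded"]
    df = df[(df["age"] >= AGE_MIN) & (df["age"] <= AGE_MAX)].copy()
    df["month"] = df["admission_date"].dt.to_period("M")

    codes_by_hosp = diagnoses.groupby("hospitalization_id")["code"].agg(list)
    groups = df["hospitalization_id"].map(
        lambda hid: classify_codes(codes_by_hosp.get(hid, []), codemap)
    )
    df["condition_groups"] = groups
    df["mh_flag"] = groups.map(bool)
    if "discharge_date" in df.columns:
        df["discharge_date"] = pd.to_datetime(df["discharge_date"], errors="coerce")
        df["length_of_stay"] = (df["discharge_date"] - df["admission_date"]).dt.days
    return df.reset_index(drop=True)


def monthly_series(records: pd.DataFrame, outcome: str) -> pd.DataFrame:
    """Per-site monthly numerator/denominator counts for one outcome.

    Returns a frame with columns ``site_id, outcome, month, period, n, k``
    covering every study month for every site present in ``records``; empty
    months are emitted with ``n = 0, k = 0`` and ``flagged = True``.

    Outcomes: ``any_mh`` (k = MH hospitalizations among all), a condition
    group name (k = hospitalizations with that group among all), or
    ``female_share_of_mh`` (n = MH hospitalizations, k = female ones).
    """
    known = {ANY_MH, FEMALE_SHARE} | _group_universe(records)
    if outcome not in known:
        raise ValidationError(f"unknown outcome label {outcome!r}")

    if outcome == FEMALE_SHARE:
        base = records[records["mh_flag"]]
        numer_mask = base["sex"] == "F"
    elif outcome == ANY_MH:
        base = records
        numer_mask = base["mh_flag"]
    else:
        base = records
        numer_mask = base["condition_groups"].map(lambda g: outcome in g)

    months = study_months()
    frame = pd.DataFrame({"site_id": base["site_id"], "month": base["month"], "hit": numer_mask.astype(int)})
    agg = frame.groupby(["site_id", "month"], observed=True)["hit"].agg(n="size", k="sum")
    sites = sorted(records["site_id"].unique())
    full = pd.MultiIndex.from_product([sites, months], names=["site_id", "month"])
    agg = agg.reindex(full, fill_value=0).reset_index()
    agg["outcome"] = outcome
    agg["period"] = agg["month"].map(month_period)
    agg["flagged"] = agg["n"] == 0
    return agg[["site_id", "outcome", "month", "period", "n", "k", "flagged"]]


def pooled_series(series: pd.DataFrame) -> pd.DataFrame:
    """Sum a per-site monthly series across sites into one pooled series."""
    pooled = (
        series.groupby(["outcome", "month", "period"], observed=True)[["n", "k"]]
        .sum()
        .reset_index()
    )
    pooled.insert(0, "site_id", "pooled")
    pooled["flagged"] = pooled["n"] == 0
    return pooled


def _group_universe(records: pd.DataFrame) -> set[str]:
    out: set[str] = set()
    for groups in records["condition_groups"]:
        out |= set(groups)
    return out


@dataclass
class CharacteristicsTable:
    """Table-1-style comparison of the MH cohort between periods."""

    summary: pd.DataFrame  # one row per characteristic with per-period values
    n_patients: dict[str, int]
    tests_skipped: bool = False

    def to_frame(self) -> pd.DataFrame:
        return self.summary


def characteristics_table(
    records: pd.DataFrame,
    *,
    per_patient: bool = True,
    los_bootstrap: int = 500,
    seed: int = 0,
) -> CharacteristicsTable:
    """Between-period comparison of the mental-health cohort.

    Unique patients are counted per period (a patient hospitalized in both
    periods contributes to both); sex and age are taken from the patient's
    first MH hospitalization in the period; condition flags are any
    diagnosis in the period.  Sex and condition prevalences are compared
    with Pearson's chi-squared test, mean age with Welch's t test, and the
    median length of stay with median (quantile) regression on a period
    indicator, whose p-value comes from a case-resampling bootstrap.

    With ``per_patient=False`` condition tallies count hospitalizations
    instead of unique patients.
    """
    mh = records[records["mh_flag"]].copy()
    rows: list[dict] = []
    periods = ("pre", "pandemic")
    firsts = {}
    n_pat = {}
    for per in periods:
        sub = mh[mh["period"] == per].sort_values("admission_date")
        firsts[per] = sub.drop_duplicates("patient_id", keep="first")
        n_pat[per] = int(sub["patient_id"].nunique())
    skipped = any(n_pat[p] == 0 for p in periods)

    rows.append(
        {"characteristic": "patients", "pre": n_pat["pre"], "pandemic": n_pat["pandemic"], "p_value": np.nan}
    )

    # Sex composition (per unique patient).
    sex_counts = {
        per: firsts[per]["sex"].value_counts().reindex(["F", "M"], fill_value=0)
        for per in periods
    }
    p_sex = np.nan
    if not skipped:
        table = np.array([[sex_counts[p]["F"], sex_counts[p]["M"]] for p in periods])
        if table.sum(axis=0).min() > 0:
            p_sex = stats.chi2_contingency(table, correction=False).pvalue
    for sex in ("F", "M"):
        rows.append(
            {
                "characteristic": f"sex_{sex}",
                "pre": int(sex_counts["pre"][sex]),
                "pre_pct": _pct(sex_counts["pre"][sex], n_pat["pre"]),
                "pandemic": int(sex_counts["pandemic"][sex]),
                "pandemic_pct": _pct(sex_counts["pandemic"][sex], n_pat["pandemic"]),
                "p_value": p_sex if sex == "F" else np.nan,
            }
        )

    # Age at first MH admission in period: mean (SD), Welch t test.
    ages = {per: firsts[per]["age"].astype(float) for per in periods}
    p_age = np.nan
    if not skipped and min(len(ages[p]) for p in periods) > 1:
        p_age = stats.ttest_ind(ages["pre"], ages["pandemic"], equal_var=False).pvalue
    rows.append(
        {
            "characteristic": "age_mean",
            "pre": float(ages["pre"].mean()) if len(ages["pre"]) else np.nan,
            "pre_sd": float(ages["pre"].std(ddof=1)) if len(ages["pre"]) > 1 else np.nan,
            "pandemic": float(ages["pandemic"].mean()) if len(ages["pandemic"]) else np.nan,
            "pandemic_sd": float(ages["pandemic"].std(ddof=1)) if len(ages["pandemic"]) > 1 else np.nan,
            "p_value": p_age,
        }
    )

    # Length of stay: median (IQR) over hospitalizations, median-regression p.
    if "length_of_stay" in mh.columns and not skipped:
        los = {per: mh.loc[mh["period"] == per, "length_of_stay"].dropna() for per in periods}
        p_los = _median_regression_p(los["pre"], los["pandemic"], los_bootstrap, seed)
        rows.append(
            {
                "characteristic": "los_median",
                "pre": float(los["pre"].median()),
                "pre_iqr_low": float(los["pre"].quantile(0.25)),
                "pre_iqr_high": float(los["pre"].quantile(0.75)),
                "pandemic": float(los["pandemic"].median()),
                "pandemic_iqr_low": float(los["pandemic"].quantile(0.25)),
                "pandemic_iqr_high": float(los["pandemic"].quantile(0.75)),
                "p_value": p_los,
            }
        )

    # Condition-group prevalence.
    universe = sorted(_group_universe(mh))
    for group in universe:
        counts = {}
        for per in periods:
            sub = mh[mh["period"] == per]
            has = sub["condition_groups"].map(lambda g: group in g)
            if per_patient:
                counts[per] = int(sub.loc[has, "patient_id"].nunique())
                denom = n_pat[per]
            else:
                counts[per] = int(has.sum())
                denom = len(sub)
            counts[per + "_denom"] = denom
        p_grp = np.nan
        if not skipped:
            table = np.array(
                [
                    [counts[p], counts[p + "_denom"] - counts[p]]
                    for p in periods
                ]
            )
            if (table.sum(axis=1) > 0).all() and table.sum(axis=0).min() > 0:
                p_grp = stats.chi2_contingency(table, correction=False).pvalue
        rows.append(
            {
                "characteristic": group,
                "pre": counts["pre"],
                "pre_pct": _pct(counts["pre"], counts["pre_denom"]),
                "pandemic": counts["pandemic"],
                "pandemic_pct": _pct(counts["pandemic"], counts["pandemic_denom"]),
                "p_value": p_grp,
            }
        )

    if skipped:
        logger.warning("a period has zero MH patients; comparison tests skipped")
    return CharacteristicsTable(pd.DataFrame(rows), n_pat, tests_skipped=skipped)


def _pct(count, denom) -> float:
    return float(100.0 * count / denom) if denom else np.nan


def _median_regression_p(pre: pd.Series, pandemic: pd.Series, n_boot: int, seed: int) -> float:
    """Median regression of LOS on a period indicator; bootstrap p-value.

    The point coefficient comes from a quantile regression at the median;
    its sampling distribution is approximated by a case-resampling
    bootstrap of the median difference, and the p-value is a
    normal-approximation z test on the bootstrap SE.
    """
    if len(pre) == 0 or len(pandemic) == 0:
        return np.nan
    import statsmodels.api as sm

    a, b = pre.to_numpy(float), pandemic.to_numpy(float)
    y = np.concatenate([a, b])
    x = sm.add_constant(np.concatenate([np.zeros(a.size), np.ones(b.size)]))
    coef = float(sm.QuantReg(y, x).fit(q=0.5).params[1])
    rng = np.random.default_rng(seed)
    draws = np.empty(n_boot)
    for i in range(n_boot):
        draws[i] = np.median(rng.choice(b, b.size)) - np.median(rng.choice(a, a.size))
    se = draws.std(ddof=1)
    if se == 0:
        return 1.0 if coef == 0 else 0.0
    z = coef / se
    return float(2.0 * stats.norm.sf(abs(z)))
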