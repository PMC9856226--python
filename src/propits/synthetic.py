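"""Synthetic multi-site hospitalization cohorts with known ground truth.

Each site is described by a :class:`SiteScenario`: a Poisson rate for total
monthly adolescent admissions, and a piecewise-linear trend for the fraction
of those admissions that carry a mental-health diagnosis.  The trend has a
prepandemic slope, plus a level shift and a slope shift that switch on at
April 2020 — the slope shift is the ground-truth analogue of the
between-period proportion difference that the ITS stage estimates.

Two sampling surfaces are provided: :func:`simulate_monthly_counts` draws
only the per-month (denominator, numerator) pairs and is the fast path used
by simulation studies, while :func:`generate_records` expands those counts
into patient-level hospitalization and diagnosis tables so the full
classification and cohort-building stack can be exercised end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError
from .periods import ONSET_INDEX, WINDOW_END, WINDOW_START, assign_period

PROP_FLOOR = 0.01
PROP_CEIL = 0.99

#: One representative diagnosis code per condition group; enough to exercise
#: the classification layer without carrying the full institutional list.
REPRESENTATIVE_CODES: dict[str, str] = {
    "Anxiety disorders": "F41.1",
    "Depressive disorders": "F32.9",
    "Suicidality or self-injury": "X84",
    "Mental health symptoms": "R45.2",
    "Trauma and stressor-related disorders": "F43.1",
    "Eating disorders": "F50.0",
    "Miscellaneous": "F48.0",
    "Disruptive, impulse control, and conduct disorders": "F91.1",
    "Substance-related and addictive disorders": "F10.1",
    "Somatic symptoms and related disorders": "F45.1",
    "Schizophrenia spectrum and other psychotic disorders": "F20.9",
    "Obsessive-compulsive and related disorders": "F42.2",
    "Bipolar and related disorders": "F31.9",
    "Sleep-wake disorders": "F51.0",
    "Personality disorders": "F60.3",
    "Dissociative disorders": "F44.8",
}

#: Non-mental-health filler codes assigned to non-flagged hospitalizations.
FILLER_CODES = ("J45.9", "S82.1", "A09", "K35.8", "E10.1", "J18.9")

#: Per-group probability of carrying each condition given a mental-health
#: hospitalization; mirrors the prevalence ranking seen in multi-site
#: adolescent inpatient cohorts (anxiety, depression and suicidality or
#: self-injury most prevalent).
DEFAULT_CONDITION_MIX: dict[str, float] = {
    "Anxiety disorders": 0.524,
    "Depressive disorders": 0.469,
    "Suicidality or self-injury": 0.423,
    "Mental health symptoms": 0.220,
    "Trauma and stressor-related disorders": 0.217,
    "Eating disorders": 0.147,
    "Miscellaneous": 0.185,
    "Disruptive, impulse control, and conduct disorders": 0.165,
    "Substance-related and addictive disorders": 0.077,
    "Somatic symptoms and related disorders": 0.044,
    "Schizophrenia spectrum and other psychotic disorders": 0.040,
    "Obsessive-compulsive and related disorders": 0.031,
    "Bipolar and related disorders": 0.039,
    "Sleep-wake disorders": 0.028,
    "Personality disorders": 0.028,
    "Dissociative disorders": 0.002,
}


@dataclass(frozen=True)
class SiteScenario:
    """Ground-truth data-generating parameters for one site.

    Proportion-trend parameters are on the fraction scale (e.g. a
    ``slope_shift`` of 0.006 is 0.6 percentage points per month).
    """

    site_id: str
    country: str
    monthly_admissions_mean: float = 350.0
    baseline_prop: float = 0.336
    slope_pre: float = 0.0
    slope_shift: float = 0.006
    level_shift: float = 0.01
    female_prob_pre: float = 0.615
    female_prob_pandemic: float = 0.685
    condition_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONDITION_MIX)
    )
    los_log_mean: float = math.log(7.0)
    los_log_sd: float = 0.75

    def __post_init__(self) -> None:
        if self.monthly_admissions_mean <= 0:
            raise ValidationError("monthly_admissions_mean must be positive")
        if not 0.0 < self.baseline_prop < 1.0:
            raise ValidationError("baseline_prop must be in (0, 1)")
        for name in ("female_prob_pre", "female_prob_pandemic"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")
        if not self.condition_mix:
            raise ValidationError("condition_mix must be nonempty")
        for group, prob in self.condition_mix.items():
            if not 0.0 <= prob <= 1.0:
                raise ValidationError(f"condition_mix[{group!r}] not in [0, 1]")


@dataclass(frozen=True)
class SyntheticConfig:
    """A reproducible multi-site generation request."""

    seed: int
    scenarios: tuple[SiteScenario, ...]
    window_start: pd.Period = WINDOW_START
    window_end: pd.Period = WINDOW_END

    def __post_init__(self) -> None:
        if not self.scenarios:
            raise ValidationError("at least one site scenario required")
        if self.window_end < self.window_start:
            raise ValidationError("window_end precedes window_start")

    @property
    def months(self) -> pd.PeriodIndex:
        return pd.period_range(self.window_start, self.window_end, freq="M")

    @property
    def onset_index(self) -> int:
        return (pd.Period("2020-04", freq="M") - self.window_start).n


def default_scenarios() -> tuple[SiteScenario, ...]:
    """Seven-site study design: five US sites and two French sites.

    Slope shifts are heterogeneous across sites (most sites show a clear
    pandemic-period acceleration, one site per country shows little or
    none), averaging roughly 0.6 percentage points per month overall.
    """
    spec = [
        ("US-A", "US", 550, 0.34, 0.009),
        ("US-B", "US", 420, 0.32, 0.008),
        ("US-C", "US", 380, 0.35, 0.0085),
        ("US-D", "US", 300, 0.33, 0.0075),
        ("US-E", "US", 260, 0.30, 0.002),
        ("FR-A", "FR", 450, 0.36, 0.006),
        ("FR-B", "FR", 280, 0.34, 0.0005),
    ]
    return tuple(
        SiteScenario(
            site_id=sid,
            country=country,
            monthly_admissions_mean=vol,
            baseline_prop=base,
            slope_shift=shift,
        )
        for sid, country, vol, base, shift in spec
    )


def uniform_scenarios(
    n_sites: int = 7,
    *,
    slope_shift: float = 0.006,
    monthly_admissions_mean: float = 2000.0,
    baseline_prop: float = 0.336,
    slope_pre: float = 0.0,
    level_shift: float = 0.01,
) -> tuple[SiteScenario, ...]:
    """Homogeneous sites sharing one true slope shift, for simulation studies."""
    return tuple(
        SiteScenario(
            site_id=f"S{i + 1:02d}",
            country="US" if i < max(1, n_sites - 2) else "FR",
            monthly_admissions_mean=monthly_admissions_mean,
            baseline_prop=baseline_prop,
            slope_pre=slope_pre,
            slope_shift=slope_shift,
            level_shift=level_shift,
        )
        for i in range(n_sites)
    )


def true_monthly_proportion(
    scenario: SiteScenario,
    month_index: int,
    *,
    n_months: int = 27,
    onset_index: int = ONSET_INDEX,
) -> float:
    """Ground-truth mental-health proportion at a month index.

    Piecewise linear: ``baseline + slope_pre*t`` before the onset month;
    from the onset month on, the level shift applies and the slope becomes
    ``slope_pre + slope_shift`` with time re-centred at onset.  The result
    is clamped to [0.01, 0.99] so binomial sampling stays nondegenerate.
    """
    if not 0 <= month_index < n_months:
        raise ValidationError(f"month index {month_index} outside window")
    t = month_index
    if t < onset_index:
        p = scenario.baseline_prop + scenario.slope_pre * t
    else:
        p_at_onset = scenario.baseline_prop + scenario.slope_pre * onset_index
        p = (
            p_at_onset
            + scenario.level_shift
            + (scenario.slope_pre + scenario.slope_shift) * (t - onset_index)
        )
    return float(min(PROP_CEIL, max(PROP_FLOOR, p)))


def true_proportion_curve(
    scenario: SiteScenario, n_months: int = 27, onset_index: int = ONSET_INDEX
) -> np.ndarray:
    """Vector of ground-truth proportions over the whole window."""
    return np.array(
        [
            true_monthly_proportion(
                scenario, t, n_months=n_months, onset_index=onset_index
            )
            for t in range(n_months)
        ]
    )


def simulate_monthly_counts(
    scenario: SiteScenario,
    rng: np.random.Generator,
    *,
    n_months: int = 27,
    onset_index: int = ONSET_INDEX,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-month (total, mental-health) admission counts for one site.

    Totals are Poisson (floored at 1 so no month has an empty denominator);
    mental-health counts are Binomial(total, true proportion).
    """
    p = true_proportion_curve(scenario, n_months, onset_index)
    n = np.maximum(1, rng.poisson(scenario.monthly_admissions_mean, size=n_months))
    k = rng.binomial(n, p)
    return n, k


def _sample_condition_groups(rng: np.random.Generator, mix: dict[str, float]):
    """Multi-label draw of condition groups; guarantees at least one group."""
    groups = [g for g, prob in mix.items() if rng.random() < prob]
    if not groups:
        names = list(mix)
        probs = np.array([mix[g] for g in names], dtype=float)
        if probs.sum() <= 0:
            raise ValidationError("condition_mix has no positive probability")
        groups = [names[rng.choice(len(names), p=probs / probs.sum())]]
    return groups


def generate_records(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate patient-level hospitalization and diagnosis tables.

    Returns ``(hospitalizations, diagnoses)``: one row per hospitalization
    (patient_id, hospitalization_id, site_id, country, admission_date,
    discharge_date, sex, age) and a long diagnosis table
    (hospitalization_id, code).  Byte-identical output for a fixed config.
    """
    rng = np.random.default_rng(config.seed)
    months = config.months
    onset = config.onset_index
    hosp_rows: list[tuple] = []
    diag_rows: list[tuple] = []
    serial = 0
    filler = list(FILLER_CODES)
    for scenario in config.scenarios:
        for t, month in enumerate(months):
            n, k = _month_counts(scenario, rng, t, len(months), onset)
            month_start = month.to_timestamp()
            days_in_month = month.days_in_month
            period = assign_period(month_start.date())
            female_p = (
                scenario.female_prob_pandemic
                if period == "pandemic"
                else scenario.female_prob_pre
            )
            for i in range(n):
                serial += 1
                is_mh = i < k
                hid = f"H{serial:07d}"
                pid = f"P{serial:07d}"
                admission = month_start + pd.Timedelta(
                    days=int(rng.integers(0, days_in_month))
                )
                los = int(np.round(rng.lognormal(scenario.los_log_mean, scenario.los_log_sd))) + 1
                age = int(rng.integers(11, 18))
                sex = "F" if rng.random() < female_p else "M"
                hosp_rows.append(
                    (
                        pid,
                        hid,
                        scenario.site_id,
                        scenario.country,
                        admission.date().isoformat(),
                        (admission + pd.Timedelta(days=los)).date().isoformat(),
                        sex,
                        age,
                    )
                )
                if is_mh:
                    for group in _sample_condition_groups(rng, scenario.condition_mix):
                        diag_rows.append((hid, REPRESENTATIVE_CODES[group]))
                else:
                    diag_rows.append((hid, filler[int(rng.integers(0, len(filler)))]))
    hosp = pd.DataFrame(
        hosp_rows,
        columns=[
            "patient_id",
            "hospitalization_id",
            "site_id",
            "country",
            "admission_date",
            "discharge_date",
            "sex",
            "age",
        ],
    )
    diag = pd.DataFrame(diag_rows, columns=["hospitalization_id", "code"])
    return hosp, diag


def _month_counts(scenario, rng, t, n_months, onset_index) -> tuple[int, int]:
    p = true_monthly_proportion(
        scenario, t, n_months=n_months, onset_index=onset_index
    )
    n = max(1, int(rng.poisson(scenario.monthly_admissions_mean)))
    k = int(rng.binomial(n, p))
    return n, k


def export_ground_truth(config: SyntheticConfig) -> pd.DataFrame:
    """True per-site trend parameters, slopes in percentage points/month."""
    rows = [
        {
            "site_id": s.site_id,
            "country": s.country,
            "slope_pre": 100.0 * s.slope_pre,
            "slope_pandemic": 100.0 * (s.slope_pre + s.slope_shift),
            "true_proportion_difference": 100.0 * s.slope_shift,
            "level_shift": 100.0 * s.level_shift,
        }
        for s in config.scenarios
    ]
    return pd.DataFrame(rows)


def with_slope_shift(scenario: SiteScenario, slope_shift: float) -> SiteScenario:
    """Copy of a scenario with a different true slope shift."""
    return replace(scenario, slope_shift=slope_shift)
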