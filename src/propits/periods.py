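"""Study-period calendar: a 14-month prepandemic window (Feb 2019 – Mar
2020) and a 13-month pandemic window (Apr 2020 – Apr 2021), with April 1,
2020 as the interruption date."""

from __future__ import annotations

import datetime as dt

import pandas as pd

from .errors import ValidationError

PRE_START = dt.date(2019, 2, 1)
PRE_END = dt.date(2020, 3, 31)
PANDEMIC_START = dt.date(2020, 4, 1)
PANDEMIC_END = dt.date(2021, 4, 30)

#: First and last calendar month of the full study window.
WINDOW_START = pd.Period("2019-02", freq="M")
WINDOW_END = pd.Period("2021-04", freq="M")

#: Month index (0-based from WINDOW_START) of the pandemic onset month.
ONSET_INDEX = (pd.Period("2020-04", freq="M") - WINDOW_START).n

N_PRE_MONTHS = 14
N_PANDEMIC_MONTHS = 13


def assign_period(date) -> str:
    """Map a calendar date to ``pre``, ``pandemic`` or ``excluded``.

    Boundaries are inclusive on both ends of each period.
    """
    if isinstance(date, str):
        try:
            date = dt.date.fromisoformat(date)
        except ValueError as exc:
            raise ValidationError(f"unparseable date {date!r}") from exc
    if isinstance(date, pd.Timestamp):
        date = date.date()
    if not isinstance(date, dt.date):
        raise ValidationError(f"not a date: {date!r}")
    if PRE_START <= date <= PRE_END:
        return "pre"
    if PANDEMIC_START <= date <= PANDEMIC_END:
        return "pandemic"
    return "excluded"


def month_period(month: pd.Period) -> str:
    """Period of a calendar month (months never straddle the boundary)."""
    return assign_period(month.to_timestamp().date())


def study_months() -> pd.PeriodIndex:
    """All 27 calendar months of the study window, in order."""
    return pd.period_range(WINDOW_START, WINDOW_END, freq="M")
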