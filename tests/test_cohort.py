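"""Cohort building: period assignment, eligibility, monthly series,
characteristics comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from propits.cohort import (
    ANY_MH,
    FEMALE_SHARE,
    characteristics_table,
    filter_eligible,
    monthly_series,
    pooled_series,
)
from propits.errors import ValidationError
from propits.periods import assign_period, study_months


class TestAssignPeriod:
    @pytest.mark.parametrize(
        "date,expected",
        [
            ("2019-02-01", "pre"),
            ("2020-03-31", "pre"),
            ("2020-04-01", "pandemic"),
            ("2021-04-30", "pandemic"),
            ("2019-01-31", "excluded"),
            ("2021-05-01", "excluded"),
        ],
    )
    def test_boundaries(self, date, expected):
        assert assign_period(date) == expected

    def test_unparseable_date(self):
        with pytest.raises(ValidationError):
            assign_period("not-a-date")

    def test_window_partition(self):
        """Every in-window date maps to exactly one period."""
        days = pd.date_range("2019-02-01", "2021-04-30", freq="D")
        periods = [assign_period(d.date()) for d in days]
        assert set(periods) == {"pre", "pandemic"}
        switch = periods.index("pandemic")
        assert all(p == "pre" for p in periods[:switch])
        assert all(p == "pandemic" for p in periods[switch:])


def _toy_inputs():
    hosp = pd.DataFrame(
        {
            "patient_id": ["P1", "P2", "P3", "P4", "P5"],
            "hospitalization_id": ["H1", "H2", "H3", "H4", "H5"],
            "site_id": "A",
            "country": "US",
            "admission_date": [
                "2019-06-15",  # eligible, MH (eating)
                "2019-06-20",  # eligible, non-MH
                "2019-06-25",  # age 10: excluded
                "2019-01-31",  # before window: excluded
                "2020-06-01",  # eligible pandemic, MH multi-group
            ],
            "discharge_date": [
                "2019-06-20",
                "2019-06-22",
                "2019-06-28",
                "2019-02-05",
                "2020-06-11",
            ],
            "sex": ["F", "M", "F", "M", "F"],
            "age": [11, 15, 10, 14, 16],
        }
    )
    diag = pd.DataFrame(
        {
            "hospitalization_id": ["H1", "H2", "H3", "H4", "H5", "H5"],
            "code": ["F50.0", "J45", "F32.9", "F41.1", "F41.1", "F32.9"],
        }
    )
    return hosp, diag


class TestFilterEligible:
    def test_filters_and_annotations(self, codemap):
        records = filter_eligible(*_toy_inputs(), codemap)
        assert set(records["hospitalization_id"]) == {"H1", "H2", "H5"}
        h1 = records.set_index("hospitalization_id").loc["H1"]
        assert h1["mh_flag"] and h1["condition_groups"] == {"Eating disorders"}
        assert h1["period"] == "pre"
        h5 = records.set_index("hospitalization_id").loc["H5"]
        assert h5["condition_groups"] == {"Anxiety disorders", "Depressive disorders"}

    def test_missing_admission_date_dropped(self, codemap):
        hosp, diag = _toy_inputs()
        hosp.loc[0, "admission_date"] = None
        records = filter_eligible(hosp, diag, codemap)
        assert "H1" not in set(records["hospitalization_id"])


class TestMonthlySeries:
    def test_counting_and_empty_months(self, codemap):
        records = filter_eligible(*_toy_inputs(), codemap)
        series = monthly_series(records, ANY_MH)
        june = series[series["month"] == pd.Period("2019-06", "M")].iloc[0]
        assert (june["n"], june["k"]) == (2, 1)
        assert len(series) == 27  # every study month emitted
        empty = series[series["month"] == pd.Period("2019-07", "M")].iloc[0]
        assert (empty["n"], empty["k"]) == (0, 0) and empty["flagged"]

    def test_multi_label_counted_in_each_group(self, codemap):
        records = filter_eligible(*_toy_inputs(), codemap)
        month = pd.Period("2020-06", "M")
        for outcome in ("Anxiety disorders", "Depressive disorders", ANY_MH):
            ser = monthly_series(records, outcome)
            assert ser.set_index("month").loc[month, "k"] == 1

    def test_female_share_denominator_is_mh(self, codemap):
        records = filter_eligible(*_toy_inputs(), codemap)
        ser = monthly_series(records, FEMALE_SHARE)
        june = ser[ser["month"] == pd.Period("2019-06", "M")].iloc[0]
        assert (june["n"], june["k"]) == (1, 1)  # only H1 is MH, female

    def test_unknown_outcome_rejected(self, codemap):
        records = filter_eligible(*_toy_inputs(), codemap)
        with pytest.raises(ValidationError):
            monthly_series(records, "no_such_outcome")

    def test_any_mh_sum_equals_total_mh_count(self, small_records):
        series = monthly_series(small_records, ANY_MH)
        assert series["k"].sum() == int(small_records["mh_flag"].sum())
        assert series["n"].sum() == len(small_records)

    def test_group_numerators_bounded_by_any_mh(self, small_records):
        any_mh = monthly_series(small_records, ANY_MH).set_index(["site_id", "month"])["k"]
        anx = monthly_series(small_records, "Anxiety disorders").set_index(
            ["site_id", "month"]
        )["k"]
        assert (anx <= any_mh).all()

    def test_pooled_series_sums_sites(self, small_records):
        per_site = monthly_series(small_records, ANY_MH)
        pooled = pooled_series(per_site)
        month = pd.Period("2019-06", "M")
        assert (
            pooled.set_index("month").loc[month, "n"]
            == per_site[per_site["month"] == month]["n"].sum()
        )
        assert len(pooled) == len(study_months())


class TestCharacteristics:
    def test_sex_chi2_matches_closed_form(self, small_records):
        """Pearson chi-squared equals the direct contingency formula."""
        table = characteristics_table(small_records, seed=0, los_bootstrap=100)
        row = table.summary.set_index("characteristic").loc["sex_F"]
        mh = small_records[small_records["mh_flag"]]
        obs = np.zeros((2, 2))
        for i, per in enumerate(["pre", "pandemic"]):
            first = (
                mh[mh["period"] == per]
                .sort_values("admission_date")
                .drop_duplicates("patient_id")
            )
            obs[i] = [(first["sex"] == "F").sum(), (first["sex"] == "M").sum()]
        expected = obs.sum(1, keepdims=True) * obs.sum(0, keepdims=True) / obs.sum()
        chi2 = ((obs - expected) ** 2 / expected).sum()
        assert row["p_value"] == pytest.approx(stats.chi2.sf(chi2, 1), rel=1e-10)

    def test_sex_percentages_sum_to_100(self, small_records):
        summary = characteristics_table(
            small_records, seed=0, los_bootstrap=100
        ).summary.set_index("characteristic")
        for col in ("pre_pct", "pandemic_pct"):
            assert summary.loc["sex_F", col] + summary.loc["sex_M", col] == pytest.approx(
                100.0, abs=0.1
            )

    def test_identical_compositions_give_p_one(self, codemap):
        hosp = pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(8)],
                "hospitalization_id": [f"H{i}" for i in range(8)],
                "site_id": "A",
                "country": "US",
                "admission_date": ["2019-06-15"] * 4 + ["2020-06-15"] * 4,
                "discharge_date": ["2019-06-20"] * 4 + ["2020-06-20"] * 4,
                "sex": ["F", "F", "M", "M"] * 2,
                "age": [14] * 8,
            }
        )
        diag = pd.DataFrame(
            {"hospitalization_id": [f"H{i}" for i in range(8)], "code": "F41.1"}
        )
        records = filter_eligible(hosp, diag, codemap)
        summary = characteristics_table(
            records, seed=0, los_bootstrap=50
        ).summary.set_index("characteristic")
        assert summary.loc["sex_F", "p_value"] == pytest.approx(1.0)

    def test_empty_period_skips_tests(self, codemap):
        hosp, diag = _toy_inputs()
        hosp = hosp[hosp["admission_date"] < "2020-01-01"]
        records = filter_eligible(hosp, diag, codemap)
        table = characteristics_table(records, seed=0, los_bootstrap=50)
        assert table.tests_skipped

    def test_per_hospitalization_switch(self, small_records):
        pp = characteristics_table(
            small_records, per_patient=True, seed=0, los_bootstrap=50
        ).summary.set_index("characteristic")
        ph = characteristics_table(
            small_records, per_patient=False, seed=0, los_bootstrap=50
        ).summary.set_index("characteristic")
        # hospitalization counts can only exceed unique-patient counts
        assert ph.loc["Anxiety disorders", "pre"] >= pp.loc["Anxiety disorders", "pre"]
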