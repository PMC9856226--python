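import numpy as np
import pandas as pd
import pytest

from propits.codemap import load_codemap
from propits.synthetic import SiteScenario, SyntheticConfig, generate_records


@pytest.fixture(scope="session")
def codemap():
    return load_codemap("default")


@pytest.fixture(scope="session")
def small_config():
    """Two small sites (one per country) over the full study window."""
    scenarios = (
        SiteScenario(
            site_id="US-X",
            country="US",
            monthly_admissions_mean=60,
            baseline_prop=0.34,
            slope_shift=0.008,
        ),
        SiteScenario(
            site_id="FR-X",
            country="FR",
            monthly_admissions_mean=40,
            baseline_prop=0.36,
            slope_shift=0.003,
        ),
    )
    return SyntheticConfig(seed=20190201, scenarios=scenarios)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_records(small_config)


@pytest.fixture(scope="session")
def small_records(small_cohort, codemap):
    from propits.cohort import filter_eligible

    hosp, diag = small_cohort
    return filter_eligible(hosp, diag, codemap)


def make_series(n, k, site_id="S01", outcome="any_mh"):
    """Monthly-series frame over the full 27-month window from count arrays."""
    n = np.asarray(n)
    k = np.asarray(k)
    months = pd.period_range("2019-02", periods=n.size, freq="M")
    period = (["pre"] * 14 + ["pandemic"] * 13)[: n.size]
    return pd.DataFrame(
        {
            "site_id": site_id,
            "outcome": outcome,
            "month": months,
            "period": period,
            "n": n,
            "k": k,
        }
    )
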