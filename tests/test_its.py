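"""ITS estimation: trend fits, the proportion-difference statistic, and
parametric-bootstrap inference."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from propits.cohort import ANY_MH, FEMALE_SHARE, monthly_series
from propits.errors import FitError
from propits.its import (
    ITSResult,
    bootstrap_its,
    fit_period_trend,
    proportion_difference,
    results_frame,
    run_all_its,
)

from conftest import make_series


class TestTrendFit:
    def test_exact_line(self):
        fit = fit_period_trend([0, 1, 2], [10.0, 20.0, 30.0], "pre")
        assert fit.slope == pytest.approx(10.0)
        assert fit.intercept == pytest.approx(10.0)

    def test_constant_series_has_zero_slope(self):
        fit = fit_period_trend(np.arange(14), np.full(14, 33.6), "pre")
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        """Closed-form slope equals a generic least-squares solve."""
        rng = np.random.default_rng(123)
        for _ in range(100):
            t = np.arange(13, dtype=float)
            y = rng.uniform(0, 100, size=13)
            coef, *_ = np.linalg.lstsq(np.column_stack([np.ones_like(t), t]), y, rcond=None)
            fit = fit_period_trend(t, y)
            assert fit.slope == pytest.approx(coef[1], abs=1e-9)
            assert fit.intercept == pytest.approx(coef[0], abs=1e-9)

    def test_too_few_months_rejected(self):
        with pytest.raises(FitError):
            fit_period_trend([0, 1], [1.0, 2.0], "pandemic")

    @pytest.mark.parametrize(
        "pre,pan,expected", [(0.0, 0.6, 0.6), (0.5, 0.5, 0.0), (0.2, -0.1, -0.3)]
    )
    def test_proportion_difference_sign_convention(self, pre, pan, expected):
        from propits.its import PeriodFit

        f = lambda s, p: PeriodFit(p, s, 0.0, 14)
        assert proportion_difference(f(pre, "pre"), f(pan, "pandemic")) == pytest.approx(
            expected
        )


class TestBootstrap:
    def test_degenerate_all_zero_numerators(self):
        series = make_series(np.full(27, 50), np.zeros(27, dtype=int))
        res = bootstrap_its(series, B=200, seed=1)
        assert res.delta == 0.0
        assert (res.ci_low, res.ci_high) == (0.0, 0.0)
        assert np.isnan(res.p_delta)  # zero-variance bootstrap distribution

    def test_bit_reproducible_for_fixed_seed(self):
        rng = np.random.default_rng(5)
        n = rng.integers(50, 150, 27)
        k = rng.binomial(n, 0.35)
        r1 = bootstrap_its(make_series(n, k), B=500, seed=99)
        r2 = bootstrap_its(make_series(n, k), B=500, seed=99)
        assert r1 == r2

    def test_point_estimate_equals_unresampled_fit(self):
        rng = np.random.default_rng(6)
        n = rng.integers(50, 150, 27)
        k = rng.binomial(n, 0.35)
        res = bootstrap_its(make_series(n, k), B=200, seed=0)
        p = 100.0 * k / n
        fit_pre = fit_period_trend(np.arange(14), p[:14], "pre")
        fit_pan = fit_period_trend(np.arange(13), p[14:], "pandemic")
        assert res.delta == pytest.approx(proportion_difference(fit_pre, fit_pan))

    def test_level_shift_leaves_delta_unchanged(self):
        """Adding a constant to every month's proportion shifts levels only."""
        n = np.full(27, 1000)
        k = (n * 0.30).astype(int)
        k2 = (n * 0.40).astype(int)  # +10 points everywhere
        r1 = bootstrap_its(make_series(n, k), B=100, seed=3)
        r2 = bootstrap_its(make_series(n, k2), B=100, seed=3)
        assert r1.delta == pytest.approx(r2.delta, abs=1e-9)

    def test_period_swap_negates_delta(self):
        rng = np.random.default_rng(8)
        n = rng.integers(100, 200, 27)
        k = rng.binomial(n, 0.35)
        r = bootstrap_its(make_series(n, k), B=100, seed=0)
        p = 100.0 * k / n
        f_pan_as_pre = fit_period_trend(np.arange(13), p[14:], "pre")
        f_pre_as_pan = fit_period_trend(np.arange(14), p[:14], "pandemic")
        assert proportion_difference(f_pan_as_pre, f_pre_as_pan) == pytest.approx(-r.delta)

    def test_ci_width_scales_with_binomial_variance(self):
        """Doubling every denominator shrinks the CI width by about 1/sqrt(2)."""
        n = np.full(27, 400)
        p_true = np.concatenate([np.full(14, 0.33), np.full(13, 0.37)])
        k = (n * p_true).astype(int)
        r1 = bootstrap_its(make_series(n, k), B=20_000, seed=11)
        r2 = bootstrap_its(make_series(2 * n, 2 * k), B=20_000, seed=11)
        w1 = r1.ci_high - r1.ci_low
        w2 = r2.ci_high - r2.ci_low
        assert w2 / w1 == pytest.approx(1 / np.sqrt(2), rel=0.05)

    def test_zero_denominator_months_excluded(self):
        n = np.full(27, 100)
        n[5] = 0
        k = (n * 0.3).astype(int)
        res = bootstrap_its(make_series(n, k), B=100, seed=0)
        assert np.isfinite(res.delta)

    def test_percentile_p_method(self):
        rng = np.random.default_rng(13)
        n = rng.integers(100, 200, 27)
        k = rng.binomial(n, 0.35)
        res = bootstrap_its(make_series(n, k), B=500, seed=0, p_method="percentile")
        assert 0.0 <= res.p_delta <= 1.0


@given(shift=st.floats(-0.5, 0.5), seed=st.integers(0, 2**20))
@settings(max_examples=25, deadline=None)
def test_ci_always_ordered_and_contains_structure(shift, seed):
    """Bootstrap CI limits are ordered for arbitrary shifts and seeds."""
    rng = np.random.default_rng(seed)
    n = rng.integers(50, 300, 27)
    p = np.clip(0.3 + shift * np.linspace(0, 1, 27), 0.01, 0.99)
    k = rng.binomial(n, p)
    res = bootstrap_its(make_series(n, k), B=200, seed=seed)
    assert res.ci_low <= res.ci_high
    assert np.isfinite(res.delta) and np.isfinite(res.delta_boot_sd)


class TestRunAll:
    def test_output_cardinality_and_pooling(self, small_records):
        outcomes = [ANY_MH, "Anxiety disorders", "Depressive disorders",
                    "Suicidality or self-injury", "Eating disorders", FEMALE_SHARE]
        series = {o: monthly_series(small_records, o) for o in outcomes}
        results = run_all_its(series, B=200, seed=1)
        sites = {r.site_id for r in results if r.outcome == ANY_MH}
        assert sites == {"US-X", "FR-X"}
        pooled = [r for r in results if r.site_id == "pooled"]
        assert len(pooled) == 5  # 4 conditions + female share
        assert len(results) == 7
        frame = results_frame(results)
        assert {"site_id", "outcome", "delta", "delta_ci_low", "delta_ci_high"} <= set(
            frame.columns
        )

    def test_failures_do_not_abort_batch(self):
        # one site with too few usable months
        n = np.zeros(27, dtype=int)
        n[:2] = 10
        bad = make_series(n, np.zeros(27, dtype=int), site_id="BAD")
        good_n = np.full(27, 100)
        good = make_series(good_n, (good_n * 0.3).astype(int), site_id="GOOD")
        series = {ANY_MH: pd.concat([bad, good], ignore_index=True)}
        results = run_all_its(series, B=100, seed=0)
        by_site = {r.site_id: r for r in results}
        assert by_site["BAD"].error is not None
        assert by_site["GOOD"].error is None
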