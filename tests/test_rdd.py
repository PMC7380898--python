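"""RDD estimators: exact recovery, estimator agreement, invariances, lags."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rddmatch import (
    SynthConfig,
    differential_effect,
    fit_local_linear_rdd,
    fit_parametric_rdd,
    generate_panel,
    results_table,
    scan_lag,
)
from conftest import linear_series, make_series


@pytest.fixture(scope="module")
def noisy_series():
    panel = generate_panel(SynthConfig(n_treated=10, n_control_pool=120, seed=21))
    return panel.outcome_series("views", panel.control_ids())


class TestParametric:
    def test_continuous_line_has_zero_jump(self):
        fit = fit_parametric_rdd(linear_series(1.0, 2.0, 0.0, 6), 6)
        assert fit.estimate == pytest.approx(0.0, abs=1e-9)

    def test_exact_jump_recovered(self):
        fit = fit_parametric_rdd(linear_series(1.0, 2.0, 5.0, 6), 6)
        assert fit.estimate == pytest.approx(5.0, abs=1e-9)
        assert fit.left_limit == pytest.approx(1.0, abs=1e-9)
        assert fit.right_limit == pytest.approx(6.0, abs=1e-9)
        assert fit.p_value == pytest.approx(0.0)  # zero residuals, nonzero jump

    def test_quadratic_trend_needs_order_two(self):
        series = make_series(
            {t: (t - 6) ** 2 + (3.0 if t >= 6 else 0.0) for t in range(1, 12)}
        )
        fit = fit_parametric_rdd(series, 6, polynomial_order=2)
        assert fit.estimate == pytest.approx(3.0, abs=1e-8)

    def test_insufficient_months_named_side(self):
        series = make_series({t: float(t) for t in (5, 6, 7, 8)})
        with pytest.raises(ValueError, match="left side.*1 distinct"):
            fit_parametric_rdd(series, 6, polynomial_order=1)

    def test_estimate_is_limit_difference(self, noisy_series):
        fit = fit_parametric_rdd(noisy_series, 6)
        assert fit.estimate == pytest.approx(
            fit.right_limit - fit.left_limit, rel=1e-12
        )


class TestLocalLinear:
    @pytest.mark.parametrize("bandwidth", [2.5, 3.0, 5.0])
    @pytest.mark.parametrize("kernel", ["triangular", "uniform", "epanechnikov"])
    def test_exact_on_piecewise_linear(self, bandwidth, kernel):
        fit = fit_local_linear_rdd(
            linear_series(2.0, -1.5, 5.0, 6), 6,
            bandwidth_months=bandwidth, kernel=kernel,
        )
        assert fit.estimate == pytest.approx(5.0, abs=1e-8)

    def test_bandwidth_too_small_reports_minimum(self):
        series = linear_series(0.0, 1.0, 2.0, 6)
        with pytest.raises(ValueError, match="minimal feasible bandwidth"):
            fit_local_linear_rdd(series, 6, bandwidth_months=1.5)

    def test_unknown_kernel_rejected(self, noisy_series):
        with pytest.raises(ValueError, match="kernel"):
            fit_local_linear_rdd(noisy_series, 6, kernel="gaussianish")

    def test_full_width_uniform_equals_parametric_order_one(self, noisy_series):
        """With a uniform kernel spanning every month, the local-linear fit is
        the same regression as the global order-1 fit."""
        par = fit_parametric_rdd(noisy_series, 6, polynomial_order=1)
        loc = fit_local_linear_rdd(
            noisy_series, 6, bandwidth_months=10.0, kernel="uniform"
        )
        assert loc.estimate == pytest.approx(par.estimate, rel=1e-8)
        assert loc.std_error == pytest.approx(par.std_error, rel=1e-8)
        assert loc.left_limit == pytest.approx(par.left_limit, rel=1e-8)


class TestInvariances:
    @given(st.floats(-1e4, 1e4), st.floats(0.1, 100.0))
    @settings(deadline=None, derandomize=True, max_examples=20)
    def test_translation_and_scale(self, shift, scale):
        panel = generate_panel(SynthConfig(n_treated=8, n_control_pool=60, seed=3))
        series = panel.outcome_series("patients", panel.control_ids())
        base = fit_parametric_rdd(series, 6)
        moved = series.assign(value=series["value"] * scale + shift)
        fit = fit_parametric_rdd(moved, 6)
        assert fit.estimate == pytest.approx(scale * base.estimate, rel=1e-9)
        assert fit.std_error == pytest.approx(scale * base.std_error, rel=1e-9)


class TestDifferential:
    def test_simple_subtraction(self):
        t = fit_parametric_rdd(linear_series(0.0, 1.0, 5.0, 6), 6, group="treated")
        c = fit_parametric_rdd(linear_series(0.0, 1.0, 2.0, 6), 6, group="control")
        d = differential_effect(t, c)
        assert d.estimate == pytest.approx(3.0, abs=1e-9)

    def test_identical_fits_cancel_with_root_two_se(self, noisy_series):
        fit = fit_parametric_rdd(noisy_series, 6)
        d = differential_effect(fit, fit)
        assert d.estimate == 0.0
        assert d.std_error == pytest.approx(np.sqrt(2.0) * fit.std_error, rel=1e-12)

    def test_mismatch_rejected(self, noisy_series):
        a = fit_parametric_rdd(noisy_series, 6, outcome="views")
        b = fit_parametric_rdd(noisy_series, 6, outcome="patients")
        with pytest.raises(ValueError, match="outcome mismatch"):
            differential_effect(a, b)
        c = fit_local_linear_rdd(noisy_series, 6, outcome="views")
        with pytest.raises(ValueError, match="method mismatch"):
            differential_effect(a, c)


class TestScanLag:
    def test_noiseless_lagged_jump_found_exactly(self):
        # a tiny deterministic physician-by-month ripple keeps the
        # cluster-robust SEs positive without materially moving the jump
        series = make_series(
            {t: 1.0 + 0.5 * t + (4.0 if t >= 7 else 0.0) for t in range(1, 12)},
            n_physicians=4,
        )
        idx = series["physician_id"].str.slice(1).astype(int)
        series["value"] += 0.01 * np.sin(3.0 * idx + series["month_index"])
        fits, best = scan_lag(series, 6, max_lag=3)
        assert best == 1
        assert len(fits) == 4
        assert fits[1].estimate == pytest.approx(4.0, abs=0.05)

    def test_out_of_range_lag_rejected(self):
        series = make_series({t: float(t) for t in range(1, 12)})
        with pytest.raises(ValueError, match="max_lag"):
            scan_lag(series, 6, max_lag=5)

    def test_profile_is_auditable(self, noisy_series):
        fits, best = scan_lag(noisy_series, 6, max_lag=2, method="nonparametric")
        assert [f.cutoff_index for f in fits] == [6, 7, 8]
        zs = [abs(f.estimate) / f.std_error for f in fits]
        assert zs[best] == max(zs)


def test_results_table_mirrors_fit_cells(noisy_series):
    fits = [
        fit_parametric_rdd(noisy_series, 6, group="control", outcome="views"),
        fit_local_linear_rdd(noisy_series, 6, group="control", outcome="views"),
    ]
    table = results_table(fits)
    assert list(table.columns) == [
        "outcome", "group", "method", "estimate", "std_error", "n_obs", "p_value"
    ]
    assert table.loc[0, "estimate"] == fits[0].estimate
    assert table.loc[1, "method"] == "nonparametric"
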