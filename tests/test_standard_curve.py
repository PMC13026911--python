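"""Standard-curve fitting, efficiency, outlier screening, linearity, bands."""

import math
import warnings

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from qpcrcurve import simulate
from qpcrcurve.standard_curve import (
    CalibrationPoint,
    acceptance_check,
    efficiency_ci,
    efficiency_from_slope,
    fit_standard_curve,
    grubbs_test,
    linearity_test,
    outlier_flags,
    points_from_table,
    slope_from_efficiency,
    standardized_residuals,
    working_hotelling_band,
)

from conftest import PERFECT_SLOPE


def _fit_quiet(points, **kw):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return fit_standard_curve(points, **kw)


class TestFit:
    def test_exact_line_recovered(self, exact_line_points):
        fit = _fit_quiet(exact_line_points)
        assert fit.slope_k == pytest.approx(PERFECT_SLOPE, abs=1e-10)
        assert fit.intercept_m == pytest.approx(34.0, abs=1e-10)
        assert fit.fit_se == pytest.approx(0.0, abs=1e-9)
        assert abs(fit.residuals.sum()) < 1e-8 * fit.n_points
        assert fit.efficiency == pytest.approx(1.0, abs=1e-10)

    def test_matches_independent_normal_equations(self, rng):
        x = rng.uniform(0, 7, 30)
        y = -3.4 * x + 33.0 + rng.normal(0, 0.3, 30)
        pts = [CalibrationPoint(xi, yi) for xi, yi in zip(x, y)]
        fit = _fit_quiet(pts)
        sm_fit = sm.OLS(y, sm.add_constant(x)).fit()
        assert fit.slope_k == pytest.approx(sm_fit.params[1], abs=1e-10)
        assert fit.intercept_m == pytest.approx(sm_fit.params[0], abs=1e-10)
        assert fit.se_slope == pytest.approx(sm_fit.bse[1], abs=1e-10)
        assert fit.se_intercept == pytest.approx(sm_fit.bse[0], abs=1e-10)
        assert fit.fit_se == pytest.approx(
            math.sqrt(sm_fit.mse_resid), abs=1e-10
        )

    def test_two_points_rejected(self):
        pts = [CalibrationPoint(0.0, 34.0), CalibrationPoint(3.0, 24.0)]
        with pytest.raises(ValueError, match=">= 3"):
            fit_standard_curve(pts)

    def test_single_level_rejected(self):
        pts = [CalibrationPoint(2.0, 27.0 + d, "L1", str(i))
               for i, d in enumerate((0.0, 0.1, -0.1))]
        with pytest.raises(ValueError, match="degenerate"):
            fit_standard_curve(pts)

    def test_thin_design_warns(self, exact_line_points):
        with pytest.warns(UserWarning, match="thin calibration design"):
            fit_standard_curve(exact_line_points)

    def test_nonfinite_cq_rejected_at_point_construction(self):
        with pytest.raises(ValueError):
            CalibrationPoint(1.0, float("nan"))

    def test_slope_recovered_within_ci(self):
        # simulated series: true slope inside its own 95% CI in >=90/100 seeds
        hits = 0
        true_k = slope_from_efficiency(0.95)
        for seed in range(100):
            cfg = simulate.SimulationConfig.from_dilution(
                1e7, 6, 10.0, sigma_tech=0.2, efficiency=0.95, seed=seed,
                replicates_per_level=3,
            )
            pts = points_from_table(simulate.simulate_dilution_series(cfg))
            fit = _fit_quiet(pts)
            lo, hi = fit.slope_ci
            hits += lo <= true_k <= hi
        assert hits >= 90


class TestEfficiency:
    @pytest.mark.parametrize(
        "k, expected",
        [(-3.33, 0.997), (-3.42, 0.961), (-3.50, 0.931)],
    )
    def test_printed_slopes(self, k, expected):
        assert round(efficiency_from_slope(k), 3) == expected

    def test_perfect_doubling_slope(self):
        assert efficiency_from_slope(-1 / math.log10(2)) == pytest.approx(
            1.0, abs=1e-12
        )

    @pytest.mark.parametrize("k", [0.0, 1.2])
    def test_rejects_nonnegative_slope(self, k):
        with pytest.raises(ValueError):
            efficiency_from_slope(k)

    @settings(derandomize=True, max_examples=60)
    @given(e=st.floats(min_value=0.3, max_value=1.0))
    def test_slope_efficiency_roundtrip(self, e):
        assert efficiency_from_slope(slope_from_efficiency(e)) == pytest.approx(
            e, abs=1e-12
        )

    def test_zero_se_gives_zero_width_ci(self, exact_line_points):
        fit = _fit_quiet(exact_line_points)
        lo, hi = efficiency_ci(fit)
        assert lo == pytest.approx(hi, abs=1e-9)
        assert lo == pytest.approx(fit.efficiency, abs=1e-9)

    def test_ci_covers_true_efficiency(self):
        # ~95% coverage over simulated curves (3-SE binomial tolerance)
        hits = 0
        n_sim = 500
        for seed in range(n_sim):
            cfg = simulate.SimulationConfig.from_dilution(
                1e7, 6, 10.0, sigma_tech=0.2, efficiency=0.95,
                seed=seed, replicates_per_level=4,
            )
            pts = points_from_table(simulate.simulate_dilution_series(cfg))
            lo, hi = _fit_quiet(pts).efficiency_ci
            hits += lo <= 0.95 <= hi
        tol = 3 * math.sqrt(0.95 * 0.05 / n_sim)
        assert abs(hits / n_sim - 0.95) < tol


class TestResidualScreening:
    def test_exact_line_all_zero_no_flags(self, exact_line_points):
        fit = _fit_quiet(exact_line_points)
        assert np.allclose(standardized_residuals(fit), 0.0)
        assert outlier_flags(fit).size == 0

    def test_injected_outlier_flagged(self):
        flagged = 0
        for seed in range(100):
            cfg = simulate.SimulationConfig.from_dilution(
                1e8, 6, 10.0, sigma_tech=0.2, efficiency=0.95, seed=seed,
                replicates_per_level=6, outliers=((2, 1, 1.2),),  # gross, +6 sigma
            )
            table = simulate.simulate_dilution_series(cfg)
            pts = points_from_table(table)
            fit = _fit_quiet(pts)
            idx = outlier_flags(fit)
            target = next(
                i for i, p in enumerate(pts)
                if p.level_id == "L03" and p.replicate_id == "1"
            )
            flagged += list(idx) == [target]
        assert flagged >= 95

class TestGrubbs:
    def test_flags_extreme_point(self):
        res = grubbs_test([0.1, -0.2, 0.05, -0.1, 4.0])
        assert res.outlier_index == 4
        # published two-sided critical value for n=5, alpha=0.05
        assert res.critical_value == pytest.approx(1.715, abs=0.005)

    def test_symmetric_residuals_pass(self, rng):
        res = grubbs_test(rng.normal(0, 1, 30) * 0.1)
        assert res.statistic < res.critical_value or res.outlier_index is None

    def test_constant_residuals_report_none(self):
        res = grubbs_test([0.5, 0.5, 0.5, 0.5])
        assert res.outlier_index is None
        assert math.isnan(res.statistic)

    def test_too_few_residuals(self):
        with pytest.raises(ValueError):
            grubbs_test([0.1, 0.2])


class TestLinearity:
    def test_quadratic_term_near_zero_on_exact_line(self, exact_line_points):
        report = linearity_test(exact_line_points)
        # a perfect line leaves nothing for higher-order terms
        assert report.max_deviation_pct < 1e-8

    def test_insufficient_levels(self):
        pts = [CalibrationPoint(float(i), 34.0 - 3.3 * i) for i in range(4)]
        with pytest.raises(ValueError, match=">= 5"):
            linearity_test(pts)

    def test_top_level_bias_detected(self):
        cfg = simulate.SimulationConfig.from_dilution(
            1e8, 6, 10.0, sigma_tech=0.15, efficiency=0.95, seed=11,
            replicates_per_level=4,
        )
        table = simulate.inject_curvature(
            simulate.simulate_dilution_series(cfg), 0.5
        )
        report = linearity_test(points_from_table(table))
        assert report.p_quadratic < 0.05
        assert not report.passes_linear


class TestWorkingHotelling:
    def test_band_geometry(self, rng):
        x = rng.uniform(0, 6, 24)
        y = -3.4 * x + 33.0 + rng.normal(0, 0.25, 24)
        fit = _fit_quiet([CalibrationPoint(a, b) for a, b in zip(x, y)])
        grid = np.linspace(-1, 8, 181)
        lo_c, hi_c = working_hotelling_band(fit, grid, "confidence")
        half = (hi_c - lo_c) / 2
        # narrowest at the design centroid
        assert abs(grid[half.argmin()] - fit.mean_log10) < 0.06
        lo_p, hi_p = working_hotelling_band(fit, grid, "prediction", b=2)
        assert np.all(hi_p - lo_p > hi_c - lo_c)
        # direct recomputation from sufficient statistics
        mult = math.sqrt(2 * stats.f.ppf(0.95, 2, fit.df))
        h = 1 / fit.n_points + (grid - fit.mean_log10) ** 2 / fit.sxx
        assert np.allclose(half, mult * fit.fit_se * np.sqrt(h), atol=1e-10)

    def test_empty_grid(self, exact_line_points):
        fit = _fit_quiet(exact_line_points)
        lo, hi = working_hotelling_band(fit, [])
        assert lo.size == 0 and hi.size == 0

    def test_pointwise_band_is_narrower(self, rng):
        x = rng.uniform(0, 6, 24)
        y = -3.4 * x + 33.0 + rng.normal(0, 0.25, 24)
        fit = _fit_quiet([CalibrationPoint(a, b) for a, b in zip(x, y)])
        grid = np.linspace(0, 6, 20)
        lo_s, hi_s = working_hotelling_band(fit, grid, simultaneous=True)
        lo_t, hi_t = working_hotelling_band(fit, grid, simultaneous=False)
        assert np.all(hi_t - lo_t < hi_s - lo_s)


class TestAcceptance:
    def _fake_fit(self, e, lo, hi, exact_line_points):
        fit = _fit_quiet(exact_line_points)
        object.__setattr__(fit, "efficiency", e)
        object.__setattr__(fit, "efficiency_ci", (lo, hi))
        return fit

    def test_good_curve_passes(self, exact_line_points):
        v = acceptance_check(self._fake_fit(0.997, 0.977, 1.017, exact_line_points))
        assert v.accepted and not v.reasons

    def test_lower_ci_above_one_fails(self, exact_line_points):
        v = acceptance_check(self._fake_fit(1.05, 1.02, 1.08, exact_line_points))
        assert not v.accepted
        assert any("100%" in r for r in v.reasons)

    def test_low_efficiency_wide_ci_warns_but_passes(self, exact_line_points):
        v = acceptance_check(self._fake_fit(0.894, 0.800, 0.988, exact_line_points))
        assert v.accepted
        assert any("below" in w for w in v.warnings)
        assert any("wide" in w for w in v.warnings)

    def test_estimate_above_one_ci_spanning_warns(self, exact_line_points):
        v = acceptance_check(self._fake_fit(1.02, 0.98, 1.06, exact_line_points))
        assert v.accepted
        assert any("encompasses 100%" in w for w in v.warnings)


def test_removing_flagged_outlier_never_widens_efficiency_ci():
    for seed in range(20):
        cfg = simulate.SimulationConfig.from_dilution(
            1e7, 6, 10.0, sigma_tech=0.2, efficiency=0.95, seed=seed,
            replicates_per_level=3, outliers=((0, 1, 2.5),),
        )
        pts = points_from_table(simulate.simulate_dilution_series(cfg))
        fit = _fit_quiet(pts)
        flagged = outlier_flags(fit)
        if flagged.size == 0:
            continue
        kept = [p for i, p in enumerate(pts) if i not in set(flagged)]
        refit = _fit_quiet(kept)
        w0 = fit.efficiency_ci[1] - fit.efficiency_ci[0]
        w1 = refit.efficiency_ci[1] - refit.efficiency_ci[0]
        assert w1 <= w0 + 1e-12
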