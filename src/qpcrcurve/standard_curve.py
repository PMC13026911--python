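"""Standard-curve fitting and validation.

The calibration model is ordinary least squares of Cq on log10 starting
copies,

    Cq(N) = k * log10(N) + m

with slope k (cycles per decade; -3.32 at perfect doubling), intercept m
(the Cq of a single double-stranded target molecule), and PCR efficiency

    E = 10**(-1/k) - 1.

Validation follows routine qPCR practice: the efficiency CI from the
delta-method SE, standardized residuals with a +-3 screening rule, a
single-pass two-sided Grubbs test on the pooled residuals, nested
polynomial F-tests against quadratic and cubic alternatives for the linear
dynamic range, Working-Hotelling simultaneous confidence/prediction bands,
and the efficiency acceptance rule (reject when the lower CI bound of E
exceeds 100 %, which signals points outside the linear range tilting the
fit).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationPoint",
    "StandardCurveFit",
    "LinearityReport",
    "GrubbsResult",
    "AcceptanceVerdict",
    "fit_standard_curve",
    "efficiency_from_slope",
    "slope_from_efficiency",
    "efficiency_ci",
    "standardized_residuals",
    "outlier_flags",
    "grubbs_test",
    "linearity_test",
    "working_hotelling_band",
    "acceptance_check",
    "points_from_table",
]

RECOMMENDED_LEVELS = 9
RECOMMENDED_REPLICATES = 4


@dataclass(frozen=True)
class CalibrationPoint:
    """One positive calibration reaction: log10 copies and its Cq."""

    log10_copies: float
    cq: float
    level_id: str = ""
    replicate_id: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.cq):
            raise ValueError(
                f"cq must be finite (negative reactions are excluded before "
                f"fitting), got {self.cq!r} at level {self.level_id!r}"
            )
        if not math.isfinite(self.log10_copies):
            raise ValueError("log10_copies must be finite")


def points_from_table(table) -> list[CalibrationPoint]:
    """Build calibration points from a reaction table (see qpcrcurve.io).

    Negative reactions (NaN Cq) are dropped; copies are converted to log10.
    """
    pts = []
    for row in table.itertuples(index=False):
        if row.cq is None or (isinstance(row.cq, float) and math.isnan(row.cq)):
            continue
        pts.append(
            CalibrationPoint(
                log10_copies=math.log10(row.copies),
                cq=float(row.cq),
                level_id=str(row.level_id),
                replicate_id=str(row.replicate),
            )
        )
    return pts


def efficiency_from_slope(k: float) -> float:
    """PCR efficiency from the standard-curve slope: E = 10**(-1/k) - 1."""
    if k >= 0:
        raise ValueError(
            f"slope must be negative for an amplification curve, got {k!r}"
        )
    return 10.0 ** (-1.0 / k) - 1.0


def slope_from_efficiency(efficiency: float) -> float:
    """Inverse of :func:`efficiency_from_slope`: k = -1/log10(1+E)."""
    if efficiency <= 0:
        raise ValueError("efficiency must be > 0")
    return -1.0 / math.log10(1.0 + efficiency)


@dataclass(frozen=True)
class StandardCurveFit:
    """OLS regression state with the sufficient statistics used downstream."""

    slope_k: float
    intercept_m: float
    se_slope: float
    se_intercept: float
    fit_se: float  # SEy.x, residual standard error
    n_points: int
    df: int
    mean_cq: float
    mean_log10: float
    sxx: float  # sum((log10 Ni - mean)^2)
    efficiency: float
    efficiency_se: float
    efficiency_ci: tuple[float, float]
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    ci_level: float
    residuals: np.ndarray
    x: np.ndarray
    y: np.ndarray
    replicate_mode: str = "raw"  # "raw" or "mean" (replicate-averaged input)

    @property
    def calibration_range(self) -> tuple[float, float]:
        return float(self.x.min()), float(self.x.max())

    def predict_cq(self, log10_copies) -> np.ndarray:
        return self.slope_k * np.asarray(log10_copies, float) + self.intercept_m


def _ols_sufficient(x: np.ndarray, y: np.ndarray):
    n = len(x)
    mx, my = float(x.mean()), float(y.mean())
    sxx = float(np.sum((x - mx) ** 2))
    sxy = float(np.sum((x - mx) * (y - my)))
    k = sxy / sxx
    m = my - k * mx
    resid = y - (k * x + m)
    df = n - 2
    rss = float(np.sum(resid**2))
    se2 = rss / df if df > 0 else float("nan")
    return k, m, resid, mx, my, sxx, df, math.sqrt(se2) if df > 0 else 0.0


def fit_standard_curve(
    points: Iterable[CalibrationPoint],
    ci_level: float = 0.95,
    replicate_mode: str = "raw",
) -> StandardCurveFit:
    """Fit Cq = k*log10(N) + m by OLS with Student-t CIs at ``ci_level``.

    Requires at least 3 points over at least 2 distinct levels (df >= 1).
    Emits a non-fatal warning when the design is thinner than the
    method-development recommendation of 9 levels x 4 replicates.
    """
    pts = list(points)
    if not 0.0 < ci_level < 1.0:
        raise ValueError("ci_level must be in (0, 1)")
    if replicate_mode not in ("raw", "mean"):
        raise ValueError("replicate_mode must be 'raw' or 'mean'")
    x = np.array([p.log10_copies for p in pts], dtype=float)
    y = np.array([p.cq for p in pts], dtype=float)
    n_levels = len(np.unique(x))
    if n_levels < 2:
        raise ValueError(
            f"degenerate design: need >= 2 distinct concentration levels, "
            f"got {n_levels}"
        )
    if len(pts) < 3:
        raise ValueError(
            f"need >= 3 calibration points (df = n - 2 >= 1), got {len(pts)}"
        )
    reps_per_level = len(pts) / n_levels
    if n_levels < RECOMMENDED_LEVELS or reps_per_level < RECOMMENDED_REPLICATES:
        warnings.warn(
            f"thin calibration design ({n_levels} levels, "
            f"~{reps_per_level:.1f} replicates/level); method development "
            f"recommends >= {RECOMMENDED_LEVELS} levels x "
            f">= {RECOMMENDED_REPLICATES} replicates",
            UserWarning,
            stacklevel=2,
        )
    k, m, resid, mx, my, sxx, df, fit_se = _ols_sufficient(x, y)
    se_k = fit_se / math.sqrt(sxx)
    se_m = fit_se * math.sqrt(1.0 / len(pts) + mx**2 / sxx)
    tcrit = float(stats.t.ppf(0.5 + ci_level / 2.0, df))
    eff = efficiency_from_slope(k) if k < 0 else float("nan")
    # delta method: dE/dk = (1+E) ln10 / k^2
    se_eff = se_k * (1.0 + eff) * math.log(10.0) / k**2 if k < 0 else float("nan")
    return StandardCurveFit(
        slope_k=k,
        intercept_m=m,
        se_slope=se_k,
        se_intercept=se_m,
        fit_se=fit_se,
        n_points=len(pts),
        df=df,
        mean_cq=my,
        mean_log10=mx,
        sxx=sxx,
        efficiency=eff,
        efficiency_se=se_eff,
        efficiency_ci=(eff - tcrit * se_eff, eff + tcrit * se_eff),
        slope_ci=(k - tcrit * se_k, k + tcrit * se_k),
        intercept_ci=(m - tcrit * se_m, m + tcrit * se_m),
        ci_level=ci_level,
        residuals=resid,
        x=x,
        y=y,
        replicate_mode=replicate_mode,
    )


def efficiency_ci(
    fit: StandardCurveFit, ci_level: float | None = None
) -> tuple[float, float]:
    """Student-t CI for E at ``ci_level`` (defaults to the fit's level).

    SE(E) = SE(k) * (1+E) * ln(10) / k**2 (delta method), CI with df = n-2.
    """
    if fit.df < 1:
        raise ValueError("efficiency CI needs df >= 1")
    if ci_level is None:
        return fit.efficiency_ci
    tcrit = float(stats.t.ppf(0.5 + ci_level / 2.0, fit.df))
    return (
        fit.efficiency - tcrit * fit.efficiency_se,
        fit.efficiency + tcrit * fit.efficiency_se,
    )


def standardized_residuals(fit: StandardCurveFit) -> np.ndarray:
    """Residuals scaled by the residual SD (zeros when the fit is exact)."""
    # an exact line leaves only float rounding noise in the residuals
    if fit.fit_se <= 1e-8 * max(1.0, abs(fit.mean_cq)):
        return np.zeros_like(fit.residuals)
    return fit.residuals / fit.fit_se


def outlier_flags(fit: StandardCurveFit, bound: float = 3.0) -> np.ndarray:
    """Indices of points whose standardized residual falls outside +-bound."""
    r = standardized_residuals(fit)
    return np.flatnonzero(np.abs(r) > bound)


@dataclass(frozen=True)
class GrubbsResult:
    outlier_index: int | None
    statistic: float
    critical_value: float
    alpha: float


def grubbs_test(residuals: Sequence[float], alpha: float = 0.05) -> GrubbsResult:
    """Single-pass two-sided Grubbs test for one outlier among residuals.

    G = max|r - rbar| / s, compared to the standard t-based critical value.
    Iterative removal is deliberately not performed.  Zero-variance input
    yields no outlier (statistic undefined, reported as NaN).
    """
    r = np.asarray(residuals, dtype=float)
    n = len(r)
    if n < 3:
        raise ValueError(f"Grubbs test needs >= 3 residuals, got {n}")
    s = r.std(ddof=1)
    if s == 0:
        return GrubbsResult(None, float("nan"), float("nan"), alpha)
    dev = np.abs(r - r.mean())
    idx = int(np.argmax(dev))
    g = float(dev[idx] / s)
    t2 = float(stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)) ** 2
    crit = (n - 1) / math.sqrt(n) * math.sqrt(t2 / (n - 2 + t2))
    return GrubbsResult(idx if g > crit else None, g, crit, alpha)


@dataclass(frozen=True)
class LinearityReport:
    passes_linear: bool
    p_quadratic: float
    p_cubic: float
    max_deviation_pct: float
    alpha: float
    notes: str = ""


def _poly_rss(x: np.ndarray, y: np.ndarray, degree: int) -> tuple[float, np.ndarray]:
    X = np.vander(x, degree + 1)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(np.sum((y - X @ beta) ** 2)), X @ beta


def _nested_f(rss0: float, rss1: float, extra: int, df1: int) -> float:
    if rss1 <= 0 or df1 <= 0:
        return float("nan")
    f = (rss0 - rss1) / extra / (rss1 / df1)
    return float(stats.f.sf(max(f, 0.0), extra, df1))


def linearity_test(
    points: Iterable[CalibrationPoint], alpha: float = 0.05
) -> LinearityReport:
    """Nested-model F-tests of the straight line against quadratic and cubic.

    ``passes_linear`` requires both higher-order terms to be non-significant
    at ``alpha``.  ``max_deviation_pct`` is the allowable-deviation check:
    the largest relative difference (linear scale) between concentrations
    back-calculated through the cubic fit and through the straight line; a
    value below 0.20 is the usual bar for accepting a slightly curved curve.
    """
    pts = list(points)
    x = np.array([p.log10_copies for p in pts], dtype=float)
    y = np.array([p.cq for p in pts], dtype=float)
    n_levels = len(np.unique(x))
    if n_levels < 5:
        raise ValueError(
            f"linearity test needs >= 5 distinct levels for the cubic fit, "
            f"got {n_levels}"
        )
    n = len(x)
    rss1, yhat1 = _poly_rss(x, y, 1)
    rss2, _ = _poly_rss(x, y, 2)
    rss3, yhat3 = _poly_rss(x, y, 3)
    p_quad = _nested_f(rss1, rss2, 1, n - 3)
    p_cub = _nested_f(rss1, rss3, 2, n - 4)
    # back-calculated concentration ratio between cubic and linear fits at
    # each level: d(log10 N) = d(Cq)/k, deviation = 10**dlog - 1
    k = np.polyfit(x, y, 1)[0]
    dlog = (yhat3 - yhat1) / k
    max_dev = float(np.max(np.abs(10.0**dlog - 1.0)))
    passes = (p_quad > alpha) and (p_cub > alpha)
    notes = ""
    if not passes and max_dev < 0.20:
        notes = (
            "polynomial test significant but allowable deviation from "
            "linearity < 20%; curve would typically still be accepted"
        )
    return LinearityReport(
        passes_linear=passes,
        p_quadratic=p_quad,
        p_cubic=p_cub,
        max_deviation_pct=max_dev,
        alpha=alpha,
        notes=notes,
    )


def working_hotelling_band(
    fit: StandardCurveFit,
    x_grid: Sequence[float],
    kind: str = "confidence",
    b: int = 1,
    simultaneous: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Working-Hotelling band around the fitted line over ``x_grid``.

    Half-width = sqrt(2 F(ci; 2, n-2)) * SEy.x * sqrt(h(x)) with leverage
    h(x) = 1/n + (x - xbar)^2/Sxx for the confidence band; the prediction
    band adds 1/b for a test sample averaged over b replicates.  With
    ``simultaneous=False`` the multiplier is the pointwise t quantile.
    """
    if kind not in ("confidence", "prediction"):
        raise ValueError("kind must be 'confidence' or 'prediction'")
    if kind == "prediction" and b < 1:
        raise ValueError("b must be >= 1 for a prediction band")
    g = np.asarray(x_grid, dtype=float)
    if g.size == 0:
        return np.array([]), np.array([])
    h = 1.0 / fit.n_points + (g - fit.mean_log10) ** 2 / fit.sxx
    if kind == "prediction":
        h = h + 1.0 / b
    if simultaneous:
        mult = math.sqrt(2.0 * stats.f.ppf(fit.ci_level, 2, fit.df))
    else:
        mult = float(stats.t.ppf(0.5 + fit.ci_level / 2.0, fit.df))
    half = mult * fit.fit_se * np.sqrt(h)
    center = fit.predict_cq(g)
    return center - half, center + half


@dataclass(frozen=True)
class AcceptanceVerdict:
    accepted: bool
    warnings: tuple[str, ...]
    reasons: tuple[str, ...]


def acceptance_check(
    fit: StandardCurveFit, low_efficiency_bound: float = 0.90
) -> AcceptanceVerdict:
    """Efficiency-based acceptance rule for a fitted curve.

    Fails when the lower CI bound of E exceeds 1.0 (true efficiency cannot
    exceed 100 %; such an estimate indicates points outside the linear
    range).  Warns when the point estimate exceeds 1.0 but the CI spans it,
    and when E falls below the common 90 % expectation.
    """
    lo, hi = fit.efficiency_ci
    reasons: list[str] = []
    warns: list[str] = []
    if lo > 1.0:
        reasons.append(
            f"lower CI bound of efficiency ({lo:.3f}) exceeds 100%: "
            "likely concentrations outside the linear dynamic range"
        )
    elif fit.efficiency > 1.0:
        warns.append(
            f"efficiency point estimate {fit.efficiency:.3f} > 100% but its "
            f"CI [{lo:.3f}, {hi:.3f}] encompasses 100%"
        )
    if fit.efficiency < low_efficiency_bound:
        warns.append(
            f"efficiency {fit.efficiency:.3f} below the common "
            f"{low_efficiency_bound:.0%} expectation"
        )
    ci_width = hi - lo
    if ci_width > 0.15:
        warns.append(
            f"efficiency CI is wide ({ci_width:.3f}); the CI width is a "
            "more meaningful quality indicator than the point estimate"
        )
    return AcceptanceVerdict(
        accepted=not reasons, warnings=tuple(warns), reasons=tuple(reasons)
    )
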