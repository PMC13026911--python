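"""Inverse prediction of test-sample concentrations from a standard curve.

Given a fitted calibration line Cq = k log10(N) + m, the concentration of a
test sample measured at Cq (averaged over b replicates) is

    log10(N) = (Cq - m) / k

with standard error

    SE(log10 N) = (SEy.x / |k|) * sqrt(1/b + 1/n + (Cq - Cqbar)^2 / (k^2 Sxx))

which combines the test measurement, the intercept and the slope
uncertainties; precision is highest at the centroid of the calibration
design and grows toward the edges.  The CI is Student-t with the
calibration fit's n - 2 degrees of freedom, symmetric on the log scale and
asymmetric (skewed upward) after back-transforming to copies.  Relative
errors are reported as 100 * CI width / point estimate on each scale.

Run QC follows the common +-1 cycle rule: a quality-control sample passes
when its measured Cq deviates from the curve at its nominal concentration
by at most one cycle (roughly 50-100 % relative error in linear scale).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .standard_curve import StandardCurveFit

__all__ = [
    "Prediction",
    "QcVerdict",
    "predict_log_n",
    "prediction_se",
    "prediction_ci",
    "predict_samples",
    "relative_error_pct",
    "qc_check",
]


@dataclass(frozen=True)
class Prediction:
    """Back-calculated concentration of one test sample with uncertainty."""

    sample_id: str
    cq_mean: float
    b: int
    log10_n: float
    se_log10: float
    ci_log10: tuple[float, float]
    n_linear: float
    ci_linear: tuple[float, float]
    re_log_pct: float
    re_linear_pct: float
    extrapolated: bool = False


def predict_log_n(fit: StandardCurveFit, cq: float) -> float:
    """Point estimate log10(N) = (Cq - m)/k; warns outside the fitted range."""
    if fit.slope_k == 0:
        raise ValueError("slope is zero: the curve carries no concentration information")
    log_n = (cq - fit.intercept_m) / fit.slope_k
    lo, hi = fit.calibration_range
    if not lo <= log_n <= hi:
        warnings.warn(
            f"predicted log10(N) = {log_n:.3f} lies outside the calibrated "
            f"interval [{lo:.3f}, {hi:.3f}] (extrapolation)",
            UserWarning,
            stacklevel=2,
        )
    return log_n


def prediction_se(fit: StandardCurveFit, cq: float, b: int = 1) -> float:
    """Inverse-prediction SE of log10(N) for a Cq averaged over b replicates."""
    if b < 1:
        raise ValueError(f"b (test replicates averaged) must be >= 1, got {b}")
    if fit.df < 1:
        raise ValueError("prediction SE needs df >= 1")
    k = fit.slope_k
    h = 1.0 / b + 1.0 / fit.n_points + (cq - fit.mean_cq) ** 2 / (k * k * fit.sxx)
    return fit.fit_se / abs(k) * math.sqrt(h)


def relative_error_pct(point: float, lo: float, hi: float) -> float:
    """RE = 100 * (CI width) / point estimate, on whichever scale given."""
    if point == 0:
        raise ValueError("relative error undefined at a zero point estimate")
    return 100.0 * (hi - lo) / point


def prediction_ci(
    fit: StandardCurveFit,
    cq,
    b: int | None = None,
    ci_level: float = 0.95,
    sample_id: str = "",
) -> Prediction:
    """Full inverse prediction for one test sample.

    ``cq`` may be a scalar (already averaged; set ``b`` to the number of
    replicates averaged, default 1) or a sequence of replicate Cq values,
    which are averaged internally with b inferred — this keeps the b in the
    SE formula consistent with the averaging actually applied.
    """
    cq_arr = np.atleast_1d(np.asarray(cq, dtype=float))
    if cq_arr.size > 1:
        if b is not None and b != cq_arr.size:
            raise ValueError(
                f"b={b} conflicts with {cq_arr.size} replicate Cq values"
            )
        b_eff = cq_arr.size
    else:
        b_eff = 1 if b is None else b
    if fit.replicate_mode == "mean" and b_eff > 1:
        warnings.warn(
            "calibrators were replicate-averaged before fitting but the test "
            "sample averages b > 1 replicates; calibration and test samples "
            "should be analyzed and averaged the same way",
            UserWarning,
            stacklevel=2,
        )
    cq_mean = float(cq_arr.mean())
    log_n = predict_log_n(fit, cq_mean)
    lo_cal, hi_cal = fit.calibration_range
    extrapolated = not lo_cal <= log_n <= hi_cal
    se = prediction_se(fit, cq_mean, b_eff)
    tcrit = float(stats.t.ppf(0.5 + ci_level / 2.0, fit.df))
    lo, hi = log_n - tcrit * se, log_n + tcrit * se
    n_lin = 10.0**log_n
    lo_lin, hi_lin = 10.0**lo, 10.0**hi
    return Prediction(
        sample_id=sample_id,
        cq_mean=cq_mean,
        b=b_eff,
        log10_n=log_n,
        se_log10=se,
        ci_log10=(lo, hi),
        n_linear=n_lin,
        ci_linear=(lo_lin, hi_lin),
        re_log_pct=relative_error_pct(log_n, lo, hi) if log_n != 0 else math.inf,
        re_linear_pct=relative_error_pct(n_lin, lo_lin, hi_lin),
        extrapolated=extrapolated,
    )


def predict_samples(
    fit: StandardCurveFit,
    samples: dict[str, Sequence[float]],
    ci_level: float = 0.95,
) -> list[Prediction]:
    """Predict several test samples, each given as replicate Cq values."""
    return [
        prediction_ci(fit, cqs, ci_level=ci_level, sample_id=sid)
        for sid, cqs in samples.items()
    ]


@dataclass(frozen=True)
class QcVerdict:
    sample_id: str
    nominal_copies: float
    cq_measured: float
    cq_expected: float
    delta_cq: float
    passed: bool
    outside_range: bool


def qc_check(
    fit: StandardCurveFit,
    qc_samples: Iterable[tuple[str, float, float]],
    max_delta_cq: float = 1.0,
) -> tuple[bool, list[QcVerdict]]:
    """Run-level QC against the +-1 cycle accuracy rule.

    ``qc_samples`` yields (sample_id, nominal_copies, measured_cq).  Each
    QC passes iff |measured Cq - curve Cq at nominal| <= ``max_delta_cq``;
    the run passes iff all QCs pass.  Nominals outside the calibrated
    range are flagged but still evaluated.  Fewer than two QC levels draws
    a warning (high and low QC levels are the accepted minimum).
    """
    verdicts = []
    for sid, nominal, cq in qc_samples:
        if nominal <= 0:
            raise ValueError(f"QC nominal copies must be > 0, got {nominal}")
        log_n = math.log10(nominal)
        expected = float(fit.predict_cq(log_n))
        delta = cq - expected
        lo, hi = fit.calibration_range
        verdicts.append(
            QcVerdict(
                sample_id=sid,
                nominal_copies=nominal,
                cq_measured=cq,
                cq_expected=expected,
                delta_cq=delta,
                passed=abs(delta) <= max_delta_cq,
                outside_range=not lo <= log_n <= hi,
            )
        )
    if len({v.nominal_copies for v in verdicts}) < 2:
        warnings.warn(
            "fewer than two QC concentration levels; at least a high and a "
            "low QC sample are recommended per run",
            UserWarning,
            stacklevel=2,
        )
    return all(v.passed for v in verdicts), verdicts
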