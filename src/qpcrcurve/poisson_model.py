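"""Poisson aliquoting model for qPCR replicates.

When an aliquot is pipetted from a well-mixed sample whose expected target
count per aliquot volume is N, the actual count x in the aliquot is
Poisson(N).  Aliquots with x = 0 are qPCR-negative; positive aliquots report

    Cq(x) = m - log10(x) / log10(1 + E)

so Cq varies across replicates even without any measurement noise.  This
module gives the closed-form consequences: occupancy probabilities, the
theoretical limit of detection (the N at which 95 % of aliquots are
positive, -ln(0.05) ~= 3 molecules), the SD of Cq over the zero-truncated
Poisson distribution, the linear-scale RSD(N) curve it implies (a hump that
peaks at a few molecules per aliquot and decays ~ 1/sqrt(N ln(1+E))), and the
theoretical limit of quantification where that curve falls back to a chosen
RSD criterion (26 molecules at the common 25 % criterion with E = 1).

Truncated moments are evaluated by direct enumeration of x from 1 to the
smallest cutoff at which the Poisson tail mass is below 1e-12, renormalised
by 1 - exp(-N); this is exact to tolerance and free of sampling noise.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats

from .scale_convert import cq_sd_to_linear_rsd

__all__ = [
    "PoissonSpec",
    "TheoreticalPrecisionCurve",
    "poisson_pmf",
    "prob_positive",
    "theoretical_lod",
    "truncated_cq_sd",
    "theoretical_rsd",
    "rsd_curve_maximum",
    "theoretical_loq",
    "invert_rsd",
    "LoqResult",
]

_TAIL_MASS = 1e-12


@dataclass(frozen=True)
class PoissonSpec:
    """Expected copies per aliquot N and PCR efficiency E."""

    expected_copies: float
    efficiency: float = 1.0

    def __post_init__(self) -> None:
        if self.expected_copies < 0:
            raise ValueError("expected_copies must be >= 0")
        if not 0.0 < self.efficiency <= 1.0:
            raise ValueError("efficiency must be in (0, 1]")


def poisson_pmf(x: int, n_expected: float) -> float:
    """P(aliquot contains exactly x targets) = exp(-N) N^x / x!.

    ``x`` must be a nonnegative integer; ``n_expected`` (N) >= 0.
    """
    if isinstance(x, (bool,)) or not float(x).is_integer():
        raise ValueError(f"x must be a nonnegative integer, got {x!r}")
    x = int(x)
    if x < 0:
        raise ValueError(f"x must be a nonnegative integer, got {x!r}")
    if n_expected < 0:
        raise ValueError(f"N must be >= 0, got {n_expected!r}")
    if n_expected == 0:
        return 1.0 if x == 0 else 0.0
    return float(stats.poisson.pmf(x, n_expected))


def prob_positive(n_expected: float) -> float:
    """P(x > 0) = 1 - exp(-N): probability an aliquot is qPCR-positive."""
    if n_expected < 0:
        raise ValueError(f"N must be >= 0, got {n_expected!r}")
    return -math.expm1(-n_expected)


def theoretical_lod(confidence: float = 0.95) -> float:
    """Expected copies per aliquot at which a fraction ``confidence`` of
    aliquots is positive: N = -ln(1 - confidence) (~2.996 at 95 %)."""
    if not 0.0 < confidence < 1.0:
        raise ValueError(f"confidence must be in (0, 1), got {confidence!r}")
    return -math.log1p(-confidence)


def _truncation_cutoff(n_expected: float) -> int:
    """Smallest x_max with Poisson tail mass P(x > x_max) < 1e-12."""
    hi = int(max(20, n_expected + 12.0 * math.sqrt(n_expected) + 20))
    # sf is monotone decreasing in x; expand if the guess is short
    while stats.poisson.sf(hi, n_expected) >= _TAIL_MASS:
        hi *= 2
    lo = int(n_expected)
    while hi - lo > 1:
        mid = (hi + lo) // 2
        if stats.poisson.sf(mid, n_expected) < _TAIL_MASS:
            hi = mid
        else:
            lo = mid
    return hi


_ASYMPTOTIC_N = 1e5


def _truncated_log_moments(n_expected: float) -> tuple[float, float]:
    """Mean and variance of ln(x) for x ~ Poisson(N) conditioned on x > 0."""
    if n_expected > _ASYMPTOTIC_N:
        # truncation is immaterial here; delta-method series, relative
        # error < 1e-9 at the switch point
        n = n_expected
        return math.log(n) - 0.5 / n, 1.0 / n + 1.5 / (n * n)
    cutoff = _truncation_cutoff(n_expected)
    x = np.arange(1, cutoff + 1, dtype=float)
    log_w = x * math.log(n_expected) - n_expected - special.gammaln(x + 1.0)
    w = np.exp(log_w) / -math.expm1(-n_expected)
    v = np.log(x)
    mean = float(np.sum(w * v))
    var = float(np.sum(w * (v - mean) ** 2))
    return mean, var


def truncated_cq_sd(n_expected: float, efficiency: float = 1.0) -> float:
    """SD of Cq (cycles) over positive aliquots, from aliquoting alone.

    Cq(x) = m - log10(x)/log10(1+E) for x ~ Poisson(N) truncated at x > 0;
    the intercept m cancels, so the result is SD(ln x) / ln(1 + E).
    """
    if n_expected <= 0:
        raise ValueError(
            "N must be > 0: an all-negative level carries no Cq values"
        )
    if not 0.0 < efficiency <= 1.0:
        raise ValueError("efficiency must be in (0, 1]")
    _, var = _truncated_log_moments(n_expected)
    return math.sqrt(var) / math.log1p(efficiency)


def theoretical_rsd(n_expected: float, efficiency: float = 1.0) -> float:
    """Linear-scale RSD (fraction) implied by aliquoting uncertainty alone."""
    return cq_sd_to_linear_rsd(
        truncated_cq_sd(n_expected, efficiency), efficiency
    )


@dataclass(frozen=True)
class TheoreticalPrecisionCurve:
    """RSD(N) evaluated on a grid, for plotting and inversion diagnostics."""

    grid: np.ndarray
    rsd: np.ndarray
    efficiency: float

    @classmethod
    def on_grid(
        cls, grid: Sequence[float], efficiency: float = 1.0
    ) -> "TheoreticalPrecisionCurve":
        g = np.asarray(grid, dtype=float)
        if g.ndim != 1 or len(g) < 2 or np.any(np.diff(g) <= 0):
            raise ValueError("grid must be a strictly increasing 1-d sequence")
        if np.any(g <= 0):
            raise ValueError("grid values must be > 0")
        r = np.array([theoretical_rsd(n, efficiency) for n in g])
        return cls(grid=g, rsd=r, efficiency=efficiency)


@functools.lru_cache(maxsize=64)
def rsd_curve_maximum(efficiency: float = 1.0) -> tuple[float, float]:
    """Location and height of the single interior maximum of RSD(N).

    Returns ``(n_at_max, rsd_max)``.  The hump always sits at a few
    molecules per aliquot (bracketed in (0.1, 50)).
    """
    res = optimize.minimize_scalar(
        lambda n: -theoretical_rsd(n, efficiency),
        bounds=(0.1, 50.0),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x), float(-res.fun)


@dataclass(frozen=True)
class LoqResult:
    """Theoretical LOQ: the RSD-criterion crossing on the decreasing branch."""

    n_real: float
    n_int: int
    rsd_threshold: float
    efficiency: float
    crossed: bool = True
    note: str = ""


_N_UPPER = 1e12  # beyond any practical per-reaction copy number


def theoretical_loq(
    rsd_threshold: float = 0.25, efficiency: float = 1.0
) -> LoqResult:
    """Smallest N on the decreasing branch of RSD(N) with RSD <= threshold.

    Found by bracketing and bisection to |dN| < 1e-6.  ``n_int`` is the
    smallest integer N satisfying the criterion (26 at the 25 % criterion
    with E = 1).  A threshold at or above the curve maximum has no crossing.
    """
    n_max, rsd_max = rsd_curve_maximum(efficiency)
    if not 0.0 < rsd_threshold < rsd_max:
        return LoqResult(
            n_real=math.nan,
            n_int=-1,
            rsd_threshold=rsd_threshold,
            efficiency=efficiency,
            crossed=False,
            note=(
                f"no crossing: threshold {rsd_threshold} is outside "
                f"(0, {rsd_max:.4f}), the attainable RSD range"
            ),
        )
    root = optimize.brentq(
        lambda n: theoretical_rsd(n, efficiency) - rsd_threshold,
        n_max,
        _N_UPPER,
        xtol=1e-6,
    )
    n_int = math.ceil(root - 1e-9)
    if theoretical_rsd(n_int, efficiency) > rsd_threshold:  # guard rounding
        n_int += 1
    return LoqResult(
        n_real=float(root),
        n_int=int(n_int),
        rsd_threshold=rsd_threshold,
        efficiency=efficiency,
    )


def invert_rsd(
    rsd: float, efficiency: float = 1.0, branch: str = "high"
) -> float:
    """Solve theoretical_rsd(N, E) = rsd on one branch of the hump.

    ``branch`` is ``"high"`` (decreasing branch, all replicates positive)
    or ``"low"`` (increasing branch, negatives expected).  Bisection to
    |dN| < 1e-6.  Raises ``ValueError`` when ``rsd`` exceeds the curve
    maximum (inconsistent with Poisson-only variation) or is too small to
    be reached within the supported range.
    """
    if branch not in ("low", "high"):
        raise ValueError(f"branch must be 'low' or 'high', got {branch!r}")
    n_max, rsd_max = rsd_curve_maximum(efficiency)
    if rsd > rsd_max:
        raise ValueError(
            f"observed RSD {rsd:.4f} exceeds the Poisson-only maximum "
            f"{rsd_max:.4f} at E={efficiency}: inconsistent with "
            "aliquoting-only variation"
        )
    if rsd <= 0:
        raise ValueError("rsd must be > 0 for a finite inversion")
    f = lambda n: theoretical_rsd(n, efficiency) - rsd
    if branch == "high":
        if f(_N_UPPER) > 0:
            raise ValueError(
                f"RSD {rsd:.3g} not reached below N={_N_UPPER:g}: "
                "above the quantifiable-by-variance range"
            )
        return float(optimize.brentq(f, n_max, _N_UPPER, xtol=1e-6))
    lo = 1e-9
    if f(lo) > 0:
        raise ValueError(
            f"RSD {rsd:.3g} not reached on the low branch above N={lo:g}"
        )
    return float(optimize.brentq(f, lo, n_max, xtol=1e-6))
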