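"""Conversion between Cq-scale imprecision and linear-scale relative SD.

qPCR measures concentration on a logarithmic scale: one cycle corresponds to
a factor (1 + E) in target amount, where E is the PCR efficiency.  A standard
deviation of the quantification cycle, SD(Cq) in cycles, therefore maps to a
relative standard deviation (coefficient of variation) of the concentration
on the linear scale.  Treating the back-calculated concentration as
log-scale-normal with spread SD(Cq) cycles at base (1 + E), the linear RSD is

    RSD = sqrt((1 + E)**(SD(Cq)**2) - 1)

which is the form that reproduces the published truncated-Poisson precision
tables (e.g. SD(Cq) at N = 16 expected copies, E = 1 converts to RSD 0.327)
and places the 25 %-RSD quantification limit at 26 copies.  The map is a
bijection of [0, inf) onto [0, inf) at every efficiency, with exact inverse

    SD(Cq) = sqrt(log1p(RSD**2) / ln(1 + E)).

RSD values are fractions throughout; multiply by 100 only when formatting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "PrecisionValue",
    "cq_sd_to_linear_rsd",
    "linear_rsd_to_cq_sd",
]


def _check_efficiency(efficiency: float) -> None:
    if not 0.0 < efficiency <= 1.0:
        raise ValueError(
            f"efficiency must be in (0, 1], got {efficiency!r}"
        )


def cq_sd_to_linear_rsd(sd_cq: float, efficiency: float) -> float:
    """Convert an SD of Cq values (cycles) to a linear-scale RSD (fraction).

    Parameters
    ----------
    sd_cq : float
        Standard deviation of replicate Cq values, in cycles. Must be >= 0.
    efficiency : float
        PCR efficiency E in (0, 1]; E = 1 means perfect doubling per cycle.

    Returns
    -------
    float
        Relative standard deviation of the concentration on the linear
        scale, as a fraction (0.25 means 25 %).
    """
    _check_efficiency(efficiency)
    if sd_cq < 0:
        raise ValueError(f"sd_cq must be >= 0, got {sd_cq!r}")
    # expm1 keeps precision for small sd_cq
    return math.sqrt(math.expm1(sd_cq * sd_cq * math.log1p(efficiency)))


def linear_rsd_to_cq_sd(rsd: float, efficiency: float) -> float:
    """Exact inverse of :func:`cq_sd_to_linear_rsd`.

    Parameters
    ----------
    rsd : float
        Linear-scale relative standard deviation (fraction), >= 0.
    efficiency : float
        PCR efficiency E in (0, 1].
    """
    _check_efficiency(efficiency)
    if rsd < 0:
        raise ValueError(f"rsd must be >= 0, got {rsd!r}")
    return math.sqrt(math.log1p(rsd * rsd) / math.log1p(efficiency))


@dataclass(frozen=True)
class PrecisionValue:
    """A matched pair of Cq-scale and linear-scale imprecision at one E."""

    sd_cq: float
    rsd_linear: float
    efficiency: float

    @classmethod
    def from_sd_cq(cls, sd_cq: float, efficiency: float) -> "PrecisionValue":
        return cls(sd_cq, cq_sd_to_linear_rsd(sd_cq, efficiency), efficiency)

    @classmethod
    def from_rsd(cls, rsd: float, efficiency: float) -> "PrecisionValue":
        return cls(linear_rsd_to_cq_sd(rsd, efficiency), rsd, efficiency)
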