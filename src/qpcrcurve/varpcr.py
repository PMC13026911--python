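"""Variance PCR: absolute copy number from replicate Cq variation.

At low template loads the dominant source of Cq variation across replicate
aliquots is Poisson variation in the number of target molecules per
aliquot.  The theoretical linear-scale RSD as a function of the expected
copies N (see ``poisson_model``) is a hump: it rises as negatives appear
and falls as 1/sqrt(N ln(1+E)) at high N.  Inverting that curve at the
observed RSD of replicate Cq values therefore estimates N directly,
without a standard curve — the varPCR principle.

The same RSD occurs at one N on each side of the hump; the ambiguity is
resolved by the presence of negative replicates: negatives place the level
on the low branch, an all-positive set of replicates on the high branch.
On the low branch the classical occupancy (dPCR-style) estimator
N = -ln(fraction negative) is also available and is the more precise
choice; ``combined_estimate`` switches between the two, which extends the
dynamic range of absolute quantification beyond where either works alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from . import poisson_model
from .scale_convert import cq_sd_to_linear_rsd

__all__ = [
    "VarPcrEstimate",
    "OccupancyEstimate",
    "CombinedEstimate",
    "varpcr_estimate",
    "varpcr_from_negatives",
    "combined_estimate",
]

MIN_REPLICATES = 8


@dataclass(frozen=True)
class VarPcrEstimate:
    """Copy-number estimate from Cq variance with its branch and CI."""

    n_hat: float
    branch: str  # "low" | "high"
    sd_cq_observed: float
    rsd_observed: float
    negative_fraction: float
    ci: tuple[float, float]
    n_replicates: int
    efficiency: float


@dataclass(frozen=True)
class OccupancyEstimate:
    """dPCR-style occupancy estimate N = -ln(negative fraction)."""

    n_hat: float
    ci: tuple[float, float]
    negative_fraction: float
    n_replicates: int


def _split(cqs) -> tuple[np.ndarray, int, int]:
    """Return positive Cq values, replicate count, negative count.

    ``cqs`` is a sequence of Cq values where NaN (or None) marks a
    negative reaction.
    """
    arr = np.asarray(
        [math.nan if c is None else float(c) for c in cqs], dtype=float
    )
    pos = arr[np.isfinite(arr)]
    return pos, len(arr), int(len(arr) - len(pos))


def _point_estimate(
    pos: np.ndarray,
    n_neg: int,
    efficiency: float,
    sigma_tech: float = 0.0,
    branch: str | None = None,
):
    sd = float(np.std(pos, ddof=1))
    if sigma_tech > 0.0:
        # experimental: remove known technical Cq noise in quadrature
        if sd <= sigma_tech:
            raise ValueError(
                f"observed SD(Cq) {sd:.4f} does not exceed the stated "
                f"technical noise {sigma_tech:.4f}; nothing attributable "
                "to aliquoting remains"
            )
        sd = math.sqrt(sd * sd - sigma_tech * sigma_tech)
    rsd = cq_sd_to_linear_rsd(sd, efficiency)
    if branch is None:
        branch = "low" if n_neg > 0 else "high"
    if rsd == 0:
        raise ValueError(
            "observed RSD is 0: no finite Poisson-consistent solution "
            "(above the quantifiable-by-variance range)"
        )
    n_hat = poisson_model.invert_rsd(rsd, efficiency, branch=branch)
    return n_hat, branch, sd, rsd


def varpcr_estimate(
    cqs,
    efficiency: float = 1.0,
    n_boot: int = 2000,
    seed: int | None = None,
    sigma_tech: float = 0.0,
    branch: str | None = None,
) -> VarPcrEstimate:
    """Estimate expected copies per aliquot from replicate Cq variance.

    The SD of the positive Cq values converts to a linear-scale RSD, which
    is inverted through the theoretical Poisson RSD(N) curve by bisection
    (|dN| < 1e-6).  By default the branch is low iff any replicate was
    negative; ``branch`` overrides that rule (the combined estimator uses
    this, since a tiny negative fraction still implies the high branch).
    The CI is a seeded nonparametric percentile bootstrap over replicate
    reactions (negatives included; the chosen branch is kept fixed across
    resamples).

    ``sigma_tech`` (experimental) subtracts a known technical Cq noise in
    quadrature on the Cq scale before conversion; by default no correction
    is applied, so technical noise inflates the RSD and biases the estimate
    downward on the high branch.

    Raises ``ValueError`` when the observed RSD exceeds the Poisson-only
    maximum (variation inconsistent with aliquoting alone), when the RSD is
    zero (above the quantifiable-by-variance range), or on fewer than
    8 replicates / 2 positives.
    """
    pos, n_total, n_neg = _split(cqs)
    if n_total < MIN_REPLICATES:
        raise ValueError(
            f"varPCR needs >= {MIN_REPLICATES} replicates, got {n_total}"
        )
    if len(pos) < 2:
        raise ValueError("varPCR needs >= 2 positive replicates")
    n_hat, branch, sd, rsd = _point_estimate(
        pos, n_neg, efficiency, sigma_tech, branch
    )
    arr = np.asarray(
        [math.nan if c is None else float(c) for c in cqs], dtype=float
    )
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        sample = arr[rng.integers(0, n_total, n_total)]
        bpos = sample[np.isfinite(sample)]
        if len(bpos) < 2:
            continue
        try:
            bn, *_ = _point_estimate(
                bpos, int(n_total - len(bpos)), efficiency, sigma_tech, branch
            )
            boots.append(bn)
        except ValueError:
            continue
    if boots:
        lo, hi = np.percentile(boots, [2.5, 97.5])
        ci = (float(lo), float(hi))
    else:
        ci = (math.nan, math.nan)
    return VarPcrEstimate(
        n_hat=n_hat,
        branch=branch,
        sd_cq_observed=sd,
        rsd_observed=rsd,
        negative_fraction=n_neg / n_total,
        ci=ci,
        n_replicates=n_total,
        efficiency=efficiency,
    )


def varpcr_from_negatives(cqs, ci_level: float = 0.95) -> OccupancyEstimate:
    """Occupancy estimate from the negative fraction, as in dPCR.

    N = -ln(f_neg) with the CI obtained by propagating a Wilson interval
    for the negative fraction.  Requires at least one negative and one
    positive replicate (otherwise the variance path applies).
    """
    pos, n_total, n_neg = _split(cqs)
    if n_neg == 0 or len(pos) == 0:
        raise ValueError(
            "occupancy estimate needs both negative and positive replicates; "
            "use varpcr_estimate for an all-positive level"
        )
    f_neg = n_neg / n_total
    lo_f, hi_f = proportion_confint(
        n_neg, n_total, alpha=1.0 - ci_level, method="wilson"
    )
    # N is decreasing in the negative fraction, so the bounds flip
    return OccupancyEstimate(
        n_hat=-math.log(f_neg),
        ci=(-math.log(hi_f), -math.log(lo_f)),
        negative_fraction=f_neg,
        n_replicates=n_total,
    )


@dataclass(frozen=True)
class CombinedEstimate:
    n_hat: float
    ci: tuple[float, float]
    method: str  # "occupancy" | "variance"
    negative_fraction: float


def combined_estimate(
    cqs,
    efficiency: float = 1.0,
    n_boot: int = 2000,
    seed: int | None = None,
) -> CombinedEstimate:
    """Occupancy below saturation, Cq variance above it.

    Uses the dPCR-style occupancy estimator when the negative fraction is
    within [0.05, 0.95] (where it is precise) and the varPCR variance
    estimator otherwise, extending absolute quantification past the point
    where all partitions are positive.  On the variance path the branch
    follows the negative fraction: below 5% negatives the level sits on the
    decreasing (high-N) side of the RSD hump, above 95% on the rising side.
    """
    _, n_total, n_neg = _split(cqs)
    f_neg = n_neg / n_total if n_total else 0.0
    if 0.05 <= f_neg <= 0.95:
        occ = varpcr_from_negatives(cqs)
        return CombinedEstimate(
            n_hat=occ.n_hat,
            ci=occ.ci,
            method="occupancy",
            negative_fraction=f_neg,
        )
    try:
        est = varpcr_estimate(
            cqs,
            efficiency=efficiency,
            n_boot=n_boot,
            seed=seed,
            branch="high" if f_neg < 0.05 else "low",
        )
    except ValueError:
        if 0.0 < f_neg < 1.0:
            # observed RSD inconsistent with the Poisson-only curve, but
            # negatives exist: fall back to the dPCR-style occupancy readout
            occ = varpcr_from_negatives(cqs)
            return CombinedEstimate(
                n_hat=occ.n_hat,
                ci=occ.ci,
                method="occupancy",
                negative_fraction=f_neg,
            )
        raise
    return CombinedEstimate(
        n_hat=est.n_hat,
        ci=est.ci,
        method="variance",
        negative_fraction=f_neg,
    )
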