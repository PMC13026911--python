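"""Empirical detection and quantification limits from replicate tables.

The limit of detection (LOD) is estimated from the fraction of positive
replicates per concentration level: the fractions are fitted with a sigmoid
in log10(N) and the LOD is the concentration at which the fitted curve
reaches the chosen positive fraction (95 % by default).  The default
sigmoid is the complementary log-log curve

    p(N) = 1 - exp(-exp(b0 + b1 ln N))

whose b0 = 0, b1 = 1 member is exactly the Poisson occupancy law
1 - exp(-N); when aliquoting uncertainty dominates, the fit therefore
recovers the theoretical LOD of about 3 molecules without family bias.  A
logistic alternative is available.  The LOD confidence interval comes from
a parametric bootstrap of the per-level binomial counts.

The limits of quantification (LLOQ/ULOQ) are read from the per-level
precision profile: the linear-scale RSD, converted from the SD of the Cq
values of the positive replicates, is compared to a threshold (25 % by
default), and the dynamic range is the contiguous run of levels meeting it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .scale_convert import cq_sd_to_linear_rsd

__all__ = [
    "PrecisionProfile",
    "LodEstimate",
    "LoqRange",
    "precision_profile",
    "empirical_lod",
    "empirical_loq",
]


@dataclass(frozen=True)
class PrecisionProfile:
    """Per-level replicate statistics: counts, positive fraction, SD, RSD."""

    table: pd.DataFrame  # columns: copies, n_replicates, n_positive,
    #          positive_fraction, sd_cq, rsd_linear, all_positive
    efficiency: float

    def __len__(self) -> int:
        return len(self.table)


def precision_profile(records: pd.DataFrame, efficiency: float) -> PrecisionProfile:
    """Summarise a reaction table into per-level precision statistics.

    ``records`` uses the shared schema (level_id, copies, replicate, cq;
    NaN cq = negative reaction).  SD(Cq) is taken over the positive
    replicates only — when some replicates are negative this conditioning
    biases the level mean and SD, which is flagged in a warning — and is
    converted to a linear-scale RSD at the assay efficiency.  Levels with
    fewer than two positives have no SD and are excluded from the RSD
    columns (kept in the table with NaN).
    """
    if not 0.0 < efficiency <= 1.0:
        raise ValueError("efficiency must be in (0, 1]")
    rows = []
    for copies, grp in records.groupby("copies", sort=True):
        cq = grp["cq"].to_numpy(dtype=float)
        n = len(cq)
        pos = cq[np.isfinite(cq)]
        n_pos = len(pos)
        sd = float(np.std(pos, ddof=1)) if n_pos >= 2 else float("nan")
        rsd = (
            cq_sd_to_linear_rsd(sd, efficiency)
            if math.isfinite(sd)
            else float("nan")
        )
        rows.append(
            dict(
                copies=float(copies),
                n_replicates=n,
                n_positive=n_pos,
                positive_fraction=n_pos / n,
                sd_cq=sd,
                rsd_linear=rsd,
                all_positive=n_pos == n,
            )
        )
    table = pd.DataFrame(rows).sort_values("copies", ignore_index=True)
    if not (table["n_positive"] >= 2).any():
        raise ValueError(
            "no level has >= 2 positive replicates; cannot profile precision"
        )
    n_single = int((table["n_positive"] == 1).sum())
    if n_single:
        warnings.warn(
            f"{n_single} level(s) with a single positive replicate have no "
            "defined SD and are excluded from RSD statistics",
            UserWarning,
            stacklevel=2,
        )
    if not table["all_positive"].all():
        warnings.warn(
            "some levels contain negative replicates; their Cq mean and SD "
            "are conditioned on positives only, which introduces bias",
            UserWarning,
            stacklevel=2,
        )
    return PrecisionProfile(table=table, efficiency=efficiency)


@dataclass(frozen=True)
class LodEstimate:
    """Sigmoid-interpolated LOD with parametric-bootstrap CI."""

    lod: float
    ci: tuple[float, float]
    confidence: float
    params: tuple[float, float]  # (b0, b1) of the fitted sigmoid
    family: str
    status: str = "ok"  # or "below_range" when every level is fully positive
    note: str = ""


def _sigmoid_fraction(log10_n: np.ndarray, b0: float, b1: float, family: str):
    z = b0 + b1 * log10_n * math.log(10.0)
    if family == "cloglog":
        return -np.expm1(-np.exp(np.clip(z, -700, 50)))
    return 1.0 / (1.0 + np.exp(-np.clip(z, -700, 700)))


def _invert_sigmoid(p: float, b0: float, b1: float, family: str) -> float:
    if family == "cloglog":
        z = math.log(-math.log1p(-p))
    else:
        z = math.log(p / (1.0 - p))
    return 10.0 ** ((z - b0) / (b1 * math.log(10.0)))


def _fit_fraction_curve(
    log10_n: np.ndarray, k_pos: np.ndarray, n_rep: np.ndarray, family: str
) -> tuple[float, float]:
    """Binomial maximum likelihood for the two-parameter sigmoid."""

    def nll(theta):
        p = _sigmoid_fraction(log10_n, theta[0], theta[1], family)
        p = np.clip(p, 1e-12, 1.0 - 1e-12)
        return -float(
            np.sum(k_pos * np.log(p) + (n_rep - k_pos) * np.log1p(-p))
        )

    best = None
    for start in ([0.0, 1.0], [-1.0, 2.0], [1.0, 0.5]):
        res = optimize.minimize(nll, start, method="Nelder-Mead")
        if best is None or res.fun < best.fun:
            best = res
    return float(best.x[0]), float(best.x[1])


def empirical_lod(
    profile: PrecisionProfile,
    confidence: float = 0.95,
    n_boot: int = 1000,
    seed: int | None = None,
    family: str = "cloglog",
) -> LodEstimate:
    """LOD from the positive-fraction curve across levels.

    Fits the chosen sigmoid family to (log10 N, positive fraction) by
    binomial maximum likelihood and inverts it at ``confidence``.  The CI
    is a percentile interval over ``n_boot`` parametric-bootstrap resamples
    of the per-level binomial counts, standing in for the confidence band
    of the fitted curve.  When every level is fully positive the LOD can
    only be bounded above by the lowest tested level.
    """
    if family not in ("cloglog", "logistic"):
        raise ValueError("family must be 'cloglog' or 'logistic'")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    t = profile.table
    if len(t) < 3:
        raise ValueError("need >= 3 levels to fit the positive-fraction curve")
    if (t["positive_fraction"] == 1.0).all():
        low = float(t["copies"].min())
        return LodEstimate(
            lod=math.nan,
            ci=(math.nan, math.nan),
            confidence=confidence,
            params=(math.nan, math.nan),
            family=family,
            status="below_range",
            note=f"all levels fully positive; LOD below lowest level tested "
            f"({low:g} copies)",
        )
    x = np.log10(t["copies"].to_numpy(dtype=float))
    k = t["n_positive"].to_numpy(dtype=float)
    n = t["n_replicates"].to_numpy(dtype=float)
    b0, b1 = _fit_fraction_curve(x, k, n, family)
    lod = _invert_sigmoid(confidence, b0, b1, family)
    rng = np.random.default_rng(seed)
    p_hat = np.clip(
        _sigmoid_fraction(x, b0, b1, family), 1e-9, 1.0 - 1e-9
    )
    boots = []
    for _ in range(n_boot):
        kb = rng.binomial(n.astype(int), p_hat).astype(float)
        try:
            bb0, bb1 = _fit_fraction_curve(x, kb, n, family)
            boots.append(_invert_sigmoid(confidence, bb0, bb1, family))
        except (ValueError, FloatingPointError):  # degenerate resample
            continue
    if boots:
        lo, hi = np.percentile(boots, [2.5, 97.5])
        ci = (float(lo), float(hi))
    else:
        ci = (math.nan, math.nan)
    return LodEstimate(
        lod=float(lod),
        ci=ci,
        confidence=confidence,
        params=(b0, b1),
        family=family,
    )


@dataclass(frozen=True)
class LoqRange:
    """Contiguous dynamic range [LLOQ, ULOQ] at an RSD criterion."""

    lloq: float
    uloq: float
    uloq_within_range: bool  # True when a high-end violation bounds the range
    rsd_threshold: float
    quantifiable: bool = True
    note: str = ""


def empirical_loq(
    profile: PrecisionProfile, rsd_threshold: float = 0.25
) -> LoqRange:
    """LLOQ and ULOQ from the per-level RSD against a threshold.

    The ULOQ is the highest tested level with RSD <= threshold; the LLOQ is
    the lowest level from which every tested level up to the ULOQ also
    meets the criterion.  Transient sub-threshold dips below that
    contiguous run do not set the LLOQ, because the dynamic range is
    defined as a contiguous interval.  When the highest tested level meets
    the criterion there is no ULOQ within the studied range (the flag
    ``uloq_within_range`` is False and ULOQ reports that highest level).
    """
    t = profile.table.dropna(subset=["rsd_linear"])
    if len(t) < 2:
        raise ValueError("need >= 2 levels with defined RSD")
    copies = t["copies"].to_numpy(dtype=float)
    ok = (t["rsd_linear"].to_numpy(dtype=float) <= rsd_threshold)
    if not ok.any():
        return LoqRange(
            lloq=math.nan,
            uloq=math.nan,
            uloq_within_range=False,
            rsd_threshold=rsd_threshold,
            quantifiable=False,
            note="no level meets the RSD criterion: not quantifiable in range",
        )
    i_uloq = int(np.flatnonzero(ok)[-1])
    # walk down from the ULOQ while the criterion holds contiguously
    i = i_uloq
    while i > 0 and ok[i - 1]:
        i -= 1
    return LoqRange(
        lloq=float(copies[i]),
        uloq=float(copies[i_uloq]),
        uloq_within_range=i_uloq < len(copies) - 1,
        rsd_threshold=rsd_threshold,
        note=""
        if i_uloq < len(copies) - 1
        else "no ULOQ within the concentration range studied",
    )
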