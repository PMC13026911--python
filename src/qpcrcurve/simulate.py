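"""Seeded Monte Carlo generator of replicate-level qPCR datasets.

Each simulated reaction draws its actual target count x ~ Poisson(N) for
the level's expected copies N.  Reactions with x = 0 are negative (emitted
with an empty Cq, not dropped, so positive-fraction statistics stay
computable); positive reactions report

    Cq = m - log10(x)/log10(1 + E) + Normal(0, sigma_tech)

i.e. the two variance sources are Poisson aliquoting and Gaussian Cq
measurement noise.  Early-cycle amplification stochasticity is deliberately
not modelled.  Output is a pandas DataFrame in the shared reaction-table
schema (level_id, copies, replicate, cq) and is byte-reproducible under a
fixed seed.

``extreme_series`` reproduces the design of a validation experiment run at
very high replication: a 2-fold dilution series from 2048 down to 1
expected copy per reaction, with 128 replicates at the lowest level, 64 at
intermediate levels and 32 at the two highest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "simulate_dilution_series",
    "extreme_series",
    "inject_curvature",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Assay and design parameters for one simulated dilution series.

    ``levels`` may be given explicitly, or built from ``top_level`` /
    ``n_levels`` / ``dilution_factor``.  ``replicates_per_level`` is either
    one integer for all levels or a sequence matching ``levels``.
    ``outliers`` is a list of (level_index, replicate_index, cq_offset)
    applied after noise.
    """

    intercept_m: float = 34.0
    efficiency: float = 1.0
    sigma_tech: float = 0.15
    levels: Sequence[float] = ()
    replicates_per_level: int | Sequence[int] = 3
    seed: int | None = None
    outliers: Sequence[tuple[int, int, float]] = field(default_factory=tuple)

    @staticmethod
    def from_dilution(
        top_level: float,
        n_levels: int,
        dilution_factor: float = 10.0,
        **kwargs,
    ) -> "SimulationConfig":
        if dilution_factor <= 1:
            raise ValueError("dilution_factor must be > 1")
        levels = [top_level / dilution_factor**i for i in range(n_levels)]
        return SimulationConfig(levels=tuple(sorted(levels)), **kwargs)

    def __post_init__(self) -> None:
        if not 0.0 < self.efficiency <= 1.0:
            raise ValueError("efficiency must be in (0, 1]")
        if self.sigma_tech < 0:
            raise ValueError("sigma_tech must be >= 0")
        if len(self.levels) == 0:
            raise ValueError("levels must be a non-empty sequence")
        if any(lv <= 0 for lv in self.levels):
            raise ValueError("levels must be strictly positive")
        reps = self.replicates_per_level
        if isinstance(reps, int):
            if reps < 1:
                raise ValueError("replicates_per_level must be >= 1")
        else:
            if len(reps) != len(self.levels):
                raise ValueError(
                    "replicates_per_level sequence must match levels"
                )
            if any(r < 1 for r in reps):
                raise ValueError("replicates_per_level must be >= 1")

    @property
    def replicate_counts(self) -> list[int]:
        reps = self.replicates_per_level
        if isinstance(reps, int):
            return [reps] * len(self.levels)
        return [int(r) for r in reps]


def simulate_dilution_series(config: SimulationConfig) -> pd.DataFrame:
    """Draw one reaction table under ``config`` (deterministic per seed)."""
    rng = np.random.default_rng(config.seed)
    slope = -1.0 / math.log10(1.0 + config.efficiency)
    frames = []
    for i, (level, n_rep) in enumerate(
        zip(config.levels, config.replicate_counts)
    ):
        x = rng.poisson(level, n_rep)
        cq = np.full(n_rep, np.nan)
        pos = x > 0
        cq[pos] = config.intercept_m + slope * np.log10(x[pos])
        if config.sigma_tech > 0:
            cq[pos] += rng.normal(0.0, config.sigma_tech, int(pos.sum()))
        frames.append(
            pd.DataFrame(
                {
                    "level_id": f"L{i + 1:02d}",
                    "copies": float(level),
                    "replicate": np.arange(1, n_rep + 1),
                    "cq": cq,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    for lvl_idx, rep_idx, offset in config.outliers:
        mask = (table["level_id"] == f"L{lvl_idx + 1:02d}") & (
            table["replicate"] == rep_idx
        )
        if not mask.any():
            raise ValueError(
                f"outlier target (level {lvl_idx}, replicate {rep_idx}) "
                "not present in the design"
            )
        table.loc[mask, "cq"] += offset
    return table


def extreme_series(
    seed: int | None = None,
    sigma_tech: float = 0.15,
    intercept_m: float = 34.0,
    efficiency: float = 1.0,
) -> pd.DataFrame:
    """High-replication 2-fold series: 1..2048 copies per reaction.

    128 replicates at N = 1, 64 at 2 <= N <= 512, 32 at N in {1024, 2048}.
    """
    levels = [2.0**i for i in range(12)]  # 1 .. 2048
    reps = [128] + [64] * 9 + [32, 32]
    cfg = SimulationConfig(
        intercept_m=intercept_m,
        efficiency=efficiency,
        sigma_tech=sigma_tech,
        levels=tuple(levels),
        replicates_per_level=reps,
        seed=seed,
    )
    return simulate_dilution_series(cfg)


def inject_curvature(
    table: pd.DataFrame, top_level_offset: float
) -> pd.DataFrame:
    """Add a Cq offset to every reaction at the highest level.

    Reproduces the classic high-end curvature failure mode (for example
    inhibition in the least-diluted calibrator) used to exercise the
    linearity test.  Returns a copy; row count is conserved.
    """
    if len(table) == 0:
        raise ValueError("empty reaction table")
    if table["copies"].nunique() < 2:
        raise ValueError("need >= 2 levels to single out a top level")
    out = table.copy()
    top = out["copies"].max()
    out.loc[out["copies"] == top, "cq"] += top_level_offset
    return out
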