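"""Readers and writers for the shared reaction-table schema and fit JSON.

The on-disk replicate table is a CSV with header ``level_id,copies,
replicate,cq``; an empty ``cq`` field marks a negative reaction.  Copies
are expected copies per reaction; a no-template control is encoded with
``level_id`` = ``ntc`` and copies 0 (the only row type allowed a
non-positive copy number).  Fits round-trip through a flat JSON document so
a curve fitted once can be reused by the prediction command.
"""

from __future__ import annotations

import dataclasses
import json
import math
import tomllib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .standard_curve import StandardCurveFit

__all__ = [
    "RunConfig",
    "read_reactions",
    "write_reactions",
    "fit_to_dict",
    "fit_from_dict",
    "save_fit",
    "load_fit",
    "load_run_config",
]

SCHEMA = ("level_id", "copies", "replicate", "cq")


@dataclass(frozen=True)
class RunConfig:
    """Analysis defaults, overridable from a TOML file or CLI flags."""

    ci_level: float = 0.95
    rsd_threshold: float = 0.25
    linearity_alpha: float = 0.05
    grubbs_alpha: float = 0.05
    lod_confidence: float = 0.95
    efficiency: float | None = None  # override; otherwise from the fit
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("ci_level", "linearity_alpha", "grubbs_alpha", "lod_confidence"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.rsd_threshold <= 0:
            raise ValueError("rsd_threshold must be > 0")
        if self.efficiency is not None and not 0.0 < self.efficiency <= 1.0:
            raise ValueError("efficiency override must be in (0, 1]")


def load_run_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from a TOML file (unknown keys rejected)."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def read_reactions(path: str | Path) -> pd.DataFrame:
    """Read and validate a reaction table CSV.

    Empty ``cq`` becomes NaN (negative reaction).  Rejects schema
    mismatches, duplicate (level_id, replicate) pairs, and non-positive
    copies outside the ``ntc`` convention, listing the offending rows.
    """
    df = pd.read_csv(path, dtype={"level_id": str})
    missing = [c for c in SCHEMA if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required column(s) {missing}; "
            f"expected header {','.join(SCHEMA)}"
        )
    df = df[list(SCHEMA)].copy()
    df["copies"] = pd.to_numeric(df["copies"], errors="coerce")
    df["cq"] = pd.to_numeric(df["cq"], errors="coerce")
    bad_copies = df.index[df["copies"].isna()].tolist()
    if bad_copies:
        raise ValueError(f"{path}: unparseable copies in rows {bad_copies}")
    is_ntc = df["level_id"].str.lower() == "ntc"
    nonpos = df.index[(df["copies"] <= 0) & ~is_ntc].tolist()
    if nonpos:
        raise ValueError(
            f"{path}: non-positive copies in rows {nonpos}; a reaction with "
            "0 expected copies is a no-template control and must use "
            "level_id 'ntc'"
        )
    dup = df.duplicated(subset=["level_id", "replicate"], keep=False)
    if dup.any():
        raise ValueError(
            f"{path}: duplicate (level_id, replicate) pairs in rows "
            f"{df.index[dup].tolist()}"
        )
    return df


def write_reactions(table: pd.DataFrame, path: str | Path) -> None:
    """Write a reaction table; negative reactions get an empty cq field."""
    table.to_csv(path, index=False, columns=list(SCHEMA))


_FIT_SCALARS = (
    "slope_k",
    "intercept_m",
    "se_slope",
    "se_intercept",
    "fit_se",
    "n_points",
    "df",
    "mean_cq",
    "mean_log10",
    "sxx",
    "efficiency",
    "efficiency_se",
    "ci_level",
    "replicate_mode",
)


def fit_to_dict(fit: StandardCurveFit) -> dict:
    d = {name: getattr(fit, name) for name in _FIT_SCALARS}
    for name in ("efficiency_ci", "slope_ci", "intercept_ci"):
        d[name] = list(getattr(fit, name))
    for name in ("residuals", "x", "y"):
        d[name] = [float(v) for v in getattr(fit, name)]
    return d


def fit_from_dict(d: dict) -> StandardCurveFit:
    kwargs = {name: d[name] for name in _FIT_SCALARS}
    for name in ("efficiency_ci", "slope_ci", "intercept_ci"):
        kwargs[name] = tuple(d[name])
    for name in ("residuals", "x", "y"):
        kwargs[name] = np.asarray(d[name], dtype=float)
    return StandardCurveFit(**kwargs)


def save_fit(fit: StandardCurveFit, path: str | Path) -> None:
    Path(path).write_text(json.dumps(fit_to_dict(fit), indent=2) + "\n")


def load_fit(path: str | Path) -> StandardCurveFit:
    return fit_from_dict(json.loads(Path(path).read_text()))
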