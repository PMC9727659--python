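"""Reading and writing time-series data, profiles and envelopes; run configs.

Data files are plain CSV with header columns ``t`` and ``y`` (time and
measurement in the user's units — no internal rescaling). Profile tables and
prediction envelopes are written as CSV at full double precision so a write /
read round trip is lossless to at least 12 significant digits. Run
configuration is a declarative TOML file validated into :class:`RunConfig`.
"""

from __future__ import annotations

import math
import tomllib
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .inference import Dataset
from .prediction import PredictionEnvelope, envelope_difference
from .profiling import ProfileResult

__all__ = [
    "read_timeseries_csv",
    "write_dataset_csv",
    "write_profile_csv",
    "write_envelope_csv",
    "radius_from_area",
    "RunConfig",
    "load_config",
]

_FLOAT_FMT = "%.17g"


def read_timeseries_csv(path) -> Dataset:
    """Read a ``t,y`` CSV into a Dataset, sorted by time (stable for ties).

    Duplicate times are replicate measurements and are kept. Malformed input
    (missing columns, non-numeric cells, empty file) raises with the
    offending row number (1-based, header excluded).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: file is empty") from None
    missing = [c for c in ("t", "y") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if len(df) == 0:
        raise ValueError(f"{path}: no data rows")
    for col in ("t", "y"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        nan_in = df[col].isna()
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise ValueError(
                f"{path}: non-numeric value {df[col][row - 1]!r} in column "
                f"{col!r} at data row {row}"
            )
        if nan_in.any():
            row = int(nan_in.idxmax()) + 1
            raise ValueError(f"{path}: empty cell in column {col!r} at data row {row}")
        df[col] = numeric
    df = df.sort_values("t", kind="stable")
    return Dataset(times=df["t"].to_numpy(), observations=df["y"].to_numpy())


def write_dataset_csv(data: Dataset, path) -> None:
    """Write a Dataset as a ``t,y`` CSV at full double precision."""
    pd.DataFrame({"t": data.times, "y": data.observations}).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def write_profile_csv(profile: ProfileResult, path) -> None:
    """Profile table: interest value, profile log-likelihood, one column per
    optimized nuisance parameter."""
    cols = {
        profile.interest_name: profile.mesh,
        "profile_loglik": profile.profile_values,
    }
    for j, name in enumerate(profile.nuisance_names):
        cols[name] = profile.nuisance_optima[:, j]
    pd.DataFrame(cols).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_envelope_csv(envelope: PredictionEnvelope, path) -> None:
    """Envelope table with the MLE curve and difference-from-MLE columns."""
    lo_diff, hi_diff = envelope_difference(envelope)
    pd.DataFrame(
        {
            "t": envelope.grid,
            "lower": envelope.lower,
            "mle": envelope.mle_curve,
            "upper": envelope.upper,
            "lower_diff": lo_diff,
            "upper_diff": hi_diff,
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def radius_from_area(area):
    """Equivalent radius of a circle of the given area: ``sqrt(area / pi)``.

    Converts top-down projected spheroid areas (μm²) into equivalent radii
    (μm) under the assumption of spherical geometry. Accepts scalars or
    arrays; negative areas raise.
    """
    arr = np.asarray(area, dtype=float)
    if np.any(arr < 0):
        raise ValueError("area must be non-negative")
    out = np.sqrt(arr / math.pi)
    return float(out) if np.isscalar(area) or arr.ndim == 0 else out


class RunConfig(BaseModel):
    """Declarative configuration of one analysis run."""

    data: Optional[str] = None
    model: str = "delayed_logistic"
    start: dict = Field(default_factory=dict)
    bounds: dict = Field(default_factory=dict)
    fixed: dict = Field(default_factory=dict)
    mesh_points: int = 40
    levels: list = Field(default_factory=lambda: [0.95, 0.99, 0.999])
    grid_points: int = 200
    solver: str = "rk2"
    seed: int = 0
    out: str = "."

    @field_validator("levels")
    @classmethod
    def _levels_in_unit_interval(cls, v):
        for lvl in v:
            if not 0.0 < float(lvl) < 1.0:
                raise ValueError(f"confidence level {lvl} outside (0, 1)")
        return [float(lvl) for lvl in v]

    @field_validator("bounds")
    @classmethod
    def _bounds_are_pairs(cls, v):
        out = {}
        for name, pair in v.items():
            lo, hi = pair
            if not float(lo) < float(hi):
                raise ValueError(f"bound for {name!r} must satisfy lower < upper")
            out[name] = (float(lo), float(hi))
        return out

    @field_validator("mesh_points", "grid_points")
    @classmethod
    def _positive(cls, v):
        if v < 2:
            raise ValueError("must be at least 2")
        return v


def load_config(path) -> RunConfig:
    """Load and validate a TOML run configuration."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    return RunConfig(**raw)
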