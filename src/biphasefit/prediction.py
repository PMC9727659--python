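"""Parameter-wise profile predictions of the mean trajectory and union envelopes.

A profile for an interest parameter ``psi`` carries, at each mesh point, the
optimized nuisance vector ``lambda*(psi)``. Evaluating the model's mean
trajectory along this profile curve — for every mesh point whose profile
log-likelihood clears the confidence threshold — and taking the pointwise
min/max over the resulting curves (the MLE trajectory included) yields a
*parameter-wise prediction envelope*: a band showing how uncertainty in that
single parameter propagates into the predicted mean. The noise scale ``sigma``
does not enter the mean, so its envelope has zero width by construction.

Unions of envelopes from different interest parameters (pointwise min of
lowers, max of uppers) give a conservative combined band whose coverage is at
least that of each constituent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .inference import FitResult, model_mean
from .models import get_model
from .profiling import ProfileResult, loglik_threshold

__all__ = [
    "PredictionEnvelope",
    "parameterwise_prediction",
    "envelope_difference",
    "union_envelope",
    "prediction_grid",
]


@dataclass(frozen=True)
class PredictionEnvelope:
    """Pointwise lower/MLE/upper mean-trajectory curves on a time grid."""

    grid: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    mle_curve: np.ndarray
    source: tuple
    level: float | None

    def __post_init__(self):
        grid = np.asarray(self.grid, dtype=float)
        if grid.size > 1 and not np.all(np.diff(grid) > 0):
            raise ValueError("prediction grid must be strictly increasing")
        for name in ("lower", "upper", "mle_curve"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != grid.shape:
                raise ValueError(f"{name} must match the grid shape")
            object.__setattr__(self, name, arr)
        object.__setattr__(self, "grid", grid)

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower


def prediction_grid(data_times: np.ndarray, num: int = 200, extend: float = 0.0) -> np.ndarray:
    """Uniform grid spanning the observation window, optionally extended
    beyond it by a fraction ``extend`` of the window for forecasting."""
    t = np.asarray(data_times, dtype=float)
    t0, t1 = float(t.min()), float(t.max())
    return np.linspace(t0, t1 + extend * (t1 - t0), num)


def parameterwise_prediction(
    profile: ProfileResult,
    model,
    fit: FitResult,
    grid: np.ndarray,
    level: float = 0.95,
    solver: str = "rk2",
    step: float | None = None,
) -> PredictionEnvelope:
    """Envelope of mean trajectories along one parameter's profile curve.

    Every mesh point whose profile value clears ``loglik_threshold(level)``
    contributes the trajectory at ``(psi_j, lambda*(psi_j))``; the envelope is
    the pointwise min/max over these trajectories and the MLE trajectory.
    """
    model = get_model(model)
    grid = np.asarray(grid, dtype=float)
    thr = loglik_threshold(level)
    ok = np.isfinite(profile.profile_values) & (profile.profile_values >= thr)
    if not np.any(ok):
        raise ValueError(
            "no profile mesh point above the threshold — inconsistent profile"
        )

    base = fit.mle.as_dict()
    mle_curve = model_mean(model, base, grid, solver=solver, step=step)
    lower = mle_curve.copy()
    upper = mle_curve.copy()
    for j in np.nonzero(ok)[0]:
        p = dict(base)
        p[profile.interest_name] = float(profile.mesh[j])
        for name, val in zip(profile.nuisance_names, profile.nuisance_optima[j]):
            p[name] = float(val)
        curve = model_mean(model, p, grid, solver=solver, step=step)
        np.minimum(lower, curve, out=lower)
        np.maximum(upper, curve, out=upper)
    return PredictionEnvelope(
        grid=grid,
        lower=lower,
        upper=upper,
        mle_curve=mle_curve,
        source=(profile.interest_name,),
        level=level,
    )


def envelope_difference(envelope: PredictionEnvelope):
    """Difference curves (lower − MLE, upper − MLE); the first is <= 0 <= the
    second pointwise by construction."""
    return envelope.lower - envelope.mle_curve, envelope.upper - envelope.mle_curve


def union_envelope(envelopes: Sequence[PredictionEnvelope]) -> PredictionEnvelope:
    """Pointwise union of envelopes on a common grid.

    Lower bound = min of lowers, upper = max of uppers; the union contains
    every constituent pointwise and its coverage is at least theirs.
    """
    envelopes = list(envelopes)
    if not envelopes:
        raise ValueError("need at least one envelope")
    first = envelopes[0]
    for env in envelopes[1:]:
        if not np.array_equal(env.grid, first.grid):
            raise ValueError("all envelopes must share an identical grid")
    lower = np.min([e.lower for e in envelopes], axis=0)
    upper = np.max([e.upper for e in envelopes], axis=0)
    levels = {e.level for e in envelopes}
    source = tuple(n for e in envelopes for n in e.source)
    return PredictionEnvelope(
        grid=first.grid,
        lower=lower,
        upper=upper,
        mle_curve=first.mle_curve,
        source=source,
        level=levels.pop() if len(levels) == 1 else None,
    )
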