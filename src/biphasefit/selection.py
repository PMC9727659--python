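"""AIC-based comparison of modelling approaches.

An *approach* is a model plus a rule for which parameters are estimated and
which are fixed. The canonical trio for delayed-growth data:

1. the full biphasic model, all parameters estimated;
2. a single-phase reading — change point fixed at ``T = 0`` and the initial
   condition pinned to the first measurement;
3. a single-phase model with ``T = 0`` but ``C0`` still estimated.

Approaches are ranked by the Akaike information criterion,
``AIC = -2 * max_loglik + 2k`` with ``k`` the number of estimated parameters
(noise scale included); fixing a parameter removes it from ``k``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .inference import Dataset, FitResult, fit_mle
from .models import get_model

__all__ = [
    "FIRST_OBSERVATION",
    "Approach",
    "ApproachFit",
    "ComparisonReport",
    "aic",
    "compare_approaches",
    "standard_approaches",
]

#: Sentinel: fix a parameter to the observation at the earliest time point.
FIRST_OBSERVATION = "first_observation"


def aic(fit: FitResult) -> float:
    """Akaike information criterion, ``-2 * max_loglik + 2 * k``."""
    if not fit.converged:
        raise ValueError("refusing to compute AIC for a non-converged fit")
    return -2.0 * fit.max_loglik + 2.0 * fit.k


@dataclass(frozen=True)
class Approach:
    """One model configuration entered into a comparison."""

    name: str
    model: object  # GrowthModel or built-in kind name
    start: Mapping[str, float]
    bounds: Mapping[str, tuple] | None = None
    fixed: Mapping[str, object] = field(default_factory=dict)

    def resolve_fixed(self, data: Dataset) -> dict:
        out = {}
        for key, value in dict(self.fixed).items():
            if value == FIRST_OBSERVATION:
                out[key] = float(data.observations[0])
            else:
                out[key] = float(value)
        return out


@dataclass(frozen=True)
class ApproachFit:
    name: str
    k: int
    max_loglik: float
    aic: float
    delta_aic: float
    converged: bool
    fit: FitResult


@dataclass(frozen=True)
class ComparisonReport:
    """Approaches ranked by AIC (ascending; best first)."""

    rows: tuple

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "approach": r.name,
                    "k": r.k,
                    "max_loglik": r.max_loglik,
                    "AIC": r.aic,
                    "dAIC": r.delta_aic,
                    "converged": r.converged,
                }
                for r in self.rows
            ]
        )

    def to_json(self, **kwargs) -> str:
        records = self.to_frame().to_dict(orient="records")
        return json.dumps(records, **kwargs)

    @property
    def best(self) -> ApproachFit:
        return self.rows[0]

    def __str__(self) -> str:
        return self.to_frame().to_string(index=False, float_format=lambda v: f"{v:.4g}")


def compare_approaches(
    data: Dataset,
    approaches: Sequence[Approach],
    **fit_kwargs,
) -> ComparisonReport:
    """Fit every approach to the same data and rank by AIC.

    Fixed parameters (including the :data:`FIRST_OBSERVATION` rule for the
    initial condition) are removed from the estimated vector, reducing ``k``.
    Non-converged fits are kept in the report but flagged.
    """
    if len(approaches) < 2:
        raise ValueError("need at least two approaches to compare")
    fits = []
    for ap in approaches:
        fixed = ap.resolve_fixed(data)
        fit = fit_mle(
            get_model(ap.model),
            data,
            start=ap.start,
            bounds=ap.bounds,
            fixed=fixed,
            **fit_kwargs,
        )
        fits.append((ap, fit))
    aics = [-2.0 * f.max_loglik + 2.0 * f.k for _, f in fits]
    best = min(aics)
    rows = [
        ApproachFit(
            name=ap.name,
            k=f.k,
            max_loglik=f.max_loglik,
            aic=a,
            delta_aic=a - best,
            converged=f.converged,
            fit=f,
        )
        for (ap, f), a in zip(fits, aics)
    ]
    rows.sort(key=lambda r: r.aic)
    return ComparisonReport(rows=tuple(rows))


def standard_approaches(
    start: Mapping[str, float],
    bounds: Mapping[str, tuple] | None = None,
    biphasic_model: str = "delayed_logistic",
    single_phase_model: str = "single_phase_logistic",
) -> list:
    """The canonical three approaches for delayed logistic growth data.

    ``start`` must cover the biphasic model's parameters plus ``sigma``; the
    single-phase approaches reuse the relevant subset.
    """
    start = dict(start)
    single_start = {k: v for k, v in start.items() if k != "T"}
    return [
        Approach(
            name="biphasic (all parameters estimated)",
            model=biphasic_model,
            start=start,
            bounds=bounds,
        ),
        Approach(
            name="single-phase, C0 fixed to first measurement",
            model=single_phase_model,
            start={k: v for k, v in single_start.items() if k != "C0"},
            bounds=bounds,
            fixed={"C0": FIRST_OBSERVATION},
        ),
        Approach(
            name="single-phase, C0 estimated",
            model=single_phase_model,
            start=single_start,
            bounds=bounds,
        ),
    ]
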