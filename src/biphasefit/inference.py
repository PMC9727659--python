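"""Gaussian observation model, log-likelihood and maximum-likelihood estimation.

Observations ``y_i`` at times ``t_i`` are modelled as the process-model
trajectory plus i.i.d. additive Gaussian noise of constant variance::

    y_i | theta ~ N( C(t_i; process params), sigma^2 )

The full parameter vector ``theta`` collects the process parameters and the
noise standard deviation ``sigma``. The MLE maximizes the log-likelihood

    l(theta) = sum_i log phi(y_i; C(t_i), sigma^2)

subject to box bounds, using Nelder–Mead on a logit-transformed copy of the
parameter space: each bounded coordinate is mapped to the real line so the
simplex search is unconstrained internally while every iterate stays strictly
inside its bounds. ``sigma`` can optionally be concentrated out analytically
(for fixed process parameters the maximizing sigma is the RMS residual), which
is exact and shrinks the search space by one dimension.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import optimize
from scipy.special import expit, logit

from .models import GrowthModel, get_model, solve_rk2

__all__ = [
    "Dataset",
    "ParameterVector",
    "FitResult",
    "log_likelihood",
    "normalized_log_likelihood",
    "fit_mle",
    "model_mean",
]

_LOG_2PI = float(np.log(2.0 * np.pi))
SIGMA = "sigma"
_DEFAULT_SIGMA_BOUNDS = (1e-8, 1e6)


@dataclass(frozen=True)
class Dataset:
    """A univariate growth time series: observation times and measurements.

    Times must be sorted (ties allowed — replicate measurements at the same
    time are legitimate); observations must be finite.
    """

    times: np.ndarray
    observations: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.observations, dtype=float)
        if t.ndim != 1 or y.ndim != 1 or t.size != y.size:
            raise ValueError("times and observations must be 1-d and equal length")
        if t.size < 1:
            raise ValueError("dataset must contain at least one observation")
        if t.size > 1 and np.any(np.diff(t) < 0):
            raise ValueError("times must be sorted non-decreasing")
        if not np.all(np.isfinite(y)) or not np.all(np.isfinite(t)):
            raise ValueError("times and observations must be finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "observations", y)

    def __len__(self) -> int:
        return self.times.size


class ParameterVector(Mapping):
    """Ordered mapping of parameter names to values with box bounds.

    Includes the process parameters and the noise scale ``sigma`` (standard
    deviation, in measurement units). Values must lie within their bounds and
    ``sigma`` must be positive.
    """

    def __init__(self, values: Mapping[str, float], bounds: Mapping[str, tuple]):
        self._names = tuple(values.keys())
        self._values = np.array([float(values[n]) for n in self._names])
        self._bounds = {n: (float(lo), float(hi)) for n, (lo, hi) in bounds.items()}
        if SIGMA in self._names and float(values[SIGMA]) <= 0:
            raise ValueError("sigma must be positive")
        for n, v in zip(self._names, self._values):
            lo, hi = self._bounds.get(n, (-np.inf, np.inf))
            if not (lo <= v <= hi):
                raise ValueError(f"parameter {n!r}={v:g} outside bounds ({lo:g}, {hi:g})")

    @property
    def names(self) -> tuple:
        return self._names

    @property
    def values(self) -> np.ndarray:
        return self._values.copy()

    @property
    def bounds(self) -> dict:
        return dict(self._bounds)

    def __getitem__(self, name):
        return float(self._values[self._names.index(name)])

    def __iter__(self):
        return iter(self._names)

    def __len__(self):
        return len(self._names)

    def as_dict(self) -> dict:
        return {n: float(v) for n, v in zip(self._names, self._values)}

    def replace(self, **updates) -> "ParameterVector":
        d = self.as_dict()
        d.update(updates)
        return ParameterVector(d, self._bounds)

    def __repr__(self):
        inner = ", ".join(f"{n}={v:g}" for n, v in zip(self._names, self._values))
        return f"ParameterVector({inner})"


@dataclass(frozen=True)
class FitResult:
    """Outcome of a maximum-likelihood fit."""

    mle: ParameterVector
    max_loglik: float
    k: int  # number of estimated parameters, sigma included when estimated
    converged: bool
    n_evals: int

    def __post_init__(self):
        if not np.isfinite(self.max_loglik):
            raise ValueError("max_loglik must be finite")


def model_mean(
    model: GrowthModel,
    params: Mapping[str, float],
    times: np.ndarray,
    solver: str = "rk2",
    step: float | None = None,
) -> np.ndarray:
    """Mean trajectory of the observation model at the given times.

    ``solver="rk2"`` integrates numerically; ``"closed_form"`` uses the exact
    solution (available for built-ins); ``"auto"`` prefers the closed form.
    Duplicate times (replicates) are handled by solving on the unique grid.
    """
    t = np.asarray(times, dtype=float)
    if solver == "auto":
        solver = "closed_form" if model.closed_form is not None else "rk2"
    if solver == "closed_form":
        if model.closed_form is None:
            raise ValueError(f"model {model.name!r} has no closed-form solution")
        return np.asarray(model.closed_form(params, t), dtype=float)
    if solver != "rk2":
        raise ValueError(f"unknown solver {solver!r}; use 'rk2', 'closed_form' or 'auto'")
    uniq, inverse = np.unique(t, return_inverse=True)
    traj = solve_rk2(model, params, uniq, step=step)
    return traj.values[inverse]


def _gaussian_loglik(residuals: np.ndarray, sigma: float) -> float:
    n = residuals.size
    return -0.5 * n * (_LOG_2PI + 2.0 * np.log(sigma)) - float(
        residuals @ residuals
    ) / (2.0 * sigma * sigma)


def log_likelihood(
    params: Mapping[str, float],
    data: Dataset,
    model: GrowthModel,
    solver: str = "rk2",
    step: float | None = None,
) -> float:
    """Gaussian log-likelihood of the data under the model trajectory.

    Sum over observations of the normal log-density with mean equal to the
    model solution at each observation time and variance ``sigma**2``.
    """
    sigma = float(params[SIGMA])
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    mean = model_mean(model, params, data.times, solver=solver, step=step)
    return _gaussian_loglik(data.observations - mean, sigma)


def normalized_log_likelihood(
    params: Mapping[str, float],
    data: Dataset,
    model: GrowthModel,
    fit: FitResult,
    solver: str = "rk2",
    step: float | None = None,
) -> float:
    """Log-likelihood shifted so its supremum is zero: ``l(theta) - l(theta_hat)``.

    Equals 0 at the MLE and is non-positive elsewhere (up to optimizer
    tolerance).
    """
    return log_likelihood(params, data, model, solver=solver, step=step) - fit.max_loglik


# ---------------------------------------------------------------------------
# bounded Nelder–Mead via logit coordinate transform


class _BoxTransform:
    """Bijective map between a box (lo, hi)^d and R^d via the logit function."""

    _EPS = 1e-12

    def __init__(self, lower: np.ndarray, upper: np.ndarray):
        self.lower = np.asarray(lower, dtype=float)
        self.upper = np.asarray(upper, dtype=float)
        self.width = self.upper - self.lower
        if np.any(self.width <= 0):
            raise ValueError("every bound must satisfy lower < upper")

    def to_unbounded(self, x: np.ndarray) -> np.ndarray:
        frac = np.clip((np.asarray(x) - self.lower) / self.width, self._EPS, 1 - self._EPS)
        return logit(frac)

    def to_bounded(self, z: np.ndarray) -> np.ndarray:
        return self.lower + self.width * expit(np.asarray(z))


def _nelder_mead(objective, x0, lower, upper, xtol, ftol, maxfev):
    """Maximize ``objective`` over a box by Nelder–Mead on logit coordinates.

    Returns (x_opt, f_opt, n_evals, converged).
    """
    box = _BoxTransform(lower, upper)

    def neg(z):
        val = objective(box.to_bounded(z))
        return -val if np.isfinite(val) else np.inf

    # a start pinned to a bound maps to |z| ~ 28 where the transform is flat
    # and the simplex cannot move that coordinate; clip the start (only) to
    # the responsive region — the search itself can still approach the bound
    z0 = np.clip(box.to_unbounded(np.asarray(x0, dtype=float)), -7.0, 7.0)
    res = optimize.minimize(
        neg,
        z0,
        method="Nelder-Mead",
        options={"xatol": xtol, "fatol": ftol, "maxfev": int(maxfev)},
    )
    x_opt = box.to_bounded(res.x)
    return x_opt, -float(res.fun), int(res.nfev), bool(res.success)


def _resolve_bounds(model, names, bounds):
    merged = dict(model.default_bounds)
    merged.setdefault(SIGMA, _DEFAULT_SIGMA_BOUNDS)
    if bounds:
        merged.update({n: (float(lo), float(hi)) for n, (lo, hi) in dict(bounds).items()})
    missing = [n for n in names if n not in merged]
    if missing:
        raise ValueError(f"no bounds available for parameters: {missing}")
    return {n: merged[n] for n in names}


def fit_mle(
    model,
    data: Dataset,
    start: Mapping[str, float],
    bounds: Mapping[str, tuple] | None = None,
    fixed: Mapping[str, float] | None = None,
    concentrate_sigma: bool = False,
    solver: str = "rk2",
    step: float | None = None,
    multistart: int = 0,
    seed: int | None = None,
    xtol: float = 1e-8,
    ftol: float = 1e-8,
    maxfev: int = 100_000,
) -> FitResult:
    """Bounded Nelder–Mead maximum-likelihood fit of a growth model.

    Parameters
    ----------
    model : GrowthModel or built-in kind name.
    data : Dataset.
    start : mapping of starting values; must cover every estimated parameter
        (process parameters plus ``sigma`` unless fixed or concentrated).
    bounds : per-parameter (lower, upper) overrides of the model defaults.
    fixed : parameters held at the given values and excluded from the
        estimated vector (``k`` shrinks accordingly).
    concentrate_sigma : if True, ``sigma`` is not searched numerically but set
        to the RMS residual of the candidate trajectory — the exact maximizer
        for fixed process parameters. ``k`` still counts sigma as estimated.
    multistart : number of additional uniform starting draws within bounds.
    seed : RNG seed for multistart draws.

    Returns
    -------
    FitResult with the MLE (all parameters, fixed ones included), the
    maximized log-likelihood, the estimated-parameter count ``k``, a
    convergence flag and the number of likelihood evaluations.
    """
    model = get_model(model)
    fixed = dict(fixed or {})
    start = dict(start)

    process_names = [n for n in model.param_names if n not in fixed]
    sigma_fixed = SIGMA in fixed
    sigma_free = not sigma_fixed
    if concentrate_sigma and sigma_fixed:
        raise ValueError("cannot concentrate a fixed sigma")

    free_names = list(process_names)
    if sigma_free and not concentrate_sigma:
        free_names.append(SIGMA)

    all_names = list(model.param_names) + [SIGMA]
    bound_map = _resolve_bounds(model, all_names, bounds)
    lower = np.array([bound_map[n][0] for n in free_names])
    upper = np.array([bound_map[n][1] for n in free_names])

    k = len(process_names) + (1 if sigma_free else 0)
    if len(data) < k:
        warnings.warn(
            f"only {len(data)} observations for {k} estimated parameters; "
            "expect flat profiles / weak identifiability",
            stacklevel=2,
        )

    missing = [n for n in free_names if n not in start]
    if missing:
        raise ValueError(f"start values missing for parameters: {missing}")
    x0 = np.array([float(start[n]) for n in free_names])
    if np.any(x0 < lower) or np.any(x0 > upper):
        raise ValueError("start values must lie within bounds")

    y = data.observations
    t = data.times
    I = y.size
    sigma_lo, sigma_hi = bound_map[SIGMA]

    def objective(x):
        p = dict(zip(free_names, x))
        p.update(fixed)
        try:
            mean = model_mean(model, p, t, solver=solver, step=step)
        except (RuntimeError, FloatingPointError, ValueError):
            return -np.inf
        resid = y - mean
        if concentrate_sigma:
            sig = np.clip(np.sqrt(resid @ resid / I), sigma_lo, sigma_hi)
        else:
            sig = p[SIGMA]
        return _gaussian_loglik(resid, max(sig, 1e-300))

    starts = [x0]
    if multistart > 0:
        rng = np.random.default_rng(seed)
        starts += [rng.uniform(lower, upper) for _ in range(int(multistart))]

    best = None
    total_evals = 0
    for s in starts:
        x_opt, f_opt, n_evals, ok = _nelder_mead(
            objective, s, lower, upper, xtol, ftol, maxfev
        )
        total_evals += n_evals
        if best is None or f_opt > best[1]:
            best = (x_opt, f_opt, ok)
    x_opt, f_opt, ok = best

    mle_dict = dict(zip(free_names, x_opt))
    mle_dict.update(fixed)
    if concentrate_sigma:
        p = dict(mle_dict)
        mean = model_mean(model, p, t, solver=solver, step=step)
        resid = y - mean
        mle_dict[SIGMA] = float(
            np.clip(np.sqrt(resid @ resid / I), sigma_lo, sigma_hi)
        )
    ordered = {n: mle_dict[n] for n in all_names if n in mle_dict}
    out_bounds = dict(bound_map)
    for n in fixed:  # fixed values are data-driven, not search-constrained
        out_bounds[n] = (-np.inf, np.inf)
    mle = ParameterVector(ordered, out_bounds)
    return FitResult(
        mle=mle, max_loglik=f_opt, k=k, converged=ok, n_evals=total_evals
    )
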