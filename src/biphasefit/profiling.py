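"""Univariate profile likelihoods, chi-squared thresholds and confidence intervals.

For an interest parameter ``psi`` the profile log-likelihood is the normalized
log-likelihood maximized over the remaining (nuisance) parameters at each fixed
value of ``psi``::

    lp(psi) = sup_lambda  [ l(psi, lambda) - l(theta_hat) ]

so that lp = 0 at the MLE and lp <= 0 everywhere. Profiles are evaluated on
two uniform meshes running outward from the MLE to the lower and upper bound
of the interest parameter (40 points per side by default, 80 mesh points plus
the MLE). Nuisance optimizations are warm-started: the first point of each
side starts from the MLE nuisance values, the second from the previous
optimum, and later points from a linear extrapolation of the previous two
optima, falling back to the previous optimum (then the MLE) when the
extrapolation leaves the bounds.

Likelihood-based confidence intervals follow from the asymptotic chi-squared
calibration of the likelihood-ratio statistic: the interval at confidence
``level`` collects the psi values whose profile lies above
``-0.5 * chi2.ppf(level, df=1)`` (−1.92, −3.32, −5.41 at 95/99/99.9%).
Endpoints are read off by linear interpolation between the two mesh points
straddling the threshold; an endpoint pinned at a bound whose profile is still
above the threshold marks practical non-identifiability at that level.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .inference import (
    SIGMA,
    Dataset,
    FitResult,
    _gaussian_loglik,
    _nelder_mead,
    _resolve_bounds,
    model_mean,
)
from .models import get_model

__all__ = [
    "ProfileMesh",
    "ProfileResult",
    "ConfidenceInterval",
    "build_mesh",
    "loglik_threshold",
    "profile_parameter",
    "confidence_interval",
]

DEFAULT_LEVELS = (0.95, 0.99, 0.999)


def loglik_threshold(level: float, df: int = 1) -> float:
    """Profile log-likelihood cutoff for a likelihood-ratio confidence set.

    ``-0.5 * chi2.ppf(level, df)``: −1.92, −3.32 and −5.41 (2 d.p.) for 95%,
    99% and 99.9% with one degree of freedom.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must lie strictly between 0 and 1")
    if df < 1:
        raise ValueError("degrees of freedom must be a positive integer")
    return -0.5 * float(stats.chi2.ppf(level, df))


@dataclass(frozen=True)
class ProfileMesh:
    """Interest-parameter mesh: two uniform outward legs plus the MLE value."""

    mle_value: float
    lower_side: np.ndarray  # outward: first point nearest the MLE, last = lower bound
    upper_side: np.ndarray  # outward: first point nearest the MLE, last = upper bound
    degenerate_lower: bool = False
    degenerate_upper: bool = False

    @property
    def sorted_values(self) -> np.ndarray:
        return np.concatenate([self.lower_side[::-1], [self.mle_value], self.upper_side])

    def outward(self):
        """Evaluation order: the MLE first, then each side walking outward."""
        yield self.mle_value
        yield from self.lower_side
        yield from self.upper_side

    def __len__(self) -> int:
        return 1 + self.lower_side.size + self.upper_side.size

    def __iter__(self):
        return self.outward()


def build_mesh(
    mle_value: float, lower: float, upper: float, points_per_side: int = 40
) -> ProfileMesh:
    """Uniform two-sided profile mesh from the MLE out to each bound.

    Each side holds ``points_per_side`` points excluding the MLE and including
    the bound. A side degenerates (empty, flagged) when the MLE sits exactly
    on that bound.
    """
    if not (lower <= mle_value <= upper):
        raise ValueError(
            f"MLE value {mle_value:g} outside bounds ({lower:g}, {upper:g})"
        )
    if points_per_side < 2:
        raise ValueError("points_per_side must be at least 2")
    if mle_value > lower:
        lower_side = np.linspace(mle_value, lower, points_per_side + 1)[1:]
        degenerate_lower = False
    else:
        lower_side = np.empty(0)
        degenerate_lower = True
    if mle_value < upper:
        upper_side = np.linspace(mle_value, upper, points_per_side + 1)[1:]
        degenerate_upper = False
    else:
        upper_side = np.empty(0)
        degenerate_upper = True
    return ProfileMesh(
        mle_value=float(mle_value),
        lower_side=lower_side,
        upper_side=upper_side,
        degenerate_lower=degenerate_lower,
        degenerate_upper=degenerate_upper,
    )


@dataclass(frozen=True)
class ConfidenceInterval:
    """Profile-likelihood interval with practical-identifiability flags."""

    level: float
    lower: float
    upper: float
    lower_at_bound: bool = False
    upper_at_bound: bool = False
    multimodal: bool = False

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper

    @property
    def width(self) -> float:
        return self.upper - self.lower


@dataclass(frozen=True)
class ProfileResult:
    """Profile log-likelihood of one interest parameter on its mesh.

    ``mesh`` is sorted ascending and contains the MLE value at ``mle_index``.
    ``profile_values`` are normalized (<= 0, equal to 0 at the MLE point);
    failed mesh points are NaN and treated as interpolation gaps.
    ``nuisance_optima[j]`` holds the optimized nuisance vector at mesh point j
    in the order of ``nuisance_names``.
    """

    interest_name: str
    mesh: np.ndarray
    profile_values: np.ndarray
    nuisance_names: tuple
    nuisance_optima: np.ndarray
    mle_value: float
    mle_index: int
    intervals: dict = field(default_factory=dict)
    n_failed: int = 0
    mle_improvement: float = 0.0
    degenerate_lower: bool = False
    degenerate_upper: bool = False

    def interval(self, level: float) -> ConfidenceInterval:
        if level in self.intervals:
            return self.intervals[level]
        return confidence_interval(self, level)


def confidence_interval(profile: ProfileResult, level: float) -> ConfidenceInterval:
    """Read a likelihood-ratio confidence interval off a computed profile.

    Endpoints come from linear interpolation between the two mesh points
    straddling the chi-squared threshold on each side of the MLE; if the
    profile at a bound is still above the threshold the endpoint is the bound
    itself and the corresponding flag is set. With multiple disjoint
    super-threshold regions the outermost crossings are reported and the
    interval is flagged multimodal.
    """
    thr = loglik_threshold(level)
    mesh = profile.mesh
    vals = profile.profile_values
    valid = np.isfinite(vals)
    if not np.any(vals[valid] >= thr):
        raise ValueError("profile lies entirely below the threshold")

    def scan(side_idx):
        """Outermost threshold crossing scanning from the outer end inward."""
        xs = mesh[side_idx][valid[side_idx]]
        vs = vals[side_idx][valid[side_idx]]
        above = vs >= thr
        if above[0]:
            return float(xs[0]), True
        j = int(np.argmax(above))  # first True; exists because MLE point is above
        x0, x1 = xs[j - 1], xs[j]
        v0, v1 = vs[j - 1], vs[j]
        return float(x0 + (thr - v0) / (v1 - v0) * (x1 - x0)), False

    i = profile.mle_index
    left = np.arange(0, i + 1)
    right = np.arange(mesh.size - 1, i - 1, -1)
    lower, lower_at_bound = scan(left)
    upper, upper_at_bound = scan(right)

    above_all = vals[valid] >= thr
    n_regions = int(np.sum(np.diff(above_all.astype(int)) == 1) + above_all[0])
    return ConfidenceInterval(
        level=level,
        lower=lower,
        upper=upper,
        lower_at_bound=lower_at_bound,
        upper_at_bound=upper_at_bound,
        multimodal=n_regions > 1,
    )


def profile_parameter(
    model,
    data: Dataset,
    fit: FitResult,
    interest_name: str,
    bounds: Mapping[str, tuple] | None = None,
    points_per_side: int = 40,
    levels: Sequence[float] = DEFAULT_LEVELS,
    fixed: Mapping[str, float] | None = None,
    concentrate_sigma: bool = False,
    solver: str = "rk2",
    step: float | None = None,
    xtol: float = 1e-8,
    ftol: float = 1e-8,
    maxfev: int = 100_000,
    max_failure_fraction: float = 0.2,
) -> ProfileResult:
    """Profile one parameter of a fitted model over its bounds.

    At each mesh point the interest parameter is held fixed and the remaining
    estimated parameters are re-optimized by bounded Nelder–Mead with the
    warm-start schedule described in the module docstring. ``fixed`` marks
    parameters that were held constant during the fit (they stay fixed here
    too). With ``concentrate_sigma`` the noise scale is recovered analytically
    as the RMS residual instead of being searched (exact; ignored when sigma
    itself is the interest parameter).

    Optimizer failures at individual mesh points are recorded as NaN gaps; if
    more than ``max_failure_fraction`` of the points fail, an error is raised.
    """
    model = get_model(model)
    fixed = dict(fixed or {})
    estimated = [n for n in list(model.param_names) + [SIGMA] if n not in fixed]
    if interest_name not in estimated:
        raise ValueError(
            f"interest parameter {interest_name!r} not among estimated parameters "
            f"{estimated}"
        )
    nuisance_names = [n for n in estimated if n != interest_name]
    concentrate = concentrate_sigma and interest_name != SIGMA and SIGMA in nuisance_names
    search_names = [n for n in nuisance_names if not (concentrate and n == SIGMA)]

    bound_map = _resolve_bounds(model, list(model.param_names) + [SIGMA], bounds)
    lo_i, hi_i = bound_map[interest_name]
    mesh_obj = build_mesh(fit.mle[interest_name], lo_i, hi_i, points_per_side)

    lower = np.array([bound_map[n][0] for n in search_names])
    upper = np.array([bound_map[n][1] for n in search_names])
    sigma_lo, sigma_hi = bound_map[SIGMA]

    y = data.observations
    t = data.times
    I = y.size
    mle_nuisance = np.array([fit.mle[n] for n in search_names])

    def make_objective(psi):
        def objective(x):
            p = dict(zip(search_names, x))
            p[interest_name] = psi
            p.update(fixed)
            try:
                mean = model_mean(model, p, t, solver=solver, step=step)
            except (RuntimeError, FloatingPointError, ValueError):
                return -np.inf
            resid = y - mean
            if concentrate:
                sig = float(np.clip(np.sqrt(resid @ resid / I), sigma_lo, sigma_hi))
            else:
                sig = p[SIGMA]
            return _gaussian_loglik(resid, max(sig, 1e-300))

        return objective

    def sigma_for(psi, x):
        if not concentrate:
            return None
        p = dict(zip(search_names, x))
        p[interest_name] = psi
        p.update(fixed)
        mean = model_mean(model, p, t, solver=solver, step=step)
        resid = y - mean
        return float(np.clip(np.sqrt(resid @ resid / I), sigma_lo, sigma_hi))

    n_failed = 0

    def run_side(side_values):
        nonlocal n_failed
        opts, logliks = [], []
        prev = None  # last successful optimum
        prev2 = None
        for j, psi in enumerate(side_values):
            if prev is None:
                x0 = mle_nuisance
            elif prev2 is None:
                x0 = prev
            else:
                x0 = 2.0 * prev - prev2  # linear extrapolation on the uniform mesh
                if np.any(x0 <= lower) or np.any(x0 >= upper):
                    x0 = prev
                if np.any(x0 <= lower) or np.any(x0 >= upper):
                    x0 = mle_nuisance
            try:
                objective = make_objective(psi)
                if search_names:
                    x_opt, f_opt, _, _ = _nelder_mead(
                        objective, x0, lower, upper, xtol, ftol, maxfev
                    )
                    # guard against simplex drift: the MLE nuisance values are
                    # a feasible candidate (and the exact optimum whenever the
                    # interest parameter does not interact with the nuisances)
                    f_mle = objective(mle_nuisance)
                    if f_mle >= f_opt:
                        x_opt, f_opt = mle_nuisance, f_mle
                else:
                    x_opt, f_opt = np.empty(0), objective(np.empty(0))
                if not np.isfinite(f_opt):
                    raise RuntimeError("non-finite profile value")
            except (RuntimeError, FloatingPointError, ValueError):
                n_failed += 1
                opts.append(np.full(len(search_names), np.nan))
                logliks.append(np.nan)
                continue
            prev2, prev = prev, x_opt
            opts.append(x_opt)
            logliks.append(f_opt)
        return opts, logliks

    lo_opts, lo_vals = run_side(mesh_obj.lower_side)
    hi_opts, hi_vals = run_side(mesh_obj.upper_side)

    total = len(mesh_obj.lower_side) + len(mesh_obj.upper_side)
    if total and n_failed > max_failure_fraction * total:
        raise RuntimeError(
            f"{n_failed}/{total} mesh-point optimizations failed while profiling "
            f"{interest_name!r}"
        )

    # assemble in ascending mesh order with the MLE point inserted
    mesh = mesh_obj.sorted_values
    mle_index = len(mesh_obj.lower_side)
    raw = np.concatenate([lo_vals[::-1], [fit.max_loglik], hi_vals])
    values = raw - fit.max_loglik

    nuis_rows = lo_opts[::-1] + [mle_nuisance] + hi_opts
    optima = np.array(nuis_rows) if search_names else np.empty((mesh.size, 0))
    if concentrate:
        sig_col = np.full(mesh.size, np.nan)
        for j in range(mesh.size):
            if np.isfinite(values[j]):
                sig_col[j] = (
                    fit.mle[SIGMA]
                    if j == mle_index
                    else sigma_for(mesh[j], optima[j])
                )
        optima = np.column_stack([optima, sig_col]) if optima.size else sig_col[:, None]
        out_names = tuple(search_names) + (SIGMA,)
    else:
        out_names = tuple(search_names)

    # an interior optimization may beat the recorded MLE; renormalize so the
    # profile never exceeds zero, and expose the improvement found
    finite = values[np.isfinite(values)]
    improvement = float(finite.max()) if finite.size else 0.0
    if improvement > 0:
        values = values - improvement

    result = ProfileResult(
        interest_name=interest_name,
        mesh=mesh,
        profile_values=values,
        nuisance_names=out_names,
        nuisance_optima=optima,
        mle_value=mesh_obj.mle_value,
        mle_index=mle_index,
        n_failed=n_failed,
        mle_improvement=max(improvement, 0.0),
        degenerate_lower=mesh_obj.degenerate_lower,
        degenerate_upper=mesh_obj.degenerate_upper,
    )
    intervals = {lvl: confidence_interval(result, lvl) for lvl in levels}
    return dataclasses.replace(result, intervals=intervals)
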