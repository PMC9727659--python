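"""Biphasic growth process models and their numerical / analytic solutions.

A biphasic model describes a population ``C(t)`` whose time derivative switches
from one rate law to another at a change point ``T``::

    dC/dt = f1(C)  for t <= T,
    dC/dt = f2(C)  for t >  T.

Models are represented by :class:`GrowthModel`: two autonomous rate functions,
an ordered list of process-parameter names (the initial condition ``C0`` is
always a parameter; the change point ``T`` is a parameter for every biphasic
model and absent for single-phase ones), and default box bounds per parameter.
Built-in models cover the delayed logistic (flat first phase, logistic second
phase), its normalized variant (carrying capacity fixed at 1), a
logistic–logistic model with distinct rates and capacities in each phase (as
used for tumour-spheroid formation and growth), and a plain single-phase
logistic.

Trajectories are computed either with a fixed-step second-order explicit
Runge–Kutta scheme (Heun's method) that splits the integration exactly at the
change point and at every requested output time, or — for the built-ins, where
each phase is solvable in closed form — analytically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "GrowthModel",
    "Trajectory",
    "SolverBlowupError",
    "make_builtin_model",
    "builtin_kinds",
    "register_model",
    "get_model",
    "solve_rk2",
    "closed_form_delayed_logistic",
]

RateFunction = Callable[[float, Mapping[str, float]], float]

_BUILTIN_KINDS = (
    "delayed_logistic",
    "delayed_normalized_logistic",
    "biphasic_logistic",
    "single_phase_logistic",
)


class SolverBlowupError(RuntimeError):
    """Raised when the ODE state becomes non-finite during integration."""

    def __init__(self, time: float, params: Mapping[str, float]):
        self.time = time
        self.params = dict(params)
        super().__init__(
            f"non-finite state encountered at t={time:g} with parameters {self.params}"
        )


@dataclass(frozen=True)
class Trajectory:
    """Model state ``C(t)`` evaluated on a strictly increasing time grid."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if times.ndim != 1 or values.ndim != 1:
            raise ValueError("times and values must be one-dimensional")
        if times.size != values.size:
            raise ValueError("times and values must have equal length")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(values)):
            raise ValueError("trajectory values must be finite")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class GrowthModel:
    """A named biphasic process model.

    Parameters
    ----------
    name : str
        Identifier used in configs and on the command line.
    phase1_rate, phase2_rate : callable ``(C, params) -> dC/dt``
        Autonomous rate laws before and after the change point. For
        single-phase models both callables coincide and ``"T"`` is absent
        from ``param_names`` (interpreted as a change point at t = 0).
    param_names : tuple of str
        Ordered process-parameter names. ``"C0"`` (initial condition) is
        mandatory; ``"T"`` (change point) is present for biphasic models.
    default_bounds : dict
        Per-parameter ``(lower, upper)`` pairs in model units; deliberately
        broad, meant to be overridden per dataset.
    closed_form : callable ``(params, times) -> values``, optional
        Exact solution, available for the built-ins; used by fast code paths
        and as an oracle for the numerical integrator.
    """

    name: str
    phase1_rate: RateFunction
    phase2_rate: RateFunction
    param_names: tuple
    default_bounds: Mapping[str, tuple] = field(default_factory=dict)
    closed_form: Callable[[Mapping[str, float], np.ndarray], np.ndarray] | None = None

    def __post_init__(self):
        names = tuple(self.param_names)
        if len(set(names)) != len(names):
            raise ValueError("param_names must be unique")
        if "C0" not in names:
            raise ValueError('param_names must include the initial condition "C0"')
        for pname, (lo, hi) in dict(self.default_bounds).items():
            if not lo < hi:
                raise ValueError(f"bound for {pname!r} must satisfy lower < upper")
        object.__setattr__(self, "param_names", names)
        object.__setattr__(self, "default_bounds", dict(self.default_bounds))

    @property
    def has_change_point(self) -> bool:
        return "T" in self.param_names

    def change_point(self, params: Mapping[str, float]) -> float:
        """Change-point time; 0 for single-phase models."""
        return float(params.get("T", 0.0)) if self.has_change_point else 0.0

    def rate(self, C: float, t: float, params: Mapping[str, float]) -> float:
        """Instantaneous rate at state ``C`` and time ``t``."""
        if t <= self.change_point(params):
            return self.phase1_rate(C, params)
        return self.phase2_rate(C, params)


def _logistic_at(C0: float, r: float, K: float, dt: np.ndarray) -> np.ndarray:
    """Logistic solution K*C0 / (C0 + (K - C0) exp(-r dt)) for dt >= 0."""
    dt = np.asarray(dt, dtype=float)
    return K * C0 / (C0 + (K - C0) * np.exp(-r * dt))


def closed_form_delayed_logistic(
    params: Mapping[str, float], output_times: Sequence[float]
) -> Trajectory:
    """Exact solution of the delayed logistic model.

    ``C(t) = C(0)`` for ``t <= T`` and
    ``C(t) = K C(0) / [C(0) + (K - C(0)) exp(-r (t - T))]`` for ``t > T``.
    """
    T = float(params.get("T", 0.0))
    C0 = float(params["C0"])
    r = float(params["r"])
    K = float(params.get("K", 1.0))
    if K <= 0:
        raise ValueError("carrying capacity K must be positive")
    if C0 <= 0:
        raise ValueError("initial condition C0 must be positive")
    t = np.asarray(output_times, dtype=float)
    values = np.where(t <= T, C0, _logistic_at(C0, r, K, np.maximum(t - T, 0.0)))
    return Trajectory(times=t, values=values)


def _delayed_logistic_values(params, t):
    T = float(params.get("T", 0.0))
    C0 = float(params["C0"])
    r = float(params["r"])
    K = float(params.get("K", 1.0))
    return np.where(t <= T, C0, _logistic_at(C0, r, K, np.maximum(t - T, 0.0)))


def _normalized_logistic_values(params, t):
    p = dict(params)
    p["K"] = 1.0
    return _delayed_logistic_values(p, t)


def _biphasic_logistic_values(params, t):
    T = float(params["T"])
    C0 = float(params["C0"])
    r1, r2 = float(params["r1"]), float(params["r2"])
    K1, K2 = float(params["K1"]), float(params["K2"])
    t = np.asarray(t, dtype=float)
    CT = float(_logistic_at(C0, r1, K1, max(T, 0.0)))
    phase1 = _logistic_at(C0, r1, K1, np.clip(t, 0.0, max(T, 0.0)))
    phase2 = _logistic_at(CT, r2, K2, np.maximum(t - T, 0.0))
    return np.where(t <= T, phase1, phase2)


def _single_phase_logistic_values(params, t):
    C0 = float(params["C0"])
    r = float(params["r"])
    K = float(params["K"])
    return _logistic_at(C0, r, K, np.maximum(np.asarray(t, dtype=float), 0.0))


def _zero_rate(C, p):
    return 0.0


def _logistic_rate(C, p):
    return p["r"] * C * (1.0 - C / p["K"])


def _normalized_logistic_rate(C, p):
    return p["r"] * C * (1.0 - C)


def _logistic_rate_1(C, p):
    return p["r1"] * C * (1.0 - C / p["K1"])


def _logistic_rate_2(C, p):
    return p["r2"] * C * (1.0 - C / p["K2"])


def _build_builtin(kind: str) -> GrowthModel:
    if kind == "delayed_logistic":
        return GrowthModel(
            name=kind,
            phase1_rate=_zero_rate,
            phase2_rate=_logistic_rate,
            param_names=("T", "C0", "r", "K"),
            default_bounds={
                "T": (0.0, 10000.0),
                "C0": (1e-3, 1000.0),
                "r": (1e-6, 10.0),
                "K": (1e-3, 1000.0),
            },
            closed_form=_delayed_logistic_values,
        )
    if kind == "delayed_normalized_logistic":
        return GrowthModel(
            name=kind,
            phase1_rate=_zero_rate,
            phase2_rate=_normalized_logistic_rate,
            param_names=("T", "C0", "r"),
            default_bounds={
                "T": (0.0, 1000.0),
                "C0": (1e-6, 1.0),
                "r": (1e-6, 10.0),
            },
            closed_form=_normalized_logistic_values,
        )
    if kind == "biphasic_logistic":
        return GrowthModel(
            name=kind,
            phase1_rate=_logistic_rate_1,
            phase2_rate=_logistic_rate_2,
            param_names=("T", "C0", "r1", "r2", "K1", "K2"),
            default_bounds={
                "T": (0.0, 1000.0),
                "C0": (1e-3, 5000.0),
                "r1": (1e-6, 10.0),
                "r2": (1e-6, 10.0),
                "K1": (1e-3, 5000.0),
                "K2": (1e-3, 5000.0),
            },
            closed_form=_biphasic_logistic_values,
        )
    if kind == "single_phase_logistic":
        return GrowthModel(
            name=kind,
            phase1_rate=_logistic_rate,
            phase2_rate=_logistic_rate,
            param_names=("C0", "r", "K"),
            default_bounds={
                "C0": (1e-3, 1000.0),
                "r": (1e-6, 10.0),
                "K": (1e-3, 1000.0),
            },
            closed_form=_single_phase_logistic_values,
        )
    raise ValueError(
        f"unknown model kind {kind!r}; valid kinds are {', '.join(_BUILTIN_KINDS)}"
    )


def make_builtin_model(kind: str) -> GrowthModel:
    """Return one of the built-in biphasic growth models by name."""
    return _build_builtin(kind)


def builtin_kinds() -> tuple:
    """Names of the built-in model kinds."""
    return _BUILTIN_KINDS


_REGISTRY: dict = {}


def register_model(model: GrowthModel, overwrite: bool = False) -> GrowthModel:
    """Register a custom model so it can be selected by name (e.g. in the CLI)."""
    if model.name in _BUILTIN_KINDS:
        raise ValueError(f"{model.name!r} shadows a built-in model kind")
    if model.name in _REGISTRY and not overwrite:
        raise ValueError(f"model {model.name!r} already registered")
    _REGISTRY[model.name] = model
    return model


def get_model(name_or_model) -> GrowthModel:
    """Resolve a model given by name (built-in or registered) or pass through."""
    if isinstance(name_or_model, GrowthModel):
        return name_or_model
    if name_or_model in _REGISTRY:
        return _REGISTRY[name_or_model]
    return make_builtin_model(name_or_model)


def _heun_segment(model, params, rate, t0, t1, C, step):
    """Integrate C' = rate(C) over [t0, t1] with Heun steps of size <= step."""
    span = t1 - t0
    if span <= 0:
        return C
    n = max(1, math.ceil(span / step - 1e-12))
    h = span / n
    for _ in range(n):
        k1 = rate(C, params)
        k2 = rate(C + h * k1, params)
        C = C + 0.5 * h * (k1 + k2)
    return C


def solve_rk2(
    model: GrowthModel,
    params: Mapping[str, float],
    output_times: Sequence[float],
    step: float | None = None,
) -> Trajectory:
    """Solve a growth model with Heun's second-order explicit Runge–Kutta method.

    Integration starts at ``t = 0`` with ``C(0) = params["C0"]``. The step
    sequence is split so that the change point ``T`` and every output time are
    landed on exactly — no step ever straddles the rate discontinuity at ``T``.

    Parameters
    ----------
    model, params : model and its process parameters.
    output_times : strictly increasing times (>= 0) at which to report the state.
    step : maximum step size; default is 1/1000 of the output horizon.

    Raises
    ------
    SolverBlowupError
        If the state becomes non-finite, reporting the time and parameters.
    """
    t_out = np.asarray(output_times, dtype=float)
    if t_out.ndim != 1 or t_out.size == 0:
        raise ValueError("output_times must be a non-empty 1-d sequence")
    if np.any(t_out < 0):
        raise ValueError("output times must be non-negative")
    if t_out.size > 1 and not np.all(np.diff(t_out) > 0):
        raise ValueError("output_times must be strictly increasing")

    horizon = float(t_out[-1]) if t_out[-1] > 0 else 1.0
    if step is None:
        step = horizon / 1000.0
    if step <= 0:
        raise ValueError("step must be positive")

    T = model.change_point(params)
    breakpoints = set(t_out.tolist())
    if 0.0 < T < horizon:
        breakpoints.add(T)
    breakpoints.add(0.0)
    grid = np.array(sorted(breakpoints))

    C = float(params["C0"])
    out = {}
    if grid[0] == 0.0 and 0.0 in breakpoints:
        out[0.0] = C
    for a, b in zip(grid[:-1], grid[1:]):
        # segment [a, b] never straddles T: phase 1 iff the segment ends at or
        # before the change point (the rate law applies for t <= T)
        rate = model.phase1_rate if b <= T else model.phase2_rate
        C = _heun_segment(model, params, rate, a, b, C, step)
        if not np.isfinite(C):
            raise SolverBlowupError(b, params)
        out[float(b)] = C
    values = np.array([out[float(t)] for t in t_out])
    return Trajectory(times=t_out, values=values)
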