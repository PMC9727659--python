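"""scikit-learn-style estimator wrapping the full biphasic-growth workflow.

:class:`BiphasicGrowthMLE` is a regressor: ``X`` is a column of observation
times, ``y`` the measurements. ``fit`` computes the bounded Nelder–Mead MLE,
``predict`` evaluates the fitted mean trajectory, and further methods expose
profile likelihoods, confidence intervals, parameter-wise prediction
envelopes and the AIC. It composes with sklearn tooling (``get_params`` /
``set_params``, cloning, pipelines); the functional API in the sibling
modules does the numerical work.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .inference import SIGMA, Dataset, fit_mle, model_mean, normalized_log_likelihood
from .models import get_model
from .prediction import parameterwise_prediction, prediction_grid, union_envelope
from .profiling import DEFAULT_LEVELS, profile_parameter
from .selection import aic as _aic

__all__ = ["BiphasicGrowthMLE"]


class BiphasicGrowthMLE(RegressorMixin, BaseEstimator):
    """Maximum-likelihood biphasic growth model with profile-likelihood UQ.

    Parameters
    ----------
    model : str or GrowthModel, default "delayed_logistic"
        Process model (built-in kind name or a custom :class:`GrowthModel`).
    start : dict
        Starting values for every estimated parameter (``sigma`` included
        unless fixed or concentrated). Required before calling ``fit``.
    bounds : dict, optional
        Per-parameter ``(lower, upper)`` overrides of the model defaults.
    fixed : dict, optional
        Parameters held constant (excluded from the estimated vector).
    solver : {"rk2", "closed_form", "auto"}, default "rk2"
        Trajectory solver used inside the likelihood.
    step : float, optional
        RK2 step size (default: 1/1000 of the observation horizon).
    concentrate_sigma : bool, default False
        Recover sigma analytically (RMS residual) instead of searching it.
    points_per_side : int, default 40
        Profile mesh points per side.
    levels : tuple, default (0.95, 0.99, 0.999)
        Confidence levels for profile intervals.
    multistart : int, default 0
        Extra uniform random starts for the MLE search.
    random_state : int, optional
        Seed for multistart draws.

    Attributes
    ----------
    model_ : GrowthModel
    fit_result_ : FitResult
    mle_ : dict  — fitted parameter values (sigma included)
    max_loglik_ : float
    k_ : int  — number of estimated parameters
    converged_ : bool
    profiles_ : dict  — cached ProfileResult per profiled parameter
    """

    def __init__(
        self,
        model="delayed_logistic",
        start=None,
        bounds=None,
        fixed=None,
        solver="rk2",
        step=None,
        concentrate_sigma=False,
        points_per_side=40,
        levels=DEFAULT_LEVELS,
        multistart=0,
        random_state=None,
    ):
        self.model = model
        self.start = start
        self.bounds = bounds
        self.fixed = fixed
        self.solver = solver
        self.step = step
        self.concentrate_sigma = concentrate_sigma
        self.points_per_side = points_per_side
        self.levels = levels
        self.multistart = multistart
        self.random_state = random_state

    @staticmethod
    def _times(X) -> np.ndarray:
        t = np.asarray(X, dtype=float)
        if t.ndim == 2:
            if t.shape[1] != 1:
                raise ValueError("X must be a single column of observation times")
            t = t[:, 0]
        elif t.ndim != 1:
            raise ValueError("X must be 1-d or a single-column 2-d array")
        return t

    def fit(self, X, y):
        """Fit the MLE to observation times ``X`` and measurements ``y``."""
        if self.start is None:
            raise ValueError("start values are required (set start=...)")
        t = self._times(X)
        y = np.asarray(y, dtype=float)
        order = np.argsort(t, kind="stable")
        data = Dataset(times=t[order], observations=y[order])
        self.model_ = get_model(self.model)
        self.data_ = data
        self.fit_result_ = fit_mle(
            self.model_,
            data,
            start=self.start,
            bounds=self.bounds,
            fixed=self.fixed,
            concentrate_sigma=self.concentrate_sigma,
            solver=self.solver,
            step=self.step,
            multistart=self.multistart,
            seed=self.random_state,
        )
        self.mle_ = self.fit_result_.mle.as_dict()
        self.max_loglik_ = self.fit_result_.max_loglik
        self.k_ = self.fit_result_.k
        self.converged_ = self.fit_result_.converged
        self.profiles_ = {}
        self.n_features_in_ = 1
        return self

    def predict(self, X) -> np.ndarray:
        """Fitted mean trajectory at the given times."""
        check_is_fitted(self, "fit_result_")
        t = self._times(X)
        order = np.argsort(t, kind="stable")
        out = np.empty_like(t)
        out[order] = model_mean(
            self.model_, self.mle_, t[order], solver=self.solver, step=self.step
        )
        return out

    def normalized_log_likelihood(self, params=None) -> float:
        """Normalized log-likelihood at ``params`` (default: the MLE, where
        it equals 0)."""
        check_is_fitted(self, "fit_result_")
        p = dict(self.mle_) if params is None else {**self.mle_, **dict(params)}
        return normalized_log_likelihood(
            p, self.data_, self.model_, self.fit_result_,
            solver=self.solver, step=self.step,
        )

    def profile(self, name: str, **kwargs):
        """Profile likelihood for one parameter (cached per name)."""
        check_is_fitted(self, "fit_result_")
        if name not in self.profiles_ or kwargs:
            result = profile_parameter(
                self.model_,
                self.data_,
                self.fit_result_,
                name,
                bounds=self.bounds,
                points_per_side=kwargs.pop("points_per_side", self.points_per_side),
                levels=kwargs.pop("levels", self.levels),
                fixed=self.fixed,
                concentrate_sigma=kwargs.pop(
                    "concentrate_sigma", self.concentrate_sigma
                ),
                solver=self.solver,
                step=self.step,
                **kwargs,
            )
            self.profiles_[name] = result
        return self.profiles_[name]

    def profile_all(self, **kwargs) -> dict:
        """Profiles for every estimated parameter."""
        check_is_fitted(self, "fit_result_")
        fixed = dict(self.fixed or {})
        names = [
            n for n in list(self.model_.param_names) + [SIGMA] if n not in fixed
        ]
        return {n: self.profile(n, **kwargs) for n in names}

    def confidence_intervals(self, level: float = 0.95, **kwargs) -> pd.DataFrame:
        """Profile confidence intervals for every estimated parameter."""
        rows = []
        for name, prof in self.profile_all(**kwargs).items():
            ci = prof.interval(level)
            rows.append(
                {
                    "parameter": name,
                    "mle": self.mle_[name],
                    "lower": ci.lower,
                    "upper": ci.upper,
                    "lower_at_bound": ci.lower_at_bound,
                    "upper_at_bound": ci.upper_at_bound,
                    "multimodal": ci.multimodal,
                }
            )
        return pd.DataFrame(rows).set_index("parameter")

    def prediction_envelope(self, names=None, grid=None, level=0.95, **kwargs):
        """Parameter-wise prediction envelope for one parameter, or the union
        over several (default: all estimated parameters)."""
        check_is_fitted(self, "fit_result_")
        if grid is None:
            grid = prediction_grid(self.data_.times)
        if isinstance(names, str):
            names = [names]
        if names is None:
            fixed = dict(self.fixed or {})
            names = [
                n for n in list(self.model_.param_names) + [SIGMA] if n not in fixed
            ]
        envelopes = [
            parameterwise_prediction(
                self.profile(n, **kwargs),
                self.model_,
                self.fit_result_,
                grid,
                level=level,
                solver=self.solver,
                step=self.step,
            )
            for n in names
        ]
        return envelopes[0] if len(envelopes) == 1 else union_envelope(envelopes)

    def aic(self) -> float:
        """Akaike information criterion of the fit."""
        check_is_fitted(self, "fit_result_")
        return _aic(self.fit_result_)
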