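"""Parametric survival: log-logistic curves, hazard-ratio adjustment, and
maximum-likelihood fitting with AIC/BIC model selection.

The central object is :class:`SurvivalCurve`, a survival function over
model-cycle time.  Extrapolated curves come from the log-logistic family

    S(t) = 1 / (1 + lam * t**kappa)

with ``lam`` resolved from a (theta, kappa) pair either directly
(``lambda_direct``, lam = theta) or as ``exp_theta`` (lam = exp(theta)).
Alternative treatment arms are derived by powering a reference curve with
a hazard ratio, S_alt(t) = S(t)**HR, i.e. proportional hazards.
"""
from __future__ import annotations

import dataclasses
import math
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LogLogisticParams",
    "SurvivalCurve",
    "FitResult",
    "FitError",
    "loglogistic_survival",
    "loglogistic_median",
    "curve_from_shape_params",
    "apply_hazard_ratio",
    "fit_parametric",
    "select_best_fit",
    "FAMILIES",
]


class FitError(RuntimeError):
    """A parametric fit could not be computed."""


@dataclasses.dataclass(frozen=True)
class LogLogisticParams:
    """(theta, kappa) shape pair of an extrapolated OS or PFS curve."""

    theta: float
    kappa: float

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")

    def lam(self, form: str = "lambda_direct") -> float:
        if form == "lambda_direct":
            return self.theta
        if form == "exp_theta":
            return math.exp(self.theta)
        raise ValueError(f"unknown log-logistic form {form!r}")


def loglogistic_survival(params: LogLogisticParams, t, form: str = "lambda_direct"):
    """S(t) = 1 / (1 + lam * t**kappa); t >= 0 in the curve's native unit."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    lam = params.lam(form)
    out = 1.0 / (1.0 + lam * np.power(t, params.kappa))
    return out if out.ndim else float(out)


def loglogistic_median(params: LogLogisticParams, form: str = "lambda_direct") -> float:
    """Time at which S(t) = 0.5: (1/lam)**(1/kappa)."""
    return (1.0 / params.lam(form)) ** (1.0 / params.kappa)


@dataclasses.dataclass(frozen=True)
class SurvivalCurve:
    """A survival probability function of model-cycle time.

    ``provenance`` records how the curve was produced
    (fitted | table | hr-adjusted | life-table-blended | grid).
    """

    fn: Callable[[np.ndarray], np.ndarray]
    provenance: str = "table"

    def __call__(self, t):
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0):
            raise ValueError("survival time must be >= 0")
        s = np.clip(self.fn(t_arr), 0.0, 1.0)
        return s if s.ndim else float(s)

    def power(self, hr: float) -> "SurvivalCurve":
        if hr <= 0:
            raise ValueError("hazard ratio must be > 0")
        base = self.fn
        return SurvivalCurve(
            fn=lambda t: np.power(np.clip(base(t), 0.0, 1.0), hr),
            provenance="hr-adjusted",
        )

    @classmethod
    def from_grid(
        cls, t_grid: np.ndarray, s_grid: np.ndarray, provenance: str = "grid"
    ) -> "SurvivalCurve":
        t_grid = np.asarray(t_grid, float)
        s_grid = np.asarray(s_grid, float)
        return cls(
            fn=lambda t: np.interp(t, t_grid, s_grid, left=1.0, right=s_grid[-1]),
            provenance=provenance,
        )


def curve_from_shape_params(
    params: LogLogisticParams,
    form: str = "lambda_direct",
    time_unit: str = "cycles",
    cycle_days: float = 21.0,
) -> SurvivalCurve:
    """Log-logistic curve as a function of model cycles.

    ``time_unit`` is the unit of t inside the formula: with "months" the
    cycle index is converted to months (cycle_days/30.44 months per cycle)
    before evaluation.
    """
    if time_unit == "cycles":
        scale = 1.0
    elif time_unit == "months":
        scale = cycle_days / 30.44
    else:
        raise ValueError(f"unknown time unit {time_unit!r}")
    return SurvivalCurve(
        fn=lambda t: loglogistic_survival(params, np.asarray(t, float) * scale, form),
        provenance="table",
    )


def apply_hazard_ratio(curve: SurvivalCurve, hr: float) -> SurvivalCurve:
    """Proportional-hazards adjustment: t -> S(t)**hr."""
    return curve.power(hr)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class FitResult:
    family: str
    params: dict[str, float]
    loglik: float
    aic: float
    bic: float
    n: int

    @property
    def k(self) -> int:
        return len(self.params)


def _lifelines_fitters():
    from lifelines import (
        ExponentialFitter,
        LogLogisticFitter,
        LogNormalFitter,
        WeibullFitter,
    )
    from lifelines.fitters import ParametricUnivariateFitter

    class GompertzFitter(ParametricUnivariateFitter):
        """Gompertz with increasing hazard: H(t) = (a/b) * (exp(b t) - 1)."""

        _fitted_parameter_names = ["a_", "b_"]
        _bounds = [(1e-9, None), (1e-9, None)]

        def _cumulative_hazard(self, params, times):
            a, b = params
            # cap the exponent so far-off optimizer steps stay finite
            return (a / b) * (np.expm1(np.minimum(b * times, 500.0)))

    return {
        "exponential": ExponentialFitter,
        "weibull": WeibullFitter,
        "lognormal": LogNormalFitter,
        "loglogistic": LogLogisticFitter,
        "gompertz": GompertzFitter,
    }


FAMILIES = ("exponential", "weibull", "lognormal", "loglogistic", "gompertz")


def _standardize_params(family: str, fitter) -> dict[str, float]:
    if family == "exponential":
        # lifelines parameterizes by the mean (lambda_ = scale)
        return {"rate": 1.0 / float(fitter.lambda_)}
    if family == "weibull":
        return {"scale": float(fitter.lambda_), "shape": float(fitter.rho_)}
    if family == "lognormal":
        return {"mu": float(fitter.mu_), "sigma": float(fitter.sigma_)}
    if family == "loglogistic":
        alpha, beta = float(fitter.alpha_), float(fitter.beta_)
        # S(t) = 1/(1 + (t/alpha)^beta)  =>  lam = alpha^-beta, kappa = beta
        return {"lam": alpha ** (-beta), "kappa": beta}
    if family == "gompertz":
        return {"a": float(fitter.a_), "b": float(fitter.b_)}
    raise ValueError(f"unknown family {family!r}")


def fit_parametric(data: pd.DataFrame, family: str) -> FitResult:
    """Maximum-likelihood fit of one parametric family to pseudo-IPD.

    ``data`` must have columns ``time_months`` (or ``time``) and ``event``
    (1 = event, 0 = right-censored).  Censored records contribute their
    survival probability to the likelihood (handled by lifelines).
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
    col = "time_months" if "time_months" in data.columns else "time"
    times = np.asarray(data[col], dtype=float)
    events = np.asarray(data["event"], dtype=int)
    if len(times) < 10:
        raise FitError("need at least 10 records to fit")
    if np.any(times <= 0):
        raise FitError("all times must be > 0")
    if not np.any(events == 1):
        raise FitError("all records censored; the likelihood is unbounded")
    if not set(np.unique(events)) <= {0, 1}:
        raise FitError("event must be 0 or 1")

    from lifelines.exceptions import ConvergenceError

    fitter_cls = _lifelines_fitters()[family]
    fitter = fitter_cls()
    try:
        fitter.fit(times, event_observed=events)
    except ConvergenceError as exc:  # pragma: no cover - data dependent
        raise FitError(f"{family} fit did not converge: {exc}") from exc

    n = len(times)
    loglik = float(fitter.log_likelihood_)
    k = len(fitter._fitted_parameter_names)
    return FitResult(
        family=family,
        params=_standardize_params(family, fitter),
        loglik=loglik,
        aic=2 * k - 2 * loglik,
        bic=k * math.log(n) - 2 * loglik,
        n=n,
    )


def select_best_fit(results: Sequence[FitResult]) -> FitResult:
    """Minimum-AIC result; ties broken by minimum BIC, then fewer parameters."""
    results = list(results)
    if not results:
        raise ValueError("no fit results to select from")
    if len({r.n for r in results}) > 1:
        raise ValueError("fit results come from different datasets (mismatched n)")
    return min(results, key=lambda r: (round(r.aic, 9), round(r.bic, 9), r.k))
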