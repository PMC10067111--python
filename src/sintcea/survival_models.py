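"""Parametric survival curves and their conversion to per-cycle transition
probabilities.

Five families are supported, in the parameterizations most common in published
Chinese cost-effectiveness models:

=============  =============  =========================================
family         parameters     survivor function S(t)
=============  =============  =========================================
exponential    (lam,)         exp(-lam * t)
weibull        (lam, gamma)   exp(-lam * t**gamma)
loglogistic    (theta, kappa) 1 / (1 + theta * t**kappa)
lognormal      (mu, sigma)    1 - Phi((log t - mu) / sigma)
gompertz       (shape, rate)  exp(-rate/shape * (exp(shape*t) - 1))
=============  =============  =========================================

The time axis is whatever unit the parameters were fitted on (the shipped
fixture uses model cycles); all functions here are unit-agnostic.  Survivor
functions are evaluated in log space so that transition probabilities remain
accurate deep in the tail.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "FAMILIES",
    "ParametricSurvival",
    "ValidationError",
    "DegenerateStateError",
    "survival",
    "cycle_transition_prob",
]

FAMILIES = ("exponential", "weibull", "loglogistic", "lognormal", "gompertz")

_N_PARAMS = {
    "exponential": 1,
    "weibull": 2,
    "loglogistic": 2,
    "lognormal": 2,
    "gompertz": 2,
}

_LOG_S_FLOOR = -745.0  # below exp() underflow


class ValidationError(ValueError):
    """Raised for invalid distribution parameters or out-of-domain inputs."""


class DegenerateStateError(ValueError):
    """Raised when a conditional transition probability is requested at a
    time where the survivor function has already vanished."""


def _validate(family: str, params: Sequence[float]) -> None:
    if family not in FAMILIES:
        raise ValidationError(f"unknown survival family {family!r}")
    params = tuple(float(p) for p in params)
    if len(params) != _N_PARAMS[family]:
        raise ValidationError(
            f"{family} expects {_N_PARAMS[family]} parameters, got {len(params)}"
        )
    if family == "exponential" and params[0] <= 0:
        raise ValidationError("exponential rate must be positive")
    elif family == "weibull" and (params[0] <= 0 or params[1] <= 0):
        raise ValidationError("weibull (lam, gamma) must both be positive")
    elif family == "loglogistic" and (params[0] <= 0 or params[1] <= 0):
        raise ValidationError("loglogistic (theta, kappa) must both be positive")
    elif family == "lognormal" and params[1] <= 0:
        raise ValidationError("lognormal sigma must be positive")
    elif family == "gompertz" and params[1] <= 0:
        raise ValidationError("gompertz rate must be positive")


@dataclass(frozen=True)
class ParametricSurvival:
    """A named survival-distribution family with its parameter vector."""

    family: str
    params: tuple

    def __post_init__(self):
        _validate(self.family, self.params)
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))

    # -- core evaluations --------------------------------------------------

    def log_survival(self, t):
        """log S(t); vectorized over t, requires t >= 0."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValidationError("survival time must be non-negative")
        p = self.params
        if self.family == "exponential":
            out = -p[0] * t
        elif self.family == "weibull":
            out = -p[0] * np.power(t, p[1])
        elif self.family == "loglogistic":
            out = -np.log1p(p[0] * np.power(t, p[1]))
        elif self.family == "lognormal":
            with np.errstate(divide="ignore"):
                z = np.where(t > 0, (np.log(np.where(t > 0, t, 1.0)) - p[0]) / p[1], -np.inf)
            out = stats.norm.logsf(z)
        else:  # gompertz
            shape, rate = p
            if abs(shape) < 1e-12:
                out = -rate * t
            else:
                out = -rate / shape * np.expm1(shape * t)
        return np.maximum(out, _LOG_S_FLOOR) if out.ndim else max(float(out), _LOG_S_FLOOR)

    def survival(self, t):
        """S(t) in [0, 1] with S(0) = 1."""
        return np.exp(self.log_survival(t))

    def log_pdf(self, t):
        """log f(t) for strictly positive event times (used by the MLE)."""
        t = np.asarray(t, dtype=float)
        if np.any(t <= 0):
            raise ValidationError("event density requires strictly positive times")
        p = self.params
        if self.family == "exponential":
            return np.log(p[0]) - p[0] * t
        if self.family == "weibull":
            lam, gam = p
            return np.log(lam * gam) + (gam - 1) * np.log(t) - lam * np.power(t, gam)
        if self.family == "loglogistic":
            th, ka = p
            u = th * np.power(t, ka)
            return np.log(th * ka) + (ka - 1) * np.log(t) - 2 * np.log1p(u)
        if self.family == "lognormal":
            mu, sig = p
            z = (np.log(t) - mu) / sig
            return stats.norm.logpdf(z) - np.log(t * sig)
        shape, rate = p
        log_h = np.log(rate) + shape * t
        return log_h + self.log_survival(t)

    def quantile(self, q):
        """Inverse CDF: the time t with 1 - S(t) = q.

        Closed form for every family; returns +inf where an improper
        distribution (negative Gompertz shape) never reaches q.
        """
        q = np.asarray(q, dtype=float)
        if np.any((q < 0) | (q >= 1)):
            raise ValidationError("quantile level must lie in [0, 1)")
        s = 1.0 - q  # target survivor value
        p = self.params
        if self.family == "exponential":
            return -np.log(s) / p[0]
        if self.family == "weibull":
            return np.power(-np.log(s) / p[0], 1.0 / p[1])
        if self.family == "loglogistic":
            return np.power((1.0 / s - 1.0) / p[0], 1.0 / p[1])
        if self.family == "lognormal":
            return np.exp(p[0] + p[1] * stats.norm.ppf(q))
        shape, rate = p
        if abs(shape) < 1e-12:
            return -np.log(s) / rate
        arg = 1.0 - shape / rate * np.log(s)
        with np.errstate(invalid="ignore"):
            out = np.where(arg > 0, np.log(np.maximum(arg, 1e-300)) / shape, np.inf)
        return out

    def median(self) -> float:
        return float(self.quantile(0.5))


def survival(dist: ParametricSurvival, t) -> float:
    """S(t) for a single time point (module-level convenience)."""
    return dist.survival(t)


def cycle_transition_prob(dist: ParametricSurvival, t, u) -> float:
    """Probability of the event within (t, t + u] conditional on survival to t.

    tp(t) = 1 - S(t + u) / S(t), computed in log space.  ``t`` is the state
    clock and ``u`` the cycle length, on the distribution's own time scale.
    """
    t_arr = np.asarray(t, dtype=float)
    u = float(u)
    if np.any(t_arr < 0):
        raise ValidationError("state clock must be non-negative")
    if u <= 0:
        raise ValidationError("cycle length must be positive")
    log_s_t = dist.log_survival(t_arr)
    if np.any(np.asarray(log_s_t) <= _LOG_S_FLOOR):
        raise DegenerateStateError(
            "survivor function vanished; state must be treated as absorbed"
        )
    tp = -np.expm1(dist.log_survival(t_arr + u) - log_s_t)
    return np.clip(tp, 0.0, 1.0)
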