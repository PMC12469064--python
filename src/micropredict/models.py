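"""Primary growth and inactivation models.

Growth models describe the sigmoidal rise of a microbial population under
constant conditions; inactivation models describe its decline under a
stressor.  Two log conventions coexist in the field and both appear here:
the modified Gompertz and Logistic models operate on log10 counts
(log CFU/g) with rate ``rmax`` in log10 units per hour, while the
Baranyi-Roberts and Huang models operate on natural-log counts with the
maximum specific growth rate ``mumax`` in 1/h.  The two rates are related
by ``mumax = rmax * ln(10)``.

Inactivation models operate on log10 counts with time in seconds.

All evaluators accept scalar or array time and are overflow-safe: every
exponential of a potentially large argument is evaluated in shifted
(log-sum-exp) form.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ParameterError

LN10 = float(np.log(10.0))

__all__ = [
    "LN10",
    "GrowthParamsLog10",
    "GrowthParamsLn",
    "InhibitionParams",
    "eval_gompertz",
    "eval_logistic",
    "eval_baranyi",
    "eval_huang",
    "eval_loglinear",
    "eval_loglinear_tail",
    "eval_weibull",
    "rmax_to_mumax",
    "mumax_to_rmax",
]


@dataclass(frozen=True)
class GrowthParamsLog10:
    """Parameters of log10-scale growth models (modified Gompertz, Logistic).

    Attributes
    ----------
    x0 : initial population, log10 CFU/g
    xmax : maximum population, log10 CFU/g
    rmax : maximum growth rate, log10 CFU/g per h
    lag : lag-phase duration, h
    """

    x0: float
    xmax: float
    rmax: float
    lag: float = 0.0

    def __post_init__(self) -> None:
        if not self.xmax > self.x0:
            raise ParameterError(f"xmax ({self.xmax}) must exceed x0 ({self.x0})")
        if not self.rmax > 0:
            raise ParameterError(f"rmax must be positive, got {self.rmax}")
        if self.lag < 0:
            raise ParameterError(f"lag must be non-negative, got {self.lag}")


@dataclass(frozen=True)
class GrowthParamsLn:
    """Parameters of natural-log-scale growth models (Baranyi, Huang).

    Attributes
    ----------
    y0 : initial population, ln CFU/g
    ymax : maximum population, ln CFU/g
    mumax : maximum specific growth rate, 1/h
    lag : lag-phase duration, h
    """

    y0: float
    ymax: float
    mumax: float
    lag: float = 0.0

    def __post_init__(self) -> None:
        if not self.ymax > self.y0:
            raise ParameterError(f"ymax ({self.ymax}) must exceed y0 ({self.y0})")
        if not self.mumax > 0:
            raise ParameterError(f"mumax must be positive, got {self.mumax}")
        if self.lag < 0:
            raise ParameterError(f"lag must be non-negative, got {self.lag}")


@dataclass(frozen=True)
class InhibitionParams:
    """Parameters of the inactivation models (log10 scale, time in s).

    Each model uses a subset: Log-Linear needs (logN0, k); Log-Linear + Tail
    needs (logN0, k, logNres); Weibull needs (logN0, delta, p).
    """

    logN0: float
    k: Optional[float] = None
    logNres: Optional[float] = None
    delta: Optional[float] = None
    p: Optional[float] = None

    def __post_init__(self) -> None:
        if self.k is not None and self.k < 0:
            raise ParameterError(f"k must be non-negative, got {self.k}")
        if self.delta is not None and not self.delta > 0:
            raise ParameterError(f"delta must be positive, got {self.delta}")
        if self.p is not None and not self.p > 0:
            raise ParameterError(f"p must be positive, got {self.p}")
        if self.logNres is not None and not self.logNres < self.logN0:
            raise ParameterError(
                f"logNres ({self.logNres}) must be below logN0 ({self.logN0})"
            )

    def _require(self, *names: str) -> None:
        for name in names:
            if getattr(self, name) is None:
                raise ParameterError(f"parameter {name!r} is required by this model")


def rmax_to_mumax(rmax):
    """Convert a log10-scale growth rate to the natural-log rate mumax (1/h)."""
    return np.asarray(rmax, dtype=float) * LN10 if np.ndim(rmax) else float(rmax) * LN10


def mumax_to_rmax(mumax):
    """Inverse of :func:`rmax_to_mumax`."""
    return np.asarray(mumax, dtype=float) / LN10 if np.ndim(mumax) else float(mumax) / LN10


def eval_gompertz(t, params: GrowthParamsLog10):
    """Modified Gompertz growth curve, log10 CFU/g.

    x(t) = x0 + (xmax - x0) * exp(-exp(rmax*e/(xmax-x0) * (lag - t) + 1))
    """
    t = np.asarray(t, dtype=float)
    span = params.xmax - params.x0
    inner = params.rmax * np.e / span * (params.lag - t) + 1.0
    # exp(-exp(inner)): clip inner to avoid overflow in the outer exp's argument;
    # exp(inner) > 745 already drives the result to exactly x0.
    inner = np.minimum(inner, 700.0)
    return params.x0 + span * np.exp(-np.exp(inner))


def eval_logistic(t, params: GrowthParamsLog10):
    """Logistic growth curve, log10 CFU/g.

    x(t) = x0 + (xmax - x0) / (1 + exp(4*rmax/(xmax-x0) * (lag - t) + 2))
    """
    t = np.asarray(t, dtype=float)
    span = params.xmax - params.x0
    inner = 4.0 * params.rmax / span * (params.lag - t) + 2.0
    inner = np.minimum(inner, 700.0)
    return params.x0 + span / (1.0 + np.exp(inner))


def _baranyi_adjustment(t, mumax: float, lag: float):
    """Baranyi-Roberts adjustment function F(t).

    F(t) = t + (1/mu) * ln(exp(-mu t) + exp(-mu lag) - exp(-mu (t + lag))),
    the explicit form equivalent to the initial physiological state
    q0 = 1 / (exp(mu*lag) - 1).  Evaluated in shifted form so that large
    mu*t or mu*lag cannot underflow to ln(0).
    """
    a = -mumax * t
    b = -mumax * lag
    m = np.maximum(a, b)
    s = np.exp(a - m) + np.exp(b - m) - np.exp(a + b - m)
    return t + (m + np.log(s)) / mumax


def eval_baranyi(t, params: GrowthParamsLn):
    """Baranyi-Roberts growth curve, ln CFU/g.

    y(t) = y0 + mu*F(t) - ln(1 + (exp(mu*F(t)) - 1) / exp(ymax - y0))
    """
    t = np.asarray(t, dtype=float)
    mu = params.mumax
    a = mu * _baranyi_adjustment(t, mu, params.lag)  # mu * F(t) >= 0
    d = params.ymax - params.y0
    # ln(1 + (e^a - 1) e^-d) = ln(e^0 + e^(a-d) - e^-d), shifted by m
    m = np.maximum(0.0, a - d)
    s = np.exp(-m) + np.exp(a - d - m) - np.exp(-d - m)
    return params.y0 + a - (m + np.log(s))


def _huang_transition(t, lag: float):
    """Huang transition function B(t) with the published coefficient 4.

    B(t) = t + (1/4) * ln((1 + exp(-4 (t - lag))) / (1 + exp(4 lag)))
    """
    return t + 0.25 * (np.logaddexp(0.0, -4.0 * (t - lag)) - np.logaddexp(0.0, 4.0 * lag))


def eval_huang(t, params: GrowthParamsLn):
    """Huang growth curve, ln CFU/g.

    y(t) = y0 + ymax - ln(exp(y0) + (exp(ymax) - exp(y0)) * exp(-mu*B(t)))
    """
    t = np.asarray(t, dtype=float)
    mb = params.mumax * _huang_transition(t, params.lag)
    y0, ymax = params.y0, params.ymax
    # ln(e^y0 + e^(ymax - mb) - e^(y0 - mb)) in shifted form
    a1 = np.broadcast_to(np.asarray(y0, dtype=float), mb.shape) if mb.ndim else y0
    a2 = ymax - mb
    m = np.maximum(a1, a2)
    s = np.exp(a1 - m) + np.exp(a2 - m) - np.exp(y0 - mb - m)
    return y0 + ymax - (m + np.log(s))


def eval_loglinear(t, params: InhibitionParams):
    """Log-Linear inactivation: log N(t) = logN0 - k*t."""
    params._require("k")
    t = np.asarray(t, dtype=float)
    return params.logN0 - params.k * t


def eval_loglinear_tail(t, params: InhibitionParams):
    """Log-Linear + Tail inactivation.

    log N(t) = (logN0 - logNres) * exp(-k*t) + logNres

    The log-count decays exponentially toward the residual tail logNres.
    """
    params._require("k", "logNres")
    t = np.asarray(t, dtype=float)
    return (params.logN0 - params.logNres) * np.exp(-params.k * t) + params.logNres


def eval_weibull(t, params: InhibitionParams):
    """Weibull inactivation: log N(t) = logN0 - (t/delta)^p.

    delta is the time of the first decimal reduction; p < 1 gives a concave
    (tailing) curve, p > 1 a convex (shouldering) one.
    """
    params._require("delta", "p")
    t = np.asarray(t, dtype=float)
    return params.logN0 - np.power(t / params.delta, params.p)
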