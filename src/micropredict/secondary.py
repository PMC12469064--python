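"""Secondary models: kinetic parameters as functions of one environmental variable.

For growth the maximum specific growth rate follows a Ratkowsky-type
response to the environmental variable X (typically storage temperature),

    mumax(X) = b1 * (X - Xmin)^2        for X > Xmin, else 0,

and the lag phase is tied to the growth rate through lag = b2 / mumax.
Note the model is implemented exactly in this squared form; b1 then carries
units 1/(h * degC^2) when X is temperature, which is what makes the form
dimensionally consistent.

For inactivation the rate constant k or the first-decimal-reduction time
delta follows a logarithmic response to the stressor concentration X
(e.g. free chlorine in mg/L),

    k or delta = a - b * log10(X).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, ParameterError

__all__ = [
    "GrowthSecondaryParams",
    "InhibitionSecondaryParams",
    "ratkowsky_mu",
    "lag_from_mu",
    "inhib_secondary",
]


@dataclass(frozen=True)
class GrowthSecondaryParams:
    """Coefficients of the growth secondary model.

    b1 : rate coefficient, 1/(h * X-units^2); must be positive
    Xmin : environmental value below which growth ceases (X units)
    b2 : lag-relation coefficient (dimensionless); lag = b2 / mumax
    """

    b1: float
    Xmin: float
    b2: float = 0.0

    def __post_init__(self) -> None:
        if not self.b1 > 0:
            raise ParameterError(f"b1 must be positive, got {self.b1}")
        if self.b2 < 0:
            raise ParameterError(f"b2 must be non-negative, got {self.b2}")


@dataclass(frozen=True)
class InhibitionSecondaryParams:
    """Coefficients of the inactivation secondary model k_or_delta = a - b*log10(X)."""

    a: float
    b: float


def ratkowsky_mu(X, params: GrowthSecondaryParams):
    """Maximum specific growth rate at environmental value X.

    Returns mumax = b1 * (X - Xmin)^2 in 1/h; X at or below Xmin yields 0
    (no growth) rather than a negative rate.
    """
    X = np.asarray(X, dtype=float)
    excess = np.maximum(X - params.Xmin, 0.0)
    return params.b1 * excess**2


def lag_from_mu(mumax, params: GrowthSecondaryParams):
    """Lag-phase duration lag = b2 / mumax (h).

    With b2 = 0 the lag is identically zero; otherwise mumax must be
    strictly positive.
    """
    mumax = np.asarray(mumax, dtype=float)
    if params.b2 == 0.0:
        return np.zeros_like(mumax)
    if np.any(mumax <= 0):
        raise DomainError("lag is undefined at zero growth rate (mumax <= 0)")
    return params.b2 / mumax


def inhib_secondary(X, params: InhibitionSecondaryParams, check_positive: bool = True):
    """Predicted k or delta at stressor level X: a - b*log10(X).

    X must be strictly positive.  When ``check_positive`` is set (default)
    a negative predicted value raises :class:`DomainError`, since a rate
    constant or decimal-reduction time below zero is meaningless inside
    the fitted range (the boundary root X = 10^(a/b) itself evaluates to 0).
    """
    X = np.asarray(X, dtype=float)
    if np.any(X <= 0):
        raise DomainError("environmental variable must be positive for log10")
    value = params.a - params.b * np.log10(X)
    if check_positive and np.any(value < 0):
        raise DomainError(
            "secondary model predicts a non-positive k/delta inside the given range"
        )
    return value
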