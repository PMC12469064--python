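"""Seeded synthetic growth and inactivation datasets with known parameters.

The generator emulates the structure of the experimental data the models
target: isothermal growth curves of spoilage bacteria on chilled poultry
at 2-20 degC spanning lag, exponential and stationary phases, and concave
chlorine-inactivation curves of surface-attached Listeria at 50-200 mg/L
over 0-360 s.  Noise is additive Gaussian on the log10 scale (default sd
0.15 log CFU for growth, 0.10 for inactivation).

Growth time grids default to 15 points from 0 to the time at which the
true curve reaches 99% of its span at that condition; inactivation grids
default to {0, 15, 30, 60, 120, 180, 240, 300, 360} s.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .datatypes import Curve, Dataset, SimulationSpec
from .errors import DomainError
from .fitting import growth_curve_log10, inhibition_curve_log10
from .secondary import (
    GrowthSecondaryParams,
    InhibitionSecondaryParams,
    inhib_secondary,
    lag_from_mu,
    ratkowsky_mu,
)

__all__ = [
    "DEFAULT_GROWTH_NOISE_SD",
    "DEFAULT_INHIBITION_NOISE_SD",
    "INHIBITION_TIMES",
    "growth_time_grid",
    "simulate_growth",
    "simulate_inhibition",
]

DEFAULT_GROWTH_NOISE_SD = 0.15
DEFAULT_INHIBITION_NOISE_SD = 0.10
#: exposure times (s) matching a 0-360 s chlorine treatment protocol
INHIBITION_TIMES = np.array([0.0, 15.0, 30.0, 60.0, 120.0, 180.0, 240.0, 300.0, 360.0])


def growth_time_grid(model_id: str, x0: float, xmax: float, mumax: float,
                     lag: float, n_times: int = 15) -> np.ndarray:
    """Evenly spaced grid from 0 to the 99%-of-span time of the true curve."""
    span = xmax - x0
    target = x0 + 0.99 * span

    def f(t):
        return float(growth_curve_log10(model_id, t, x0, xmax, mumax, lag)) - target

    hi = lag + 20.0 * span * np.log(10.0) / mumax + 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e9:
            raise DomainError("could not bracket the 99% span time")
    t99 = brentq(f, 0.0, hi, xtol=1e-6)
    return np.linspace(0.0, t99, n_times)


def _per_condition_params(spec: SimulationSpec, X: float):
    """Resolve the true kinetic parameters at condition X."""
    if spec.kind == "growth":
        if spec.secondary is not None:
            sec = spec.secondary
            if isinstance(sec, dict):
                sec = GrowthSecondaryParams(**sec)
            mu = float(ratkowsky_mu(X, sec))
            if mu <= 0:
                raise DomainError(f"no growth at condition {X} (at or below Xmin)")
            lag = float(lag_from_mu(mu, sec))
            x0 = spec.primary["x0"]
            xmax = spec.primary["xmax"]
        else:
            p = dict(spec.primary)
            if "mumax" not in p:  # per-condition parameter mappings
                key = X if X in p else float(X)
                p = dict(p[key])
            mu = p["mumax"]
            lag = p.get("lag", 0.0)
            x0, xmax = p["x0"], p["xmax"]
        return x0, xmax, mu, lag
    else:
        if spec.secondary is not None:
            sec = spec.secondary
            if isinstance(sec, dict):
                sec = InhibitionSecondaryParams(**sec)
            rate = float(inhib_secondary(X, sec))
        else:
            rate = spec.primary.get("delta", spec.primary.get("k"))
        return rate


def simulate_growth(spec: SimulationSpec) -> Dataset:
    """Generate a growth Dataset from a SimulationSpec.

    With secondary coefficients the per-condition truth is
    mumax = b1 (X - Xmin)^2 and lag = b2 / mumax plus the shared x0/xmax;
    otherwise ``spec.primary`` supplies (x0, xmax, mumax, lag) applied at
    every condition.  ``spec.replicates`` curves are drawn per condition,
    each with independent Gaussian noise.
    """
    if spec.kind != "growth":
        raise DomainError("spec.kind must be 'growth'")
    sd = DEFAULT_GROWTH_NOISE_SD if spec.noise_sd is None else spec.noise_sd
    rng = np.random.default_rng(spec.seed)
    name = spec.condition_name or "temperature"
    curves = []
    for X in spec.conditions:
        x0, xmax, mu, lag = _per_condition_params(spec, float(X))
        times = _resolve_times(spec, X)
        if times is None:
            times = growth_time_grid(spec.model_id, x0, xmax, mu, lag, spec.n_times)
        truth = np.asarray(
            growth_curve_log10(spec.model_id, times, x0, xmax, mu, lag), dtype=float)
        for _ in range(spec.replicates):
            noisy = truth + sd * rng.standard_normal(truth.shape)
            curves.append(Curve(times=times.copy(), values=noisy, condition=float(X),
                                condition_name=name))
    return Dataset(curves=curves, kind="growth")


def simulate_inhibition(spec: SimulationSpec) -> Dataset:
    """Generate an inactivation Dataset from a SimulationSpec.

    With secondary coefficients, delta(X) (Weibull) or k(X) (log-linear)
    follows a - b log10(X) while logN0, p and logNres are shared via
    ``spec.primary``; otherwise the primary parameters apply unchanged at
    every condition.
    """
    if spec.kind != "inhibition":
        raise DomainError("spec.kind must be 'inhibition'")
    sd = DEFAULT_INHIBITION_NOISE_SD if spec.noise_sd is None else spec.noise_sd
    rng = np.random.default_rng(spec.seed)
    name = spec.condition_name or "chlorine"
    curves = []
    for X in spec.conditions:
        times = _resolve_times(spec, X)
        if times is None:
            times = INHIBITION_TIMES.copy()
        theta = _inhibition_theta(spec, float(X))
        truth = np.asarray(
            inhibition_curve_log10(spec.model_id, times, theta), dtype=float)
        for _ in range(spec.replicates):
            noisy = truth + sd * rng.standard_normal(truth.shape)
            curves.append(Curve(times=times.copy(), values=noisy, condition=float(X),
                                condition_name=name, response_units="log CFU/cm2"))
    return Dataset(curves=curves, kind="inhibition")


def _inhibition_theta(spec: SimulationSpec, X: float):
    p = dict(spec.primary)
    if spec.secondary is not None:
        rate = _per_condition_params(spec, X)
        if spec.model_id == "weibull":
            return (p["logN0"], rate, p["p"])
        if spec.model_id == "loglinear":
            return (p["logN0"], rate)
        return (p["logN0"], rate, p["logNres"])
    if spec.model_id == "weibull":
        return (p["logN0"], p["delta"], p["p"])
    if spec.model_id == "loglinear":
        return (p["logN0"], p["k"])
    return (p["logN0"], p["k"], p["logNres"])


def _resolve_times(spec: SimulationSpec, X) -> Optional[np.ndarray]:
    if spec.times is None:
        return None
    if isinstance(spec.times, dict):
        val = spec.times.get(X, spec.times.get(float(X)))
        return None if val is None else np.asarray(val, dtype=float)
    return np.asarray(spec.times, dtype=float)
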