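"""Two-step and one-step (global) nonlinear least-squares estimation.

Two-step workflow: fit a primary model to each condition's curve, then
regress the recovered kinetic parameters (mumax and lag for growth, k or
delta for inactivation) against the environmental variable with the
secondary model.  One-step workflow: substitute the secondary model into
the primary equation and minimise the joint SSE over all curves at once,
which avoids propagating primary-stage estimation error into the secondary
stage.

All optimisation uses trust-region-reflective least squares behind a
seeded multi-start (data-driven heuristic starts plus jittered copies;
for one-step fits the two-step reconstruction is always one of the
starts, which guarantees the joint SSE can never exceed it).  Estimates
are reported on the conventional scales: populations in log10 CFU/g,
mumax in 1/h regardless of the primary model's internal log base.
"""

from __future__ import annotations

from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

from .datatypes import Curve, Dataset, FitResult, TwoStepResult
from .errors import ConvergenceError, DegenerateDataError, DomainError
from .models import (
    LN10,
    GrowthParamsLn,
    GrowthParamsLog10,
    InhibitionParams,
    eval_baranyi,
    eval_gompertz,
    eval_huang,
    eval_logistic,
    eval_loglinear,
    eval_loglinear_tail,
    eval_weibull,
)
from .uncertainty import param_covariance, standard_errors

__all__ = [
    "GROWTH_MODELS",
    "INHIBITION_MODELS",
    "DEFAULT_SEED",
    "growth_curve_log10",
    "inhibition_curve_log10",
    "fit_primary_growth",
    "fit_primary_inhibition",
    "fit_secondary_growth",
    "fit_secondary_inhibition",
    "run_two_step",
    "fit_one_step_growth",
    "fit_one_step_inhibition",
]

GROWTH_MODELS = ("gompertz", "logistic", "baranyi", "huang")
INHIBITION_MODELS = ("loglinear", "loglinear_tail", "weibull")

DEFAULT_SEED = 20250910
N_STARTS = 8
_DELTA_FLOOR = 1e-3  # smallest delta (s) the one-step Weibull residual will evaluate


# ---------------------------------------------------------------------------
# model evaluation on the common log10 scale
# ---------------------------------------------------------------------------

def growth_curve_log10(model_id: str, t, x0: float, xmax: float,
                       mumax: float, lag: float):
    """Evaluate any primary growth model on the log10 scale.

    x0/xmax are log10 CFU/g and mumax is the natural-log rate in 1/h;
    the log10-based models receive rmax = mumax / ln(10), the ln-based
    models run internally in natural log and are converted back.
    """
    if model_id == "gompertz":
        return eval_gompertz(t, GrowthParamsLog10(x0, xmax, mumax / LN10, lag))
    if model_id == "logistic":
        return eval_logistic(t, GrowthParamsLog10(x0, xmax, mumax / LN10, lag))
    if model_id == "baranyi":
        return eval_baranyi(t, GrowthParamsLn(x0 * LN10, xmax * LN10, mumax, lag)) / LN10
    if model_id == "huang":
        return eval_huang(t, GrowthParamsLn(x0 * LN10, xmax * LN10, mumax, lag)) / LN10
    raise DomainError(f"unknown growth model {model_id!r}; choose from {GROWTH_MODELS}")


def inhibition_curve_log10(model_id: str, t, theta: Sequence[float]):
    """Evaluate a primary inactivation model from its natural parameter vector.

    loglinear: theta = (logN0, k); loglinear_tail: (logN0, k, logNres);
    weibull: (logN0, delta, p).
    """
    if model_id == "loglinear":
        return eval_loglinear(t, InhibitionParams(logN0=theta[0], k=theta[1]))
    if model_id == "loglinear_tail":
        return eval_loglinear_tail(
            t, InhibitionParams(logN0=theta[0], k=theta[1], logNres=theta[2]))
    if model_id == "weibull":
        return eval_weibull(t, InhibitionParams(logN0=theta[0], delta=theta[1], p=theta[2]))
    raise DomainError(
        f"unknown inhibition model {model_id!r}; choose from {INHIBITION_MODELS}")


# ---------------------------------------------------------------------------
# multi-start optimisation core
# ---------------------------------------------------------------------------

def _multistart(residual: Callable[[np.ndarray], np.ndarray],
                starts: Sequence[np.ndarray],
                lb: np.ndarray, ub: np.ndarray):
    """Run least_squares from every start; return the best solution.

    Selection: lowest SSE; near-ties broken by the smaller parameter-vector
    norm.  Raises ConvergenceError if every start fails.
    """
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    width = ub - lb
    best = None
    for s in starts:
        x0 = np.clip(np.asarray(s, dtype=float), lb + 1e-10 * width, ub - 1e-10 * width)
        try:
            sol = least_squares(residual, x0, bounds=(lb, ub), method="trf",
                                x_scale="jac", ftol=1e-12, xtol=1e-12, gtol=1e-12,
                                max_nfev=400 * len(x0))
        except (ValueError, FloatingPointError):
            continue
        if not np.all(np.isfinite(sol.fun)):
            continue
        sse = float(sol.fun @ sol.fun)
        norm = float(np.linalg.norm(sol.x))
        if best is None:
            best = (sse, norm, sol)
        else:
            b_sse, b_norm, _ = best
            if sse < b_sse - 1e-12 * max(b_sse, 1.0):
                best = (sse, norm, sol)
            elif abs(sse - b_sse) <= 1e-12 * max(b_sse, 1.0) and norm < b_norm:
                best = (sse, norm, sol)
    if best is None:
        raise ConvergenceError("nonlinear least squares failed from every start point")
    return best[2]


def _jittered_starts(base: Sequence[np.ndarray], rng: np.random.Generator,
                     n_total: int, lb: np.ndarray, ub: np.ndarray) -> List[np.ndarray]:
    """Heuristic starts plus multiplicative/additive jittered copies."""
    starts = [np.asarray(b, dtype=float) for b in base]
    i = 0
    while len(starts) < n_total:
        s0 = starts[i % len(base)]
        step = np.where(np.abs(s0) > 1e-8, 0.4 * np.abs(s0), 0.4)
        starts.append(s0 + step * rng.standard_normal(s0.size))
        i += 1
    return starts


def _finish_fit(model_id: str, sol, observed: np.ndarray,
                names: List[str], transform: Optional[np.ndarray] = None,
                extras: Optional[dict] = None) -> FitResult:
    """Build a FitResult from a least_squares solution.

    ``transform`` is the linear map A taking the internal parametrisation
    to the reported one (theta_r = A theta_i + const handled by caller);
    the covariance maps as A C A^T.
    """
    theta_i = sol.x
    resid = sol.fun  # model - data ordering is irrelevant for squares
    C_i = param_covariance(sol.jac, resid)
    if transform is None:
        theta_r = theta_i
        C_r = C_i
    else:
        theta_r = transform @ theta_i
        C_r = transform @ C_i @ transform.T
    n, p = resid.size, theta_i.size
    sse = float(resid @ resid)
    sst = float(np.sum((observed - observed.mean()) ** 2))
    return FitResult(
        model_id=model_id,
        param_names=names,
        estimates=theta_r,
        std_errors=standard_errors(C_r),
        covariance=C_r,
        resid_var=sse / (n - p),
        n_obs=n,
        n_params=p,
        rmse=float(np.sqrt(sse / (n - p))),
        r2=1.0 - sse / sst if sst > 0 else float("nan"),
        sse=sse,
        sst=sst,
        extras=extras or {},
    )


# ---------------------------------------------------------------------------
# primary fits
# ---------------------------------------------------------------------------

def _growth_heuristics(times: np.ndarray, values: np.ndarray):
    """Data-driven start (x0, span, mumax, lag) for a growth curve.

    Rate from the steepest 3-point secant; lag from the time-axis intercept
    of the tangent at that secant.
    """
    x0 = values[0]
    span = max(values.max() - x0, 0.6)
    if len(times) >= 3:
        # epsilon guards duplicate times from pooled replicate curves
        sec = (values[2:] - values[:-2]) / np.maximum(times[2:] - times[:-2], 1e-9)
        i = int(np.argmax(sec))
        slope = max(sec[i], 1e-3)
        t_mid = times[i + 1]
        y_mid = values[i + 1]
        lag = max(t_mid - (y_mid - x0) / slope, 0.0)
    else:
        slope = span / max(times[-1], 1.0)
        lag = 0.0
    mu = slope * LN10
    return x0, span, mu, lag


def fit_primary_growth(curve: Curve, model_id: str,
                       seed: int = DEFAULT_SEED,
                       n_starts: int = N_STARTS) -> FitResult:
    """Fit one primary growth model to a single curve.

    Reported estimates: initial and maximum population in log10 CFU/g,
    the rate on the model's native scale (rmax for Gompertz/Logistic,
    mumax for Baranyi/Huang) and the lag (h); extras always carry mumax
    in 1/h with its standard error.
    """
    if model_id not in GROWTH_MODELS:
        raise DomainError(f"unknown growth model {model_id!r}")
    t, y = curve.times, curve.values
    if len(t) < 5:
        raise DegenerateDataError("growth fitting needs at least 5 observations")
    if y.max() - y.min() <= 1.0:
        raise DegenerateDataError(
            "observed range spans <= 1 log10; no growth signal to fit")
    if y[-1] < y[0]:
        raise DegenerateDataError(
            "curve trends downward; not growth data (use an inhibition model)")

    x0h, spanh, muh, lagh = _growth_heuristics(t, y)
    lb = np.array([y.min() - 2.0, 0.5, 1e-4, 0.0])
    ub = np.array([y.min() + 2.0, (y.max() - y.min()) + 4.0, 50.0, float(t[-1])])
    base = [np.array([x0h, spanh, muh, lagh]),
            np.array([x0h, spanh, muh, 0.0])]
    rng = np.random.default_rng(seed)
    starts = _jittered_starts(base, rng, n_starts, lb, ub)

    def residual(th):
        return growth_curve_log10(model_id, t, th[0], th[0] + th[1], th[2], th[3]) - y

    sol = _multistart(residual, starts, lb, ub)

    A = np.eye(4)
    A[1, 0] = 1.0  # xmax = x0 + span
    mu_hat = sol.x[2]
    if model_id in ("gompertz", "logistic"):
        names = ["x0", "xmax", "rmax", "lag"]
        A[2, 2] = 1.0 / LN10  # report rmax on the log10 scale
    else:
        names = ["y0", "ymax", "mumax", "lag"]
    fr = _finish_fit(model_id, sol, y, names, transform=A)
    # mumax (1/h) is always exposed, whatever the native rate scale
    se_mu = standard_errors(param_covariance(sol.jac, sol.fun))[2]
    fr.extras["mumax"] = float(mu_hat)
    fr.extras["mumax_se"] = float(se_mu)
    return fr


def _inhibition_heuristics(model_id: str, times: np.ndarray, values: np.ndarray):
    logN0 = values[0]
    drop = max(values[0] - values[-1], 0.2)
    t_end = max(times[-1], 1.0)
    k0 = drop / t_end
    below = np.nonzero(values <= values[0] - 1.0)[0]
    if below.size:
        j = below[0]
        delta0 = float(np.interp(values[0] - 1.0,
                                 [values[j], values[j - 1]] if j > 0 else [values[j]],
                                 [times[j], times[j - 1]] if j > 0 else [times[j]]))
        delta0 = max(delta0, 1e-2)
    else:
        delta0 = t_end / 3.0
    return logN0, k0, drop, delta0


def fit_primary_inhibition(curve: Curve, model_id: str,
                           seed: int = DEFAULT_SEED,
                           n_starts: int = N_STARTS) -> FitResult:
    """Fit one primary inactivation model to a single survival curve."""
    if model_id not in INHIBITION_MODELS:
        raise DomainError(f"unknown inhibition model {model_id!r}")
    t, y = curve.times, curve.values
    if len(t) < 4:
        raise DegenerateDataError("inhibition fitting needs at least 4 observations")
    if y[-1] > y[0]:
        raise DegenerateDataError(
            "curve trends upward; not inactivation data (use a growth model)")
    return _fit_inhibition_arrays(t, y, model_id, seed, n_starts=n_starts)


# ---------------------------------------------------------------------------
# secondary fits
# ---------------------------------------------------------------------------

def fit_secondary_growth(param_table: Mapping[float, Tuple[float, float]],
                         seed: int = DEFAULT_SEED,
                         n_starts: int = N_STARTS) -> FitResult:
    """Fit the growth secondary model to per-condition (mumax, lag) estimates.

    mumax(X) = b1 (X - Xmin)^2 is fitted by multi-start nonlinear least
    squares; b2 of lag = b2 / mumax has the closed-form solution of a
    regression of lag on 1/mumax through the origin.  Entries may be bare
    mumax values, in which case b2 is fixed at 0.

    Returns a FitResult with parameters (b1, Xmin, b2); its covariance is
    block-diagonal because the two regressions use disjoint responses.
    """
    if len(param_table) < 3:
        raise DegenerateDataError("secondary fitting needs at least 3 conditions")
    X = np.array(sorted(param_table))
    entries = [param_table[x] for x in X]
    if np.ndim(entries[0]) == 0:
        mu = np.array([float(e) for e in entries])
        lag = None
    else:
        mu = np.array([float(e[0]) for e in entries])
        lag = np.array([float(e[1]) for e in entries])
    if np.any(mu <= 0):
        raise DomainError("all mumax values must be positive")

    # sqrt-linearised start: sqrt(mu) ~ sqrt(b1) * (X - Xmin)
    m, c = np.polyfit(X, np.sqrt(mu), 1)
    if m > 0 and -c / m < X.min():
        start = np.array([m**2, -c / m])
    else:
        start = np.array([mu.max() / (X.max() - X.min() + 5.0) ** 2, X.min() - 5.0])
    lb = np.array([1e-8, X.min() - 80.0])
    ub = np.array([10.0, X.min() - 1e-6])
    rng = np.random.default_rng(seed)
    starts = _jittered_starts([start], rng, n_starts, lb, ub)

    def residual(th):
        return th[0] * (X - th[1]) ** 2 - mu

    sol = _multistart(residual, starts, lb, ub)
    b1, Xmin = sol.x
    C_mu = param_covariance(sol.jac, sol.fun)

    # lag = b2 / mu: least squares through the origin in z = 1/mu
    if lag is None or np.allclose(lag, 0.0):
        b2 = 0.0
        var_b2 = 0.0
        lag_resid = np.zeros(0)
        lag_obs = np.zeros(0)
    else:
        z = 1.0 / mu
        b2 = float(np.sum(lag * z) / np.sum(z * z))
        b2 = max(b2, 0.0)
        lag_resid = b2 * z - lag
        dof = max(len(lag) - 1, 1)
        var_b2 = float(lag_resid @ lag_resid) / dof / float(np.sum(z * z))
        lag_obs = lag

    C = np.zeros((3, 3))
    C[:2, :2] = C_mu
    C[2, 2] = var_b2
    resid = np.concatenate([sol.fun, lag_resid])
    obs = np.concatenate([mu, lag_obs])
    n = resid.size
    p = 3
    sse = float(resid @ resid)
    sst = float(np.sum((obs - obs.mean()) ** 2))
    return FitResult(
        model_id="ratkowsky",
        param_names=["b1", "Xmin", "b2"],
        estimates=np.array([b1, Xmin, b2]),
        std_errors=standard_errors(C),
        covariance=C,
        resid_var=sse / max(n - p, 1),
        n_obs=n,
        n_params=p,
        rmse=float(np.sqrt(sse / max(n - p, 1))),
        r2=1.0 - sse / sst if sst > 0 else float("nan"),
        sse=sse,
        sst=sst,
    )


def fit_secondary_inhibition(param_table: Mapping[float, float]) -> FitResult:
    """Fit k_or_delta = a - b*log10(X) to per-condition estimates (closed-form OLS)."""
    if len(param_table) < 3:
        raise DegenerateDataError("secondary fitting needs at least 3 conditions")
    X = np.array(sorted(param_table))
    if np.any(X <= 0):
        raise DomainError("conditions must be positive for log10")
    v = np.array([float(param_table[x]) for x in X])
    Z = np.column_stack([np.ones_like(X), -np.log10(X)])
    coef, *_ = np.linalg.lstsq(Z, v, rcond=None)
    resid = Z @ coef - v
    n, p = len(v), 2
    s2 = float(resid @ resid) / (n - p) if n > p else 0.0
    C = s2 * np.linalg.inv(Z.T @ Z)
    sse = float(resid @ resid)
    sst = float(np.sum((v - v.mean()) ** 2))
    return FitResult(
        model_id="log_concentration",
        param_names=["a", "b"],
        estimates=coef,
        std_errors=standard_errors(C),
        covariance=C,
        resid_var=s2,
        n_obs=n,
        n_params=p,
        rmse=float(np.sqrt(sse / (n - p))) if n > p else 0.0,
        r2=1.0 - sse / sst if sst > 0 else float("nan"),
        sse=sse,
        sst=sst,
    )


# ---------------------------------------------------------------------------
# two-step and one-step workflows
# ---------------------------------------------------------------------------

def _group_by_condition(dataset: Dataset) -> Dict[float, List[Curve]]:
    groups: Dict[float, List[Curve]] = {}
    for c in dataset.curves:
        groups.setdefault(float(c.condition), []).append(c)
    return groups


def run_two_step(dataset: Dataset, model_id: str,
                 seed: int = DEFAULT_SEED) -> TwoStepResult:
    """Two-step workflow: primary fit per condition, then the secondary fit.

    Replicate curves at the same condition are pooled into one primary fit.
    For growth the secondary stage consumes (mumax, lag); for inactivation
    it consumes delta (Weibull) or k (log-linear variants).
    """
    groups = _group_by_condition(dataset)
    if len(groups) < 2:
        raise DegenerateDataError("two-step fitting needs at least 2 distinct conditions")
    primary: Dict[float, FitResult] = {}
    if dataset.kind == "growth":
        for X, curves in groups.items():
            primary[X] = _fit_growth_pooled(curves, model_id, seed=seed)
        table = {X: (fr.extras["mumax"], fr.params["lag"]) for X, fr in primary.items()}
        secondary = fit_secondary_growth(table, seed=seed)
    else:
        for X, curves in groups.items():
            primary[X] = _fit_inhibition_pooled(curves, model_id, seed=seed)
        key = "delta" if model_id == "weibull" else "k"
        table = {X: fr.params[key] for X, fr in primary.items()}
        secondary = fit_secondary_inhibition(table)
        if model_id == "weibull":
            secondary.extras["mean_p"] = float(
                np.mean([fr.params["p"] for fr in primary.values()]))
    return TwoStepResult(primary_fits=primary, secondary_fit=secondary)


def _fit_growth_pooled(curves: List[Curve], model_id: str, seed: int) -> FitResult:
    if len(curves) == 1:
        return fit_primary_growth(curves[0], model_id, seed=seed)
    t = np.concatenate([c.times for c in curves])
    y = np.concatenate([c.values for c in curves])
    order = np.argsort(t, kind="stable")
    # pooled replicate fit: shared parameters across replicates at one condition
    tt, yy = t[order], y[order]
    x0h, spanh, muh, lagh = _growth_heuristics(tt, yy)
    lb = np.array([yy.min() - 2.0, 0.5, 1e-4, 0.0])
    ub = np.array([yy.min() + 2.0, (yy.max() - yy.min()) + 4.0, 50.0, float(tt[-1])])
    rng = np.random.default_rng(seed)
    starts = _jittered_starts([np.array([x0h, spanh, muh, lagh])], rng, N_STARTS, lb, ub)

    def residual(th):
        return growth_curve_log10(model_id, tt, th[0], th[0] + th[1], th[2], th[3]) - yy

    sol = _multistart(residual, starts, lb, ub)
    A = np.eye(4)
    A[1, 0] = 1.0
    if model_id in ("gompertz", "logistic"):
        names = ["x0", "xmax", "rmax", "lag"]
        A[2, 2] = 1.0 / LN10
    else:
        names = ["y0", "ymax", "mumax", "lag"]
    fr = _finish_fit(model_id, sol, yy, names, transform=A)
    fr.extras["mumax"] = float(sol.x[2])
    fr.extras["mumax_se"] = float(
        standard_errors(param_covariance(sol.jac, sol.fun))[2])
    return fr


def _fit_inhibition_pooled(curves: List[Curve], model_id: str, seed: int) -> FitResult:
    if len(curves) == 1:
        return fit_primary_inhibition(curves[0], model_id, seed=seed)
    t = np.concatenate([c.times for c in curves])
    y = np.concatenate([c.values for c in curves])
    order = np.argsort(t, kind="stable")
    pooled = Curve(times=np.arange(len(t), dtype=float),  # placeholder grid
                   values=y[order], condition=curves[0].condition,
                   condition_name=curves[0].condition_name)
    # bypass Curve's strict-monotone check by fitting on raw arrays directly
    pooled.times = t[order]
    return _fit_inhibition_arrays(pooled.times, pooled.values, model_id, seed)


def _fit_inhibition_arrays(t: np.ndarray, y: np.ndarray, model_id: str,
                           seed: int, n_starts: int = N_STARTS) -> FitResult:
    """Shared inactivation fitter on raw (possibly pooled) arrays.

    The tail model runs internally on (logN0, k, drop) with drop > 0, which
    enforces logNres = logN0 - drop < logN0 as a box bound.
    """
    logN0h, k0, droph, delta0 = _inhibition_heuristics(model_id, t, y)
    rng = np.random.default_rng(seed)
    t_end = float(t[-1])
    if model_id == "loglinear":
        lb = np.array([y[0] - 2.0, 0.0])
        ub = np.array([y[0] + 2.0, max(10.0 * k0, 1.0)])
        base = [np.array([logN0h, k0])]
        names = ["logN0", "k"]
        transform = None

        def residual(th):
            return th[0] - th[1] * t - y
    elif model_id == "loglinear_tail":
        lb = np.array([y[0] - 2.0, 0.0, 1e-3])
        ub = np.array([y[0] + 2.0, max(20.0 * k0, 1.0), (y.max() - y.min()) + 5.0])
        base = [np.array([logN0h, 3.0 * k0, droph]),
                np.array([logN0h, k0, droph])]
        names = ["logN0", "k", "logNres"]
        transform = np.array([[1.0, 0.0, 0.0],
                              [0.0, 1.0, 0.0],
                              [1.0, 0.0, -1.0]])  # logNres = logN0 - drop

        def residual(th):
            logN0, k, drop = th
            return drop * np.exp(-k * t) + (logN0 - drop) - y
    else:  # weibull
        lb = np.array([y[0] - 2.0, _DELTA_FLOOR, 0.05])
        ub = np.array([y[0] + 2.0, 10.0 * t_end, 5.0])
        base = [np.array([logN0h, delta0, 1.0]),
                np.array([logN0h, delta0, 0.4])]
        names = ["logN0", "delta", "p"]
        transform = None

        def residual(th):
            return th[0] - np.power(t / th[1], th[2]) - y

    starts = _jittered_starts(base, rng, n_starts, lb, ub)
    sol = _multistart(residual, starts, lb, ub)
    return _finish_fit(model_id, sol, y, names, transform=transform)


def _one_step_growth_residual(model_id: str, curves: List[Curve]):
    """Residual closure for theta = (y0, span, Xmin, b1, b2)."""
    def residual(th):
        y0, span, Xmin, b1, b2 = th
        parts = []
        for c in curves:
            mu = b1 * max(float(c.condition) - Xmin, 1e-9) ** 2
            lag = b2 / mu
            parts.append(
                growth_curve_log10(model_id, c.times, y0, y0 + span, mu, lag) - c.values)
        return np.concatenate(parts)
    return residual


def fit_one_step_growth(dataset: Dataset, model_id: str,
                        seed: int = DEFAULT_SEED,
                        n_starts: int = N_STARTS) -> FitResult:
    """One-step global fit of a growth model across all conditions.

    The secondary model mumax(X) = b1 (X - Xmin)^2 and lag(X) = b2 / mumax
    is substituted into the primary equation; (y0, ymax, Xmin, b1, b2) are
    shared across every curve and estimated jointly.  The two-step
    reconstruction is always included among the start points.
    """
    if model_id not in GROWTH_MODELS:
        raise DomainError(f"unknown growth model {model_id!r}")
    conds = np.unique(dataset.conditions)
    if len(conds) < 2:
        raise DegenerateDataError("one-step fitting needs at least 2 distinct conditions")
    for c in dataset.curves:
        if len(c) < 5:
            raise DegenerateDataError("every curve needs at least 5 observations")

    y_all = np.concatenate([c.values for c in dataset.curves])
    minX = float(conds.min())
    lb = np.array([y_all.min() - 2.0, 0.5, minX - 80.0, 1e-8, 0.0])
    ub = np.array([y_all.min() + 2.0, (y_all.max() - y_all.min()) + 4.0,
                   minX - 0.5, 10.0, 100.0])

    base = []
    try:
        two_step = run_two_step(dataset, model_id, seed=seed)
        b1, Xmin, b2 = two_step.secondary_fit.estimates
        y0s = float(np.mean([fr.estimates[0] for fr in two_step.primary_fits.values()]))
        spans = float(np.mean([fr.estimates[1] - fr.estimates[0]
                               for fr in two_step.primary_fits.values()]))
        base.append(np.array([y0s, spans, Xmin, b1, b2]))
    except (DegenerateDataError, ConvergenceError):
        pass
    # slope-based heuristic start
    mu_guess = {}
    for c in dataset.curves:
        _, _, mu, _ = _growth_heuristics(c.times, c.values)
        mu_guess.setdefault(float(c.condition), []).append(mu)
    Xs = np.array(sorted(mu_guess))
    mus = np.array([np.mean(mu_guess[x]) for x in Xs])
    m, cc = np.polyfit(Xs, np.sqrt(np.maximum(mus, 1e-6)), 1)
    if m > 0 and -cc / m < minX:
        base.append(np.array([np.mean([c.values[0] for c in dataset.curves]),
                              max(y_all.max() - y_all.min(), 0.6),
                              -cc / m, m**2, 1.0]))
    base.append(np.array([np.mean([c.values[0] for c in dataset.curves]),
                          max(y_all.max() - y_all.min(), 0.6),
                          minX - 5.0, 0.002, 1.0]))
    rng = np.random.default_rng(seed)
    starts = _jittered_starts(base, rng, max(n_starts, len(base)), lb, ub)

    sol = _multistart(_one_step_growth_residual(model_id, dataset.curves), starts, lb, ub)
    A = np.eye(5)
    A[1, 0] = 1.0  # ymax = y0 + span
    names = ["y0", "ymax", "Xmin", "b1", "b2"]
    return _finish_fit(model_id, sol, y_all, names, transform=A)


def _one_step_inhibition_residual(model_id: str, curves: List[Curve]):
    """Residual closure; theta depends on the model:

    weibull: (logN0, a, b, p) with delta(X) = a - b log10 X (floored);
    loglinear: (logN0, a, b) with k(X) = a - b log10 X (floored at 0);
    loglinear_tail: (logN0, a, b, drop) with global logNres = logN0 - drop.
    """
    def residual(th):
        parts = []
        for c in curves:
            lx = np.log10(float(c.condition))
            if model_id == "weibull":
                logN0, a, b, p = th
                delta = max(a - b * lx, _DELTA_FLOOR)
                pred = inhibition_curve_log10("weibull", c.times, (logN0, delta, p))
            elif model_id == "loglinear":
                logN0, a, b = th
                k = max(a - b * lx, 0.0)
                pred = logN0 - k * c.times
            else:
                logN0, a, b, drop = th
                k = max(a - b * lx, 0.0)
                pred = drop * np.exp(-k * c.times) + (logN0 - drop)
            parts.append(pred - c.values)
        return np.concatenate(parts)
    return residual


def fit_one_step_inhibition(dataset: Dataset, model_id: str,
                            seed: int = DEFAULT_SEED,
                            n_starts: int = N_STARTS) -> FitResult:
    """One-step global fit of an inactivation model across all conditions.

    For the Weibull model the shared parameters are (logN0, a, b, p) with
    delta(X) = a - b log10(X); the log-linear variants substitute the same
    secondary form for k.  The two-step reconstruction is always one of
    the start points.
    """
    if model_id not in INHIBITION_MODELS:
        raise DomainError(f"unknown inhibition model {model_id!r}")
    conds = np.unique(dataset.conditions)
    if len(conds) < 2:
        raise DegenerateDataError("one-step fitting needs at least 2 distinct conditions")

    y_all = np.concatenate([c.values for c in dataset.curves])
    logN0h = float(np.mean([c.values[0] for c in dataset.curves]))

    base = []
    two_step_start = None
    try:
        ts = run_two_step(dataset, model_id, seed=seed)
        a, b = ts.secondary_fit.estimates
        if model_id == "weibull":
            p_mean = ts.secondary_fit.extras.get("mean_p", 1.0)
            two_step_start = np.array([logN0h, a, b, p_mean])
        elif model_id == "loglinear":
            two_step_start = np.array([logN0h, a, b])
        else:
            drop = float(np.mean([fr.params["logN0"] - fr.params["logNres"]
                                  for fr in ts.primary_fits.values()]))
            two_step_start = np.array([logN0h, a, b, drop])
        base.append(two_step_start)
    except (DegenerateDataError, ConvergenceError):
        pass

    if model_id == "weibull":
        lb = np.array([y_all.max() - 3.0, -500.0, -250.0, 0.05])
        ub = np.array([y_all.max() + 3.0, 500.0, 250.0, 5.0])
        base.append(np.array([logN0h, 20.0, 5.0, 1.0]))
        names = ["logN0", "a", "b", "p"]
        transform = None
    elif model_id == "loglinear":
        lb = np.array([y_all.max() - 3.0, -10.0, -10.0])
        ub = np.array([y_all.max() + 3.0, 10.0, 10.0])
        base.append(np.array([logN0h, 0.05, 0.01]))
        names = ["logN0", "a", "b"]
        transform = None
    else:
        lb = np.array([y_all.max() - 3.0, -10.0, -10.0, 1e-3])
        ub = np.array([y_all.max() + 3.0, 10.0, 10.0, (y_all.max() - y_all.min()) + 5.0])
        base.append(np.array([logN0h, 0.05, 0.01,
                              max(y_all.max() - y_all.min(), 0.5)]))
        names = ["logN0", "a", "b", "logNres"]
        transform = np.eye(4)
        transform[3, 0] = 1.0
        transform[3, 3] = -1.0  # logNres = logN0 - drop
    rng = np.random.default_rng(seed)
    starts = _jittered_starts(base, rng, max(n_starts, len(base)), lb, ub)

    sol = _multistart(_one_step_inhibition_residual(model_id, dataset.curves),
                      starts, lb, ub)
    return _finish_fit(model_id, sol, y_all, names, transform=transform)
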