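"""Uncertainty quantification for fitted curves.

For nonlinear least squares the parameter covariance is the Gauss-Newton
approximation C = s^2 (J^T J)^{-1} with residual variance
s^2 = SSE / (n - p); pointwise 95% prediction bands follow from the delta
method, sigma_yhat^2(t) = grad f(t)^T C grad f(t) + s^2, with the fixed
normal quantile 1.96.  Non-probabilistic regressors get percentile
bootstrap bands (2.5th / 97.5th percentiles over refit predictions).
"""

from __future__ import annotations

import warnings
from typing import Callable, Optional, Tuple

import numpy as np

from .datatypes import PredictionBand
from .errors import DomainError

__all__ = [
    "Z95",
    "param_covariance",
    "standard_errors",
    "numerical_gradient",
    "prediction_band",
    "bootstrap_band",
]

#: normal 97.5% quantile used for all 95% intervals
Z95 = 1.96


def param_covariance(jacobian, residuals) -> np.ndarray:
    """Covariance C = s^2 (J^T J)^{-1} from the residual Jacobian.

    jacobian is the n x p matrix of model sensitivities at the optimum and
    residuals the length-n residual vector; s^2 = SSE / (n - p).  A
    rank-deficient J^T J falls back to the Moore-Penrose pseudo-inverse
    with a warning.
    """
    J = np.atleast_2d(np.asarray(jacobian, dtype=float))
    r = np.asarray(residuals, dtype=float).ravel()
    n, p = J.shape
    if n <= p:
        raise DomainError(f"need n > p for a covariance estimate (n={n}, p={p})")
    if r.size != n:
        raise DomainError("residual length must match the Jacobian row count")
    s2 = float(r @ r) / (n - p)
    jtj = J.T @ J
    if np.linalg.matrix_rank(jtj) < p:
        warnings.warn(
            "Jacobian is rank-deficient at the optimum; covariance uses a "
            "pseudo-inverse and some parameters are not identified",
            RuntimeWarning,
            stacklevel=2,
        )
        inv = np.linalg.pinv(jtj)
    else:
        inv = np.linalg.inv(jtj)
    C = s2 * inv
    return (C + C.T) / 2.0


def standard_errors(C) -> np.ndarray:
    """Per-parameter standard errors: square roots of the covariance diagonal."""
    C = np.asarray(C, dtype=float)
    diag = np.diag(C).copy()
    diag[diag < 0] = 0.0  # tiny negative round-off from pseudo-inverses
    return np.sqrt(diag)


def numerical_gradient(
    fn: Callable[[np.ndarray], np.ndarray],
    theta: np.ndarray,
    rel_step: float = 1e-6,
) -> np.ndarray:
    """Central finite-difference gradient of fn w.r.t. theta.

    fn maps a parameter vector to an m-vector of outputs; returns an m x p
    array.  The step for parameter i is rel_step * max(|theta_i|, 1).
    """
    theta = np.asarray(theta, dtype=float)
    p = theta.size
    cols = []
    for i in range(p):
        h = rel_step * max(abs(theta[i]), 1.0)
        up = theta.copy()
        dn = theta.copy()
        up[i] += h
        dn[i] -= h
        cols.append((np.asarray(fn(up), dtype=float) - np.asarray(fn(dn), dtype=float)) / (2 * h))
    return np.column_stack(cols)


def prediction_band(
    model: Callable[..., np.ndarray],
    params: np.ndarray,
    C,
    s2: float,
    times,
    grad_fn: Optional[Callable[[np.ndarray, np.ndarray], np.ndarray]] = None,
) -> PredictionBand:
    """Delta-method 95% prediction band for a fitted curve.

    model(times, theta) evaluates the curve; sigma^2(t) is
    grad^T C grad + s2 and the bounds are mean +/- 1.96 sigma.  Gradients
    come from ``grad_fn(times, theta)`` when registered, otherwise central
    finite differences with relative step 1e-6.
    """
    times = np.asarray(times, dtype=float)
    theta = np.asarray(params, dtype=float)
    C = np.asarray(C, dtype=float)
    mean = np.asarray(model(times, theta), dtype=float)
    if grad_fn is not None:
        G = np.asarray(grad_fn(times, theta), dtype=float)
    else:
        G = numerical_gradient(lambda th: model(times, th), theta)
    var = np.einsum("ij,jk,ik->i", G, C, G) + float(s2)
    var[var < 0] = 0.0
    sigma = np.sqrt(var)
    half = Z95 * sigma
    return PredictionBand(times=times, mean=mean, sigma=sigma,
                          lower=mean - half, upper=mean + half)


def bootstrap_band(
    train_fn: Callable[[Tuple[np.ndarray, np.ndarray], int], Callable[[np.ndarray], np.ndarray]],
    train_data: Tuple[np.ndarray, np.ndarray],
    query_points,
    B: int = 100,
    seed: int = 0,
) -> PredictionBand:
    """Non-parametric percentile bootstrap band over B refits.

    train_fn(data, seed) must train on ``data = (X, y)`` and return a
    prediction callable; rows of X and y are resampled jointly with
    replacement B times, the model is refit on each resample, and the band
    bounds are the 2.5th / 97.5th percentiles of the B predictions at each
    query point (mean = average prediction).  Deterministic for fixed seed.
    """
    if B < 2:
        raise DomainError("bootstrap needs at least 2 iterations")
    X, y = train_data
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = len(y)
    query = np.asarray(query_points, dtype=float)
    qx = query[:, None] if query.ndim == 1 else query
    rng = np.random.default_rng(seed)
    preds = np.empty((B, len(qx)))
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        predict = train_fn((X[idx], y[idx]), int(rng.integers(0, 2**31 - 1)))
        preds[b] = np.asarray(predict(qx), dtype=float).ravel()
    lower = np.percentile(preds, 2.5, axis=0)
    upper = np.percentile(preds, 97.5, axis=0)
    mean = preds.mean(axis=0)
    sigma = preds.std(axis=0, ddof=1)
    times = query if query.ndim == 1 else query[:, 0]
    return PredictionBand(times=times, mean=mean, sigma=sigma, lower=lower, upper=upper)
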