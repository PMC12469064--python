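"""Machine-learning regression workflow for growth/inactivation data.

Features are exactly (time, one environmental variable); the response is
the log10 count.  The pipeline: canonical row ordering -> stratified 80/20
split on the condition -> z-score feature scaling fitted on training rows
only -> small-sample augmentation of the training rows (resample with
replacement up to 750 rows, uniform +/-0.2 log CFU noise on the resampled
responses) -> regressor fit -> 5-fold cross-validation and held-out
metrics -> 95% uncertainty band (analytic for GPR, percentile bootstrap
with 100 refits for SVR/RFR).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.model_selection import GridSearchCV, KFold, train_test_split
from sklearn.svm import SVR

from .datatypes import MLConfig, MLResult, PredictionBand
from .errors import DegenerateDataError, DomainError
from .metrics import r_squared, rmse
from .uncertainty import Z95, bootstrap_band

__all__ = [
    "Scaler",
    "zscore_fit",
    "zscore_apply",
    "zscore_invert",
    "augment",
    "stratified_split",
    "cross_validate",
    "fit_ml",
]

ALGORITHMS = ("gpr", "svr", "rfr")


@dataclass(frozen=True)
class Scaler:
    """Per-feature z-score parameters (mean and population sd)."""

    mean: np.ndarray
    sd: np.ndarray


def zscore_fit(features) -> Scaler:
    """Fit per-column z-score parameters; constant columns get sd 1."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # population sd
    sd = np.where(sd == 0.0, 1.0, sd)
    return Scaler(mean=mean, sd=sd)


def zscore_apply(scaler: Scaler, features) -> np.ndarray:
    X = np.atleast_2d(np.asarray(features, dtype=float))
    return (X - scaler.mean) / scaler.sd


def zscore_invert(scaler: Scaler, scaled) -> np.ndarray:
    X = np.atleast_2d(np.asarray(scaled, dtype=float))
    return X * scaler.sd + scaler.mean


def augment(features, response, config: MLConfig,
            rng: Optional[np.random.Generator] = None
            ) -> Tuple[np.ndarray, np.ndarray]:
    """Resample a small training set up to ``config.augment_threshold`` rows.

    Rows are drawn with replacement from the originals; features are
    copied unchanged while each added response gets uniform noise in
    +/- ``config.augment_noise`` log CFU.  Inputs at or above the
    threshold are returned unchanged.  Apply to training rows only.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(response, dtype=float)
    n = len(y)
    if n >= config.augment_threshold:
        return X, y
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_extra = config.augment_threshold - n
    idx = rng.integers(0, n, size=n_extra)
    noise = rng.uniform(-config.augment_noise, config.augment_noise, size=n_extra)
    return np.vstack([X, X[idx]]), np.concatenate([y, y[idx] + noise])


def stratified_split(features, response, condition, test_fraction: float,
                     seed: int):
    """Stratified train/test split preserving the condition distribution.

    Falls back to a plain split when any condition level is too small to
    stratify (fewer than 2 rows per class).
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(response, dtype=float)
    cond = np.asarray(condition)
    idx = np.arange(len(y))
    _, counts = np.unique(cond, return_counts=True)
    strat = cond if (len(counts) > 1 and counts.min() >= 2) else None
    tr, te = train_test_split(idx, test_size=test_fraction, random_state=seed,
                              stratify=strat)
    tr = np.sort(tr)
    te = np.sort(te)
    return (X[tr], y[tr]), (X[te], y[te])


def _median_heuristic_gamma(X: np.ndarray) -> float:
    """RBF width from the median pairwise squared distance."""
    n = len(X)
    if n > 400:  # subsample for the quantile; deterministic
        X = X[:: n // 400 + 1]
    d2 = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=-1)
    med = np.median(d2[np.triu_indices_from(d2, k=1)])
    return 1.0 / med if med > 0 else 1.0


def _make_regressor(algorithm: str, X_train: np.ndarray, y_train: np.ndarray,
                    config: MLConfig, seed: int):
    """Construct and fit the requested regressor on scaled training data."""
    if algorithm == "gpr":
        kernel = (ConstantKernel(1.0, (1e-3, 1e3))
                  * RBF(length_scale=1.0, length_scale_bounds=(1e-2, 1e2))
                  + WhiteKernel(1e-2, (1e-10, 1e1)))
        model = GaussianProcessRegressor(
            kernel=kernel, normalize_y=True,
            n_restarts_optimizer=config.gpr_restarts, random_state=seed)
        model.fit(X_train, y_train)
        return model
    if algorithm == "svr":
        g0 = _median_heuristic_gamma(X_train)
        grid = {
            "C": [1.0, 10.0, 100.0],
            "epsilon": [0.01, 0.1],
            "gamma": [0.5 * g0, g0, 2.0 * g0],
        }
        search = GridSearchCV(
            SVR(kernel="rbf"), grid,
            cv=KFold(n_splits=5, shuffle=True, random_state=seed),
            scoring="neg_root_mean_squared_error", n_jobs=1)
        search.fit(X_train, y_train)
        return search.best_estimator_
    if algorithm == "rfr":
        model = RandomForestRegressor(n_estimators=config.rf_trees,
                                      random_state=seed, n_jobs=1)
        model.fit(X_train, y_train)
        return model
    raise DomainError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


def cross_validate(algorithm: str, features, response, folds: int = 5,
                   seed: int = 0, config: Optional[MLConfig] = None) -> float:
    """Across-fold average RMSE of the full per-fold pipeline.

    Scaling and augmentation are re-fit inside each training fold so no
    validation information leaks into preprocessing.
    """
    config = config or MLConfig()
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(response, dtype=float)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    rng = np.random.default_rng(seed)
    scores = []
    for k, (tr, va) in enumerate(kf.split(X)):
        scaler = zscore_fit(X[tr])
        Xa, ya = augment(zscore_apply(scaler, X[tr]), y[tr], config, rng)
        model = _make_regressor(algorithm, Xa, ya, config, seed + k)
        pred = model.predict(zscore_apply(scaler, X[va]))
        scores.append(rmse(y[va], pred, s=0))
    return float(np.mean(scores))


def fit_ml(algorithm: str, features, response, config: Optional[MLConfig] = None,
           condition: Optional[np.ndarray] = None) -> MLResult:
    """Run the full ML workflow on a (time, condition) feature table.

    ``features`` must have exactly two columns: time and one environmental
    variable.  ``condition`` defaults to the second feature column and
    drives the stratified split.  Returns metrics on the unscaled response
    plus a 95% band at the test points (GPR: analytic mean +/- 1.96 sigma;
    SVR/RFR: percentile bootstrap unless ``config.compute_band`` is off).
    """
    config = config or MLConfig()
    if algorithm not in ALGORITHMS:
        raise DomainError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(response, dtype=float)
    if X.shape[1] != 2:
        raise DomainError("features must be exactly (time, one environmental variable)")
    if len(y) < 10:
        raise DegenerateDataError("need at least 10 observations for ML fitting")
    if condition is None:
        condition = X[:, 1]

    # canonical ordering makes the pipeline invariant to input row order
    order = np.lexsort((y, X[:, 0], np.asarray(condition)))
    X, y = X[order], y[order]
    condition = np.asarray(condition)[order]

    (X_tr, y_tr), (X_te, y_te) = stratified_split(
        X, y, condition, config.test_fraction, config.seed)

    scaler = zscore_fit(X_tr)
    rng = np.random.default_rng(config.seed)
    Xa, ya = augment(zscore_apply(scaler, X_tr), y_tr, config, rng)
    model = _make_regressor(algorithm, Xa, ya, config, config.seed)

    pred_tr = model.predict(zscore_apply(scaler, X_tr))
    pred_te = model.predict(zscore_apply(scaler, X_te))
    cv = (cross_validate(algorithm, X_tr, y_tr, folds=config.cv_folds,
                         seed=config.seed, config=config)
          if config.compute_cv else float("nan"))

    band = None
    if config.compute_band:
        Xq = zscore_apply(scaler, X_te)
        if algorithm == "gpr":
            mean, sigma = model.predict(Xq, return_std=True)
            band = PredictionBand(times=X_te[:, 0], mean=mean, sigma=sigma,
                                  lower=mean - Z95 * sigma, upper=mean + Z95 * sigma)
        else:
            # bootstrap refits reuse the selected hyperparameters; re-running
            # the SVR grid search inside every replicate would be pure cost
            def train_fn(data, bseed):
                Xb, yb = data
                if algorithm == "svr":
                    m = SVR(kernel="rbf", C=model.C, epsilon=model.epsilon,
                            gamma=model.gamma)
                else:
                    m = RandomForestRegressor(n_estimators=config.rf_trees,
                                              random_state=bseed, n_jobs=1)
                m.fit(Xb, yb)
                return lambda q: m.predict(q)

            band = bootstrap_band(train_fn, (Xa, ya), Xq,
                                  B=config.bootstrap_iters, seed=config.seed)
            band.times = X_te[:, 0]

    return MLResult(
        algorithm=algorithm,
        scaler=scaler,
        model=model,
        train_rmse=rmse(y_tr, pred_tr, s=0),
        train_r2=r_squared(y_tr, pred_tr),
        test_rmse=rmse(y_te, pred_te, s=0),
        test_r2=r_squared(y_te, pred_te),
        cv_rmse=cv,
        band=band,
        extras={"n_train": int(len(y_tr)), "n_test": int(len(y_te)),
                "n_train_augmented": int(len(ya))},
    )
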