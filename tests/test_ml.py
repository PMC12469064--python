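"""ML workflow: scaling, augmentation, splitting, CV and regressors."""

import numpy as np
import pytest

from micropredict import (
    DegenerateDataError,
    augment,
    cross_validate,
    fit_ml,
    stratified_split,
    zscore_apply,
    zscore_fit,
)
from micropredict.datatypes import MLConfig, SimulationSpec
from micropredict.errors import DomainError
from micropredict.ml import _make_regressor, zscore_invert
from micropredict.synthetic import simulate_growth


def _growth_table(seed, noise_sd=0.3):
    spec = SimulationSpec(
        kind="growth", model_id="baranyi", conditions=[4.0, 10.0, 15.0, 20.0],
        primary={"x0": 3.5, "xmax": 9.5},
        secondary={"b1": 0.0014, "Xmin": -9.24, "b2": 1.29},
        noise_sd=noise_sd, seed=seed)
    return simulate_growth(spec).to_table()


def test_zscore_population_sd():
    sc = zscore_fit(np.array([[1.0], [2.0], [3.0]]))
    scaled = zscore_apply(sc, np.array([[1.0], [2.0], [3.0]]))
    np.testing.assert_allclose(scaled.ravel(),
                               [-np.sqrt(1.5), 0.0, np.sqrt(1.5)], atol=1e-12)
    assert scaled.ravel()[0] == pytest.approx(-1.2247, abs=1e-4)


def test_zscore_constant_column_guard_and_roundtrip():
    X = np.column_stack([np.arange(5.0), np.full(5, 7.0)])
    sc = zscore_fit(X)
    scaled = zscore_apply(sc, X)
    np.testing.assert_allclose(scaled[:, 1], 0.0)
    np.testing.assert_allclose(zscore_invert(sc, scaled), X, atol=1e-12)


def test_augment_contracts():
    cfg = MLConfig()
    rng = np.random.default_rng(0)
    X = np.column_stack([np.arange(10.0), np.full(10, 4.0)])
    y = np.linspace(3.0, 9.0, 10)
    Xa, ya = augment(X, y, cfg, rng)
    assert len(ya) == 750
    np.testing.assert_array_equal(Xa[:10], X)
    np.testing.assert_array_equal(ya[:10], y)
    # every added row copies some source row's features, response within 0.2
    for xa, yv in zip(Xa[10:], ya[10:]):
        src = np.where((X == xa).all(axis=1))[0]
        assert len(src) > 0
        assert np.min(np.abs(y[src] - yv)) <= 0.2 + 1e-12


def test_augment_disabled_at_threshold():
    cfg = MLConfig()
    X = np.ones((800, 2))
    y = np.zeros(800)
    Xa, ya = augment(X, y, cfg, np.random.default_rng(0))
    assert Xa is X and ya is y


def test_stratified_split_proportions():
    X = np.column_stack([np.arange(100.0), np.repeat([1.0, 2.0], 50)])
    y = np.arange(100.0)
    (Xtr, ytr), (Xte, yte) = stratified_split(X, y, X[:, 1], 0.2, seed=0)
    assert len(ytr) == 80 and len(yte) == 20
    for cond in (1.0, 2.0):
        assert np.sum(Xte[:, 1] == cond) == 10


def test_stratified_split_single_condition_plain():
    X = np.column_stack([np.arange(20.0), np.full(20, 5.0)])
    y = np.arange(20.0)
    (_, ytr), (_, yte) = stratified_split(X, y, X[:, 1], 0.25, seed=1)
    assert len(ytr) == 15 and len(yte) == 5


def test_stratified_split_reproducible():
    X = np.column_stack([np.arange(40.0), np.repeat([1.0, 2.0], 20)])
    y = np.arange(40.0)
    s1 = stratified_split(X, y, X[:, 1], 0.2, seed=7)
    s2 = stratified_split(X, y, X[:, 1], 0.2, seed=7)
    np.testing.assert_array_equal(s1[0][1], s2[0][1])
    np.testing.assert_array_equal(s1[1][1], s2[1][1])


def test_cross_validate_constant_response_zero_rmse():
    X = np.column_stack([np.arange(30.0), np.tile([1.0, 2.0, 3.0], 10)])
    y = np.full(30, 5.0)
    cfg = MLConfig(rf_trees=20, augment_noise=0.0)
    assert cross_validate("rfr", X, y, folds=5, seed=0, config=cfg) == pytest.approx(0.0, abs=1e-12)


def test_gpr_near_interpolation_on_noise_free_sigmoid():
    t = np.linspace(-3, 3, 40)
    X = np.column_stack([t, np.zeros_like(t)])
    y = 1.0 / (1.0 + np.exp(-2 * t))
    model = _make_regressor("gpr", X, y, MLConfig(gpr_restarts=2), seed=0)
    pred = model.predict(X)
    assert float(np.sqrt(np.mean((pred - y) ** 2))) < 1e-2


def test_fit_ml_requires_two_features_and_enough_rows():
    with pytest.raises(DomainError):
        fit_ml("gpr", np.ones((20, 3)), np.ones(20))
    with pytest.raises(DegenerateDataError):
        fit_ml("gpr", np.ones((5, 2)), np.ones(5))
    with pytest.raises(DomainError):
        fit_ml("mlp", np.ones((20, 2)), np.ones(20))


def test_scaler_uses_training_rows_only():
    tab = _growth_table(3)
    cfg = MLConfig(algorithm="rfr", rf_trees=30, compute_band=False,
                   compute_cv=False, seed=5)
    res = fit_ml("rfr", tab[:, :2], tab[:, 2], config=cfg)
    n_tr = res.extras["n_train"]
    assert n_tr == round(0.8 * len(tab))
    # the scaler mean must be reproducible from some 80% subset statistic,
    # not from the full table
    full = zscore_fit(tab[:, :2])
    assert not np.allclose(res.scaler.mean, full.mean)


def test_pipeline_invariant_to_row_order():
    tab = _growth_table(4)
    cfg = MLConfig(algorithm="rfr", rf_trees=50, compute_band=False,
                   compute_cv=False, seed=11)
    r1 = fit_ml("rfr", tab[:, :2], tab[:, 2], config=cfg)
    perm = np.random.default_rng(0).permutation(len(tab))
    r2 = fit_ml("rfr", tab[perm, :2], tab[perm, 2], config=cfg)
    assert r1.train_rmse == r2.train_rmse
    assert r1.test_rmse == r2.test_rmse


def test_rfr_bitwise_deterministic():
    tab = _growth_table(5)
    cfg = MLConfig(algorithm="rfr", compute_band=False, compute_cv=False, seed=2)
    r1 = fit_ml("rfr", tab[:, :2], tab[:, 2], config=cfg)
    r2 = fit_ml("rfr", tab[:, :2], tab[:, 2], config=cfg)
    grid = zscore_apply(r1.scaler, tab[:, :2])
    np.testing.assert_array_equal(r1.model.predict(grid), r2.model.predict(grid))
    assert r1.test_rmse == r2.test_rmse


def test_gpr_band_reasonable_coverage_of_truth():
    """GPR analytic band should cover the noise-free truth at most test points."""
    spec = SimulationSpec(
        kind="growth", model_id="baranyi", conditions=[4.0, 10.0, 15.0, 20.0],
        primary={"x0": 3.5, "xmax": 9.5},
        secondary={"b1": 0.0014, "Xmin": -9.24, "b2": 1.29},
        noise_sd=0.15, seed=31)
    ds = simulate_growth(spec)
    tab = ds.to_table()
    cfg = MLConfig(algorithm="gpr", gpr_restarts=2, compute_cv=False, seed=13)
    res = fit_ml("gpr", tab[:, :2], tab[:, 2], config=cfg)
    band = res.band
    # recover each test row's condition from its time value (grids are
    # condition-specific; the shared t=0 point has a condition-independent truth)
    from micropredict.fitting import growth_curve_log10

    rows = [(t, c.condition) for c in ds.curves for t in c.times]
    covered = 0
    for i, t in enumerate(band.times):
        cond = next(cd for tt, cd in rows if abs(tt - t) < 1e-9)
        mu = 0.0014 * (cond + 9.24) ** 2
        truth = float(growth_curve_log10("baranyi", t, 3.5, 9.5, mu, 1.29 / mu))
        covered += band.lower[i] - 1e-9 <= truth <= band.upper[i] + 1e-9
    assert covered / len(band.times) >= 0.85
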