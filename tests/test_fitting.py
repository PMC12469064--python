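"""Fitting workflows: heuristics, edge cases, consistency, invariants."""

import numpy as np
import pytest

from micropredict import (
    Curve,
    Dataset,
    DegenerateDataError,
    fit_one_step_growth,
    fit_primary_growth,
    fit_primary_inhibition,
    fit_secondary_growth,
    fit_secondary_inhibition,
    r_squared,
    rmse,
    run_two_step,
)
from micropredict.datatypes import SimulationSpec
from micropredict.fitting import (
    _one_step_growth_residual,
    growth_curve_log10,
    inhibition_curve_log10,
)
from micropredict.synthetic import simulate_growth


def test_flat_curve_rejected():
    t = np.linspace(0, 10, 8)
    with pytest.raises(DegenerateDataError):
        fit_primary_growth(Curve(times=t, values=np.full(8, 5.0), condition=5.0),
                           "baranyi")


def test_decreasing_data_rejected_as_growth():
    t = np.linspace(0, 10, 8)
    y = 7.0 - 0.3 * t
    with pytest.raises(DegenerateDataError):
        fit_primary_growth(Curve(times=t, values=y, condition=5.0), "gompertz")


def test_increasing_data_rejected_as_inhibition():
    t = np.linspace(0, 100, 8)
    y = 3.0 + 0.05 * t
    with pytest.raises(DegenerateDataError):
        fit_primary_inhibition(Curve(times=t, values=y, condition=50.0), "weibull")


def test_too_few_observations_rejected():
    with pytest.raises(DegenerateDataError):
        fit_primary_growth(Curve(times=np.arange(4.0), values=np.array([3, 5, 7, 9.0]),
                                 condition=5.0), "baranyi")


def test_loglinear_data_fit_by_weibull_returns_unit_shape():
    """Weibull nests the log-linear model: p -> 1 on log-linear truth."""
    t = np.array([0.0, 15, 30, 60, 120, 180, 240, 300, 360])
    y = np.asarray(inhibition_curve_log10("loglinear", t, (7.0, 0.01)))
    fr = fit_primary_inhibition(Curve(times=t, values=y, condition=50.0), "weibull")
    assert fr.params["p"] == pytest.approx(1.0, abs=1e-5)
    assert fr.params["delta"] == pytest.approx(100.0, rel=1e-4)


def test_fit_statistics_recomputable_via_metrics_module(baranyi_curve, rng):
    y = baranyi_curve.values + 0.1 * rng.standard_normal(len(baranyi_curve))
    curve = Curve(times=baranyi_curve.times, values=y, condition=20.0)
    fr = fit_primary_growth(curve, "baranyi")
    pred = np.asarray(growth_curve_log10(
        "baranyi", curve.times, fr.params["y0"], fr.params["ymax"],
        fr.params["mumax"], fr.params["lag"]))
    assert fr.rmse == pytest.approx(rmse(y, pred, s=fr.n_params), rel=1e-9)
    assert fr.r2 == pytest.approx(r_squared(y, pred), rel=1e-9)
    assert np.allclose(fr.std_errors, np.sqrt(np.diag(fr.covariance)))


def test_estimator_consistency_with_sample_size():
    """mumax bias shrinks as the per-curve sample size grows."""
    biases = {}
    for n in (10, 40, 160):
        rng = np.random.default_rng(1000 + n)
        errs = []
        for i in range(15):
            t = np.linspace(0.0, 60.0, n)
            truth = np.asarray(growth_curve_log10("baranyi", t, 3.0, 9.0, 0.2, 5.0))
            y = truth + 0.15 * rng.standard_normal(n)
            fr = fit_primary_growth(Curve(times=t, values=y, condition=20.0),
                                    "baranyi", seed=i)
            errs.append(fr.extras["mumax"] - 0.2)
        biases[n] = abs(float(np.mean(errs)))
    assert biases[160] < biases[10] + 0.002
    assert biases[160] < 0.01


def test_secondary_growth_exact_recovery():
    mus = {X: 0.0014 * (X + 9.24) ** 2 for X in (2.0, 4.0, 10.0, 15.0, 20.0)}
    table = {X: (m, 1.29 / m) for X, m in mus.items()}
    fr = fit_secondary_growth(table)
    assert fr.params["b1"] == pytest.approx(0.0014, rel=1e-6)
    assert fr.params["Xmin"] == pytest.approx(-9.24, rel=1e-6)
    assert fr.params["b2"] == pytest.approx(1.29, rel=1e-6)


def test_secondary_growth_noisy_recovery():
    rng = np.random.default_rng(4)
    X = np.array([2.0, 4.0, 10.0, 15.0, 20.0])
    mu_true = 0.0014 * (X + 9.24) ** 2
    ests = []
    for _ in range(30):
        mus = mu_true * np.exp(0.05 * rng.standard_normal(5))
        fr = fit_secondary_growth({x: (m, 1.29 / m) for x, m in zip(X, mus)})
        ests.append([fr.params["b1"], fr.params["Xmin"]])
    mean = np.mean(ests, axis=0)
    sd = np.std(ests, axis=0)
    assert abs(mean[0] - 0.0014) < 3 * sd[0] / np.sqrt(30) + 1e-5
    assert abs(mean[1] + 9.24) < 3 * sd[1] / np.sqrt(30) + 0.05


def test_secondary_inhibition_exact_recovery():
    table = {X: 64.49 - 26.92 * np.log10(X) for X in (50.0, 100.0, 150.0, 200.0)}
    fr = fit_secondary_inhibition(table)
    assert fr.params["a"] == pytest.approx(64.49, rel=1e-9)
    assert fr.params["b"] == pytest.approx(26.92, rel=1e-9)


def _growth_dataset(noise_sd, seed):
    spec = SimulationSpec(
        kind="growth", model_id="gompertz",
        conditions=[2.0, 4.0, 10.0, 15.0, 20.0],
        primary={"x0": 3.97, "xmax": 9.66},
        secondary={"b1": 0.0014, "Xmin": -9.24, "b2": 1.29},
        noise_sd=noise_sd, seed=seed)
    return simulate_growth(spec)


def test_two_step_composition_identity():
    """run_two_step output equals manually chaining the stages."""
    ds = _growth_dataset(0.2, 21)
    res = run_two_step(ds, "gompertz", seed=5)
    for curve in ds.curves:
        manual = fit_primary_growth(curve, "gompertz", seed=5)
        np.testing.assert_array_equal(
            res.primary_fits[curve.condition].estimates, manual.estimates)
    table = {X: (fr.extras["mumax"], fr.params["lag"])
             for X, fr in res.primary_fits.items()}
    manual_sec = fit_secondary_growth(table, seed=5)
    np.testing.assert_array_equal(res.secondary_fit.estimates, manual_sec.estimates)


def test_one_step_sse_never_exceeds_frozen_two_step():
    ds = _growth_dataset(0.3, 33)
    one = fit_one_step_growth(ds, "gompertz", seed=9)
    two = run_two_step(ds, "gompertz", seed=9)
    b1, Xmin, b2 = two.secondary_fit.estimates
    y0 = float(np.mean([fr.estimates[0] for fr in two.primary_fits.values()]))
    span = float(np.mean([fr.estimates[1] - fr.estimates[0]
                          for fr in two.primary_fits.values()]))
    frozen = _one_step_growth_residual("gompertz", ds.curves)(
        np.array([y0, span, Xmin, b1, b2]))
    assert one.sse <= float(frozen @ frozen) + 1e-9


def test_one_step_requires_multiple_conditions():
    ds = _growth_dataset(0.1, 2)
    single = Dataset(curves=[ds.curves[0]], kind="growth")
    with pytest.raises(DegenerateDataError):
        fit_one_step_growth(single, "gompertz")


def test_run_two_step_pools_replicate_curves():
    spec = SimulationSpec(
        kind="growth", model_id="baranyi", conditions=[10.0, 15.0, 20.0],
        primary={"x0": 3.0, "xmax": 9.0},
        secondary={"b1": 0.0014, "Xmin": -9.24, "b2": 1.29},
        noise_sd=0.15, replicates=2, seed=77)
    ds = simulate_growth(spec)
    res = run_two_step(ds, "baranyi", seed=7)
    assert set(res.primary_fits) == {10.0, 15.0, 20.0}
    # each pooled fit saw both replicates
    assert all(fr.n_obs == 30 for fr in res.primary_fits.values())
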