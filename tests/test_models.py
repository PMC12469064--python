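"""Primary-model evaluators: anchor values, limits, invariants, oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from micropredict import (
    GrowthParamsLn,
    GrowthParamsLog10,
    InhibitionParams,
    ParameterError,
    eval_baranyi,
    eval_gompertz,
    eval_huang,
    eval_logistic,
    eval_loglinear,
    eval_loglinear_tail,
    eval_weibull,
    mumax_to_rmax,
    rmax_to_mumax,
)

GROWTH_LOG10 = {"gompertz": eval_gompertz, "logistic": eval_logistic}
GROWTH_LN = {"baranyi": eval_baranyi, "huang": eval_huang}


# --- direct, unstabilised re-evaluations used as independent oracles -------

def _gompertz_direct(t, x0, xmax, rmax, lag):
    return x0 + (xmax - x0) * math.exp(
        -math.exp(rmax * math.e / (xmax - x0) * (lag - t) + 1.0))


def _logistic_direct(t, x0, xmax, rmax, lag):
    return x0 + (xmax - x0) / (1.0 + math.exp(4.0 * rmax / (xmax - x0) * (lag - t) + 2.0))


def _huang_direct(t, y0, ymax, mu, lag):
    B = t + 0.25 * math.log((1.0 + math.exp(-4.0 * (t - lag)))
                            / (1.0 + math.exp(4.0 * lag)))
    return y0 + ymax - math.log(
        math.exp(y0) + (math.exp(ymax) - math.exp(y0)) * math.exp(-mu * B))


def _baranyi_ode(t_eval, y0, ymax, mu, lag):
    """Numerical integration of the growth ODE with explicit adjustment.

    The physiological state q(t) = q0 exp(mu t), q0 = 1/(exp(mu*lag) - 1),
    has a closed solution, so only dy/dt = mu * q/(1+q) * (1 - exp(y - ymax))
    is integrated; the adjustment factor q/(1+q) is a logistic in t, written
    through its log for numerical stability at tiny q0.
    """
    log_q0 = -math.log(math.expm1(mu * lag))

    def rhs(t, state):
        alpha = 1.0 / (1.0 + math.exp(-(mu * t + log_q0)))
        return [mu * alpha * (1.0 - math.exp(state[0] - ymax))]

    sol = solve_ivp(rhs, (0.0, float(t_eval[-1])), [y0], t_eval=t_eval,
                    method="DOP853", rtol=1e-12, atol=1e-13)
    assert sol.success
    return sol.y[0]


def test_gompertz_anchors():
    p = GrowthParamsLog10(3.0, 9.0, 0.2, 5.0)
    # at t = lag the double exponential collapses to exp(-e)
    assert eval_gompertz(5.0, p) == pytest.approx(3.0 + 6.0 * math.exp(-math.e), abs=1e-12)
    assert eval_gompertz(1e6, p) == pytest.approx(9.0, abs=1e-9)
    p2 = GrowthParamsLog10(3.0, 9.0, 0.1, 10.0)
    assert eval_gompertz(30.0, p2) == pytest.approx(
        _gompertz_direct(30.0, 3.0, 9.0, 0.1, 10.0), abs=1e-12)


def test_logistic_anchors():
    p = GrowthParamsLog10(3.0, 9.0, 0.2, 5.0)
    assert eval_logistic(5.0, p) == pytest.approx(3.0 + 6.0 / (1.0 + math.e**2), abs=1e-12)
    assert eval_logistic(1e6, p) == pytest.approx(9.0, abs=1e-9)


@pytest.mark.parametrize("fn", [eval_baranyi, eval_huang])
def test_ln_models_identity_at_origin_and_limit(fn):
    p = GrowthParamsLn(7.0, 21.0, 0.24, 5.0)
    assert float(fn(0.0, p)) == pytest.approx(7.0, abs=1e-9)
    assert float(fn(1e6, p)) == pytest.approx(21.0, abs=1e-6)


def test_baranyi_matches_ode_integration():
    """Closed form vs numerical integration of the two-state system."""
    rng = np.random.default_rng(42)
    for _ in range(100):
        y0 = rng.uniform(2.0, 10.0)
        ymax = y0 + rng.uniform(3.0, 15.0)
        mu = rng.uniform(0.05, 1.5)
        lag = rng.uniform(0.2, 20.0)
        horizon = lag + (ymax - y0) / mu * 3.0
        t = np.linspace(1e-3, horizon, 7)
        closed = eval_baranyi(t, GrowthParamsLn(y0, ymax, mu, lag))
        ode = _baranyi_ode(t, y0, ymax, mu, lag)
        np.testing.assert_allclose(closed, ode, atol=1e-8)


def test_huang_matches_direct_formula():
    rng = np.random.default_rng(7)
    for _ in range(100):
        y0 = rng.uniform(2.0, 10.0)
        ymax = y0 + rng.uniform(3.0, 15.0)
        mu = rng.uniform(0.05, 1.5)
        lag = rng.uniform(0.0, 20.0)
        t = rng.uniform(0.0, lag + (ymax - y0) / mu * 2.0)
        got = float(eval_huang(t, GrowthParamsLn(y0, ymax, mu, lag)))
        assert got == pytest.approx(_huang_direct(t, y0, ymax, mu, lag), abs=1e-8)


def test_log10_models_match_direct_formula():
    rng = np.random.default_rng(11)
    for _ in range(100):
        x0 = rng.uniform(1.0, 5.0)
        xmax = x0 + rng.uniform(1.0, 7.0)
        rmax = rng.uniform(0.02, 0.8)
        lag = rng.uniform(0.0, 30.0)
        t = rng.uniform(0.0, lag + (xmax - x0) / rmax * 2.0)
        p = GrowthParamsLog10(x0, xmax, rmax, lag)
        assert float(eval_gompertz(t, p)) == pytest.approx(
            _gompertz_direct(t, x0, xmax, rmax, lag), abs=1e-8)
        assert float(eval_logistic(t, p)) == pytest.approx(
            _logistic_direct(t, x0, xmax, rmax, lag), abs=1e-8)


@pytest.mark.parametrize("model", ["gompertz", "logistic", "baranyi", "huang"])
def test_growth_monotone_and_bounded(model):
    """Every growth model is non-decreasing and stays within [initial, max]."""
    rng = np.random.default_rng(3)
    for _ in range(25):
        lo = rng.uniform(1.0, 6.0)
        hi = lo + rng.uniform(1.0, 12.0)
        mu = rng.uniform(0.05, 1.0)
        lag = rng.uniform(0.0, 15.0)
        horizon = lag + (hi - lo) / mu * 4.0
        t = np.linspace(0.0, horizon, 300)
        if model in GROWTH_LOG10:
            y = GROWTH_LOG10[model](t, GrowthParamsLog10(lo, hi, mu, lag))
        else:
            y = GROWTH_LN[model](t, GrowthParamsLn(lo, hi, mu, lag))
        assert np.all(np.diff(y) >= -1e-9)
        assert y.min() >= lo - 1e-9
        assert y.max() <= hi + 1e-6


def test_inhibition_anchors():
    assert float(eval_loglinear(0.0, InhibitionParams(logN0=7.0, k=0.01))) == 7.0
    assert float(eval_loglinear(100.0, InhibitionParams(logN0=7.0, k=0.01))) == pytest.approx(6.0)
    assert float(eval_loglinear(57.0, InhibitionParams(logN0=7.0, k=0.0123))) == pytest.approx(
        7.0 - 0.7011, abs=1e-12)
    tail = InhibitionParams(logN0=7.0, k=0.02, logNres=3.0)
    assert float(eval_loglinear_tail(0.0, tail)) == pytest.approx(7.0)
    assert float(eval_loglinear_tail(60.0, tail)) == pytest.approx(
        3.0 + 4.0 * math.exp(-1.2), abs=1e-12)
    assert float(eval_loglinear_tail(1e9, tail)) == pytest.approx(3.0, abs=1e-9)
    wb = InhibitionParams(logN0=7.0, delta=20.43, p=0.33)
    assert float(eval_weibull(360.0, wb)) == pytest.approx(
        7.0 - (360.0 / 20.43) ** 0.33, abs=1e-12)


@pytest.mark.parametrize("p", [0.3, 1.0, 2.5])
def test_weibull_first_decimal_reduction_at_delta(p):
    wb = InhibitionParams(logN0=7.0, delta=42.0, p=p)
    assert float(eval_weibull(42.0, wb)) == pytest.approx(6.0, abs=1e-12)


@settings(max_examples=50, derandomize=True)
@given(delta=st.floats(0.5, 500.0), logN0=st.floats(2.0, 10.0))
def test_weibull_p1_equals_loglinear(delta, logN0):
    t = np.linspace(0.0, 360.0, 200)
    wb = eval_weibull(t, InhibitionParams(logN0=logN0, delta=delta, p=1.0))
    ll = eval_loglinear(t, InhibitionParams(logN0=logN0, k=1.0 / delta))
    assert np.max(np.abs(wb - ll)) < 1e-9 * max(1.0, 360.0 / delta)


def test_rate_conversion_roundtrip():
    assert rmax_to_mumax(0.0) == 0.0
    assert rmax_to_mumax(0.1) == pytest.approx(0.1 * math.log(10.0), abs=1e-12)
    for r in [0.01, 0.3, 2.0]:
        assert mumax_to_rmax(rmax_to_mumax(r)) == pytest.approx(r, rel=1e-15)


def test_overflow_safe_at_extreme_arguments():
    p = GrowthParamsLn(7.0, 23.0, 2.0, 3.0)
    vals = eval_baranyi(np.array([0.0, 1e4, 1e6]), p)
    assert np.all(np.isfinite(vals))
    vals = eval_huang(np.array([0.0, 1e4, 1e6]), p)
    assert np.all(np.isfinite(vals))


@pytest.mark.parametrize("make", [
    lambda: GrowthParamsLog10(9.0, 3.0, 0.1, 1.0),   # xmax below x0
    lambda: GrowthParamsLog10(3.0, 9.0, -0.1, 1.0),  # negative rate
    lambda: GrowthParamsLn(3.0, 9.0, 0.1, -1.0),     # negative lag
    lambda: InhibitionParams(logN0=7.0, delta=-2.0, p=0.5),
    lambda: InhibitionParams(logN0=7.0, k=0.1, logNres=8.0),  # tail above start
    lambda: InhibitionParams(logN0=7.0, delta=5.0, p=0.0),
])
def test_invalid_parameters_raise(make):
    with pytest.raises(ParameterError):
        make()
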