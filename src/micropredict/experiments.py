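"""Parameter-recovery validation experiments.

Each experiment simulates datasets whose generating truths are published
kinetic-parameter estimates for the target systems (Pseudomonas growth on
chicken fillets at 2-20 degC; chlorine inactivation of Listeria on
stainless steel at 50-200 mg/L), runs the corresponding estimator on every
replicate, and reports the mean recovered parameters.  They double as the
package's end-to-end validation surface: an unbiased, converging fitter
should return the generating values on average.

All randomness flows from a single integer seed through a SeedSequence,
so results are exactly reproducible.
"""

from __future__ import annotations

from typing import Dict, List

import numpy as np

from .datatypes import Dataset, MLConfig, SimulationSpec
from .fitting import (
    DEFAULT_SEED,
    fit_one_step_growth,
    fit_one_step_inhibition,
    fit_primary_growth,
    fit_primary_inhibition,
)
from .ml import fit_ml
from .synthetic import simulate_growth, simulate_inhibition

__all__ = [
    "BARANYI_20C_TRUTH",
    "WEIBULL_50MGL_TRUTH",
    "ONE_STEP_GROWTH_TRUTH",
    "ONE_STEP_INHIBITION_TRUTH",
    "GROWTH_TEMPS",
    "CHLORINE_LEVELS",
    "two_step_growth_recovery",
    "two_step_inhibition_recovery",
    "one_step_growth_recovery",
    "one_step_inhibition_recovery",
    "ml_ordering_experiment",
]

#: Baranyi truth at 20 degC: initial/maximum population (log10 CFU/g),
#: maximum specific growth rate (1/h) and lag (h)
BARANYI_20C_TRUTH = dict(x0=3.03, xmax=8.19, mumax=0.243, lag=2.0)

#: Weibull truth at 50 mg/L free chlorine: logN0 (log10 CFU/cm2),
#: first-decimal-reduction time delta (s) and shape p
WEIBULL_50MGL_TRUTH = dict(logN0=7.0, delta=20.43, p=0.33)

#: one-step modified-Gompertz truth: shared y0/ymax (log10 CFU/g) plus the
#: secondary coefficients mumax(T) = b1 (T - Tmin)^2, lag = b2 / mumax
ONE_STEP_GROWTH_TRUTH = dict(x0=3.97, xmax=9.66, Xmin=-9.24, b1=0.0014, b2=1.29)

#: one-step Weibull truth: delta(C) = a - b log10(C), shared shape and logN0
ONE_STEP_INHIBITION_TRUTH = dict(logN0=7.0, a=64.49, b=26.92, p=0.33)

GROWTH_TEMPS = [2.0, 4.0, 10.0, 15.0, 20.0]
CHLORINE_LEVELS = [50.0, 100.0, 150.0, 200.0]

#: per-temperature Baranyi truths used by the ML ordering experiment
#: (two-step per-temperature estimates; lag tied to the rate via b2 = 1.29)
PER_TEMP_BARANYI_TRUTH = {
    2.0: dict(x0=3.71, xmax=9.94, mumax=0.024),
    4.0: dict(x0=3.83, xmax=9.61, mumax=0.035),
    10.0: dict(x0=3.32, xmax=9.87, mumax=0.076),
    15.0: dict(x0=4.24, xmax=9.46, mumax=0.178),
    20.0: dict(x0=3.03, xmax=8.19, mumax=0.243),
}


def _child_seeds(seed: int, n: int) -> List[int]:
    """n reproducible integer seeds below 2**31 derived from one seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def two_step_growth_recovery(seed: int = DEFAULT_SEED, n_rep: int = 100,
                             noise_sd: float = 0.15) -> Dict[str, float]:
    """Repeatedly fit the Baranyi model to synthetic 20 degC growth curves.

    Each replicate: 16 times evenly spaced over 0-72 h, truth =
    BARANYI_20C_TRUTH, Gaussian noise on the log10 counts.  Returns the
    mean recovered parameters over ``n_rep`` replicates.
    """
    truth = BARANYI_20C_TRUTH
    spec = SimulationSpec(
        kind="growth", model_id="baranyi", conditions=[20.0],
        primary=dict(truth), times=np.linspace(0.0, 72.0, 16),
        noise_sd=noise_sd, replicates=n_rep, seed=seed)
    ds = simulate_growth(spec)
    mus, lags, y0s, ymaxs = [], [], [], []
    for curve, s in zip(ds.curves, _child_seeds(seed, n_rep)):
        fr = fit_primary_growth(curve, "baranyi", seed=s)
        mus.append(fr.extras["mumax"])
        lags.append(fr.params["lag"])
        y0s.append(fr.params["y0"])
        ymaxs.append(fr.params["ymax"])
    return {
        "mean_mumax": float(np.mean(mus)),
        "mean_lag": float(np.mean(lags)),
        "mean_y0": float(np.mean(y0s)),
        "mean_ymax": float(np.mean(ymaxs)),
        "n_rep": n_rep,
    }


def two_step_inhibition_recovery(seed: int = DEFAULT_SEED, n_rep: int = 100,
                                 noise_sd: float = 0.10) -> Dict[str, float]:
    """Repeatedly fit the Weibull model to synthetic 50 mg/L survival curves.

    Each replicate: the standard 0-360 s exposure grid, truth =
    WEIBULL_50MGL_TRUTH, Gaussian noise sd 0.10 log.  Returns mean
    recovered delta and p.
    """
    truth = WEIBULL_50MGL_TRUTH
    spec = SimulationSpec(
        kind="inhibition", model_id="weibull", conditions=[50.0],
        primary=dict(truth), noise_sd=noise_sd, replicates=n_rep, seed=seed)
    ds = simulate_inhibition(spec)
    deltas, ps = [], []
    for curve, s in zip(ds.curves, _child_seeds(seed, n_rep)):
        fr = fit_primary_inhibition(curve, "weibull", seed=s)
        deltas.append(fr.params["delta"])
        ps.append(fr.params["p"])
    return {
        "mean_delta": float(np.mean(deltas)),
        "mean_p": float(np.mean(ps)),
        "n_rep": n_rep,
    }


def one_step_growth_recovery(seed: int = DEFAULT_SEED, n_rep: int = 20,
                             noise_sd: float = 0.3) -> Dict[str, float]:
    """One-step modified-Gompertz recovery across five temperatures.

    Each replicate dataset: curves at 2/4/10/15/20 degC, 15 points spanning
    lag through stationary phase, truth = ONE_STEP_GROWTH_TRUTH with
    mumax(T) = b1 (T - Tmin)^2 and lag = b2/mumax, noise sd 0.3 log.
    """
    truth = ONE_STEP_GROWTH_TRUTH
    spec = SimulationSpec(
        kind="growth", model_id="gompertz", conditions=GROWTH_TEMPS,
        primary={"x0": truth["x0"], "xmax": truth["xmax"]},
        secondary={"b1": truth["b1"], "Xmin": truth["Xmin"], "b2": truth["b2"]},
        noise_sd=noise_sd, replicates=n_rep, seed=seed)
    all_curves = simulate_growth(spec).curves
    tmins, b1s, b2s = [], [], []
    for r, s in enumerate(_child_seeds(seed, n_rep)):
        ds = Dataset(curves=[all_curves[ci * n_rep + r]
                             for ci in range(len(GROWTH_TEMPS))], kind="growth")
        fr = fit_one_step_growth(ds, "gompertz", seed=s)
        tmins.append(fr.params["Xmin"])
        b1s.append(fr.params["b1"])
        b2s.append(fr.params["b2"])
    return {
        "mean_Tmin": float(np.mean(tmins)),
        "mean_b1": float(np.mean(b1s)),
        "mean_b2": float(np.mean(b2s)),
        "n_rep": n_rep,
    }


def one_step_inhibition_recovery(seed: int = DEFAULT_SEED, n_rep: int = 50,
                                 noise_sd: float = 0.15) -> Dict[str, float]:
    """One-step Weibull recovery across four chlorine concentrations.

    Each replicate dataset: curves at 50/100/150/200 mg/L on the 0-360 s
    grid, truth = ONE_STEP_INHIBITION_TRUTH with delta(C) = a - b log10(C),
    noise sd 0.15 log.
    """
    truth = ONE_STEP_INHIBITION_TRUTH
    spec = SimulationSpec(
        kind="inhibition", model_id="weibull", conditions=CHLORINE_LEVELS,
        primary={"logN0": truth["logN0"], "p": truth["p"]},
        secondary={"a": truth["a"], "b": truth["b"]},
        noise_sd=noise_sd, replicates=n_rep, seed=seed)
    all_curves = simulate_inhibition(spec).curves
    aa, bb, pp = [], [], []
    for r, s in enumerate(_child_seeds(seed, n_rep)):
        ds = Dataset(curves=[all_curves[ci * n_rep + r]
                             for ci in range(len(CHLORINE_LEVELS))],
                     kind="inhibition")
        fr = fit_one_step_inhibition(ds, "weibull", seed=s)
        aa.append(fr.params["a"])
        bb.append(fr.params["b"])
        pp.append(fr.params["p"])
    return {
        "mean_a": float(np.mean(aa)),
        "mean_b": float(np.mean(bb)),
        "mean_p": float(np.mean(pp)),
        "n_rep": n_rep,
    }


def ml_ordering_experiment(seed: int = DEFAULT_SEED, n_rep: int = 50,
                           noise_sd: float = 0.3,
                           gpr_restarts: int = 0) -> Dict[str, float]:
    """Repeated GPR/SVR/RFR comparison on synthetic multi-temperature growth data.

    Each repetition simulates Baranyi growth curves at the five study
    temperatures from the per-temperature truths (15 points per curve,
    noise sd 0.3 log), runs the full ML pipeline for each algorithm, and
    records the held-out test RMSEs.  Returns the fraction of repetitions
    in which GPR and RFR beat SVR.  CV and bands are skipped and GPR uses
    a reduced restart count purely to size the repeated experiment.
    """
    gpr_wins = rfr_wins = 0
    test_rmses = {"gpr": [], "svr": [], "rfr": []}
    for s in _child_seeds(seed, n_rep):
        truth = {k: dict(v, lag=1.29 / v["mumax"])
                 for k, v in PER_TEMP_BARANYI_TRUTH.items()}
        spec = SimulationSpec(kind="growth", model_id="baranyi",
                              conditions=list(truth), primary=truth,
                              noise_sd=noise_sd, seed=s)
        tab = simulate_growth(spec).to_table()
        res = {}
        for alg in ("gpr", "svr", "rfr"):
            cfg = MLConfig(algorithm=alg, seed=s, compute_band=False,
                           compute_cv=False, gpr_restarts=gpr_restarts)
            res[alg] = fit_ml(alg, tab[:, :2], tab[:, 2], config=cfg).test_rmse
            test_rmses[alg].append(res[alg])
        gpr_wins += res["gpr"] < res["svr"]
        rfr_wins += res["rfr"] < res["svr"]
    return {
        "gpr_win_fraction": gpr_wins / n_rep,
        "rfr_win_fraction": rfr_wins / n_rep,
        "mean_test_rmse_gpr": float(np.mean(test_rmses["gpr"])),
        "mean_test_rmse_svr": float(np.mean(test_rmses["svr"])),
        "mean_test_rmse_rfr": float(np.mean(test_rmses["rfr"])),
        "n_rep": n_rep,
    }
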