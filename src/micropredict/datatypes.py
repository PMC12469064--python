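"""Shared containers: curves, datasets, fit results, configs, reports."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Dict, List, Mapping, Optional

import numpy as np

from .errors import DomainError

__all__ = [
    "Curve",
    "Dataset",
    "FitResult",
    "TwoStepResult",
    "PredictionBand",
    "MLConfig",
    "MLResult",
    "SimulationSpec",
    "Report",
]


@dataclass
class Curve:
    """One condition's time series of log10 counts.

    times are hours for growth and seconds for inactivation; values are
    log10 CFU/g (or log10 CFU/cm^2 for surface data).
    """

    times: np.ndarray
    values: np.ndarray
    condition: float
    condition_name: str = "temperature"
    response_units: str = "log CFU/g"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise DomainError("times and values must be 1-D arrays of equal length")
        if len(self.times) >= 2 and not np.all(np.diff(self.times) > 0):
            raise DomainError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class Dataset:
    """A collection of curves sharing one environmental variable."""

    curves: List[Curve]
    kind: str = "growth"  # growth | inhibition

    def __post_init__(self) -> None:
        if self.kind not in ("growth", "inhibition"):
            raise DomainError(f"kind must be 'growth' or 'inhibition', got {self.kind!r}")
        names = {c.condition_name for c in self.curves}
        if len(names) > 1:
            raise DomainError(f"curves mix condition names: {sorted(names)}")

    @property
    def conditions(self) -> np.ndarray:
        return np.array([c.condition for c in self.curves])

    @property
    def n_obs(self) -> int:
        return int(sum(len(c) for c in self.curves))

    def to_table(self) -> np.ndarray:
        """Stack to an (n, 3) array of (time, condition, response) rows."""
        rows = [
            np.column_stack([c.times, np.full(len(c), c.condition), c.values])
            for c in self.curves
        ]
        return np.vstack(rows) if rows else np.empty((0, 3))


@dataclass
class FitResult:
    """Outcome of a nonlinear least-squares fit.

    estimates/std_errors are aligned with param_names; covariance is the
    Gauss-Newton approximation s^2 (J^T J)^-1 in the reported
    parametrisation; resid_var is s^2 = SSE / (n - p).
    """

    model_id: str
    param_names: List[str]
    estimates: np.ndarray
    std_errors: np.ndarray
    covariance: np.ndarray
    resid_var: float
    n_obs: int
    n_params: int
    rmse: float
    r2: float
    sse: float
    sst: float
    extras: Dict[str, Any] = field(default_factory=dict)

    @property
    def params(self) -> Dict[str, float]:
        return {n: float(v) for n, v in zip(self.param_names, self.estimates)}

    def __getitem__(self, name: str) -> float:
        return self.params[name]

    def to_dict(self) -> Dict[str, Any]:
        return {
            "model_id": self.model_id,
            "param_names": list(self.param_names),
            "estimates": [float(v) for v in self.estimates],
            "std_errors": [float(v) for v in self.std_errors],
            "covariance": np.asarray(self.covariance).tolist(),
            "resid_var": float(self.resid_var),
            "n_obs": int(self.n_obs),
            "n_params": int(self.n_params),
            "rmse": float(self.rmse),
            "r2": float(self.r2),
            "sse": float(self.sse),
            "sst": float(self.sst),
            "extras": _jsonify(self.extras),
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "FitResult":
        return cls(
            model_id=d["model_id"],
            param_names=list(d["param_names"]),
            estimates=np.asarray(d["estimates"], dtype=float),
            std_errors=np.asarray(d["std_errors"], dtype=float),
            covariance=np.asarray(d["covariance"], dtype=float),
            resid_var=float(d["resid_var"]),
            n_obs=int(d["n_obs"]),
            n_params=int(d["n_params"]),
            rmse=float(d["rmse"]),
            r2=float(d["r2"]),
            sse=float(d["sse"]),
            sst=float(d["sst"]),
            extras=dict(d.get("extras", {})),
        )


@dataclass
class TwoStepResult:
    """Primary fits per condition plus the secondary regression on their estimates."""

    primary_fits: Dict[float, FitResult]
    secondary_fit: FitResult

    def to_dict(self) -> Dict[str, Any]:
        return {
            "primary_fits": {str(k): v.to_dict() for k, v in self.primary_fits.items()},
            "secondary_fit": self.secondary_fit.to_dict(),
        }


@dataclass
class PredictionBand:
    """Pointwise 95% prediction band on a query grid."""

    times: np.ndarray
    mean: np.ndarray
    sigma: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        for name in ("times", "mean", "sigma", "lower", "upper"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))

    def to_dict(self) -> Dict[str, Any]:
        return {k: np.asarray(getattr(self, k)).tolist()
                for k in ("times", "mean", "sigma", "lower", "upper")}


@dataclass
class MLConfig:
    """Configuration of the machine-learning workflow.

    Datasets below ``augment_threshold`` training rows are resampled with
    replacement up to that size, with uniform +/- ``augment_noise`` log CFU
    noise added to the resampled responses (training folds only).
    """

    algorithm: str = "gpr"  # gpr | svr | rfr
    augment_threshold: int = 750
    augment_noise: float = 0.2
    test_fraction: float = 0.2
    cv_folds: int = 5
    bootstrap_iters: int = 100
    seed: int = 20250910
    gpr_restarts: int = 5
    rf_trees: int = 500
    compute_band: bool = True
    compute_cv: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise DomainError("test_fraction must lie in (0, 1)")
        if self.cv_folds < 2:
            raise DomainError("cv_folds must be at least 2")
        if self.augment_noise < 0:
            raise DomainError("augment_noise must be non-negative")


@dataclass
class MLResult:
    """Trained regressor with its scaling, metrics and uncertainty band."""

    algorithm: str
    scaler: Any
    model: Any
    train_rmse: float
    train_r2: float
    test_rmse: float
    test_r2: float
    cv_rmse: float
    band: Optional[PredictionBand] = None
    extras: Dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> Dict[str, Any]:
        return {
            "algorithm": self.algorithm,
            "scaler": {
                "mean": np.asarray(self.scaler.mean).tolist(),
                "sd": np.asarray(self.scaler.sd).tolist(),
            },
            "train_rmse": float(self.train_rmse),
            "train_r2": float(self.train_r2),
            "test_rmse": float(self.test_rmse),
            "test_r2": float(self.test_r2),
            "cv_rmse": float(self.cv_rmse),
            "band": self.band.to_dict() if self.band is not None else None,
            "extras": _jsonify(self.extras),
        }


@dataclass
class SimulationSpec:
    """Recipe for a seeded synthetic dataset with known parameters.

    Either ``primary`` holds one primary-parameter mapping applied at each
    condition, or ``secondary`` holds secondary coefficients from which the
    condition-dependent kinetic parameters are derived (plus the shared
    curve-level entries in ``primary`` such as x0/xmax or logN0/p).
    """

    kind: str  # growth | inhibition
    model_id: str
    conditions: List[float]
    primary: Dict[str, float] = field(default_factory=dict)
    secondary: Optional[Any] = None
    times: Optional[Any] = None  # array, or mapping condition -> array
    n_times: int = 15
    noise_sd: Optional[float] = None
    replicates: int = 1
    seed: int = 20250910
    condition_name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("growth", "inhibition"):
            raise DomainError(f"kind must be growth|inhibition, got {self.kind!r}")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise DomainError("noise_sd must be non-negative")
        if self.replicates < 1:
            raise DomainError("replicates must be at least 1")


@dataclass
class Report:
    """Serializable run report: metadata plus result blocks."""

    metadata: Dict[str, Any] = field(default_factory=dict)
    results: Dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> Dict[str, Any]:
        return {"metadata": _jsonify(self.metadata), "results": _jsonify(self.results)}

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "Report":
        return cls(metadata=dict(d.get("metadata", {})), results=dict(d.get("results", {})))


def _jsonify(obj: Any) -> Any:
    """Recursively convert numpy scalars/arrays and dataclass results to JSON types."""
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "to_dict"):
        return obj.to_dict()
    return obj
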