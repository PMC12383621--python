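"""Bayesian hyperparameter optimization with held-out validation subjects.

Whole subjects (default four) are removed from the training cohort to form
a validation set; candidate hyperparameter configurations are then
evaluated sequentially (default 100 iterations) and scored by the RMSE of
their predictions on the pooled validation windows.  The first candidate
is always the architecture's default configuration; a handful of random
probes follow, after which candidates are proposed by maximizing expected
improvement under a Gaussian-process surrogate fitted to the observed
(configuration, RMSE) pairs on the unit-cube encoding of the declared
search space.  The candidate with minimum validation RMSE wins, so the
tuned configuration is never worse than the default on the validation
split.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern

from .features import FeatureMatrix, split_by_subjects
from .modeling import SEARCH_SPACES, ModelSpec, default_spec, fit, predict

__all__ = ["TuningConfig", "TuningResult", "tune_bayesian"]

_N_RANDOM_PROBES = 10
_N_EI_CANDIDATES = 256


@dataclass(frozen=True)
class TuningConfig:
    n_iterations: int = 100
    n_validation_subjects: int = 4
    seed: int = 0
    search_space: dict[str, tuple] | None = None  # defaults to the declared space

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.n_validation_subjects < 1:
            raise ValueError("n_validation_subjects must be >= 1")


@dataclass
class TuningResult:
    best_spec: ModelSpec
    best_rmse: float
    audit_log: pd.DataFrame  # iteration, hyperparameters (JSON), validation RMSE
    validation_subjects: tuple[str, ...]
    training_subjects: tuple[str, ...]


# ---------------------------------------------------------------------------
# search-space encoding: every dimension maps to [0, 1]


def _encode(space: dict[str, tuple], params: dict) -> np.ndarray:
    out = []
    for name, dim in space.items():
        kind = dim[0]
        v = params[name]
        if kind == "categorical":
            choices = dim[1]
            idx = choices.index(v)
            out.append(idx / max(len(choices) - 1, 1))
        elif kind == "loguniform":
            lo, hi = np.log(dim[1]), np.log(dim[2])
            out.append(np.clip((np.log(max(v, 1e-300)) - lo) / (hi - lo), 0.0, 1.0))
        else:  # uniform, int
            lo, hi = dim[1], dim[2]
            out.append(np.clip((v - lo) / (hi - lo), 0.0, 1.0))
    return np.asarray(out)


def _decode(space: dict[str, tuple], u: np.ndarray) -> dict:
    params = {}
    for (name, dim), x in zip(space.items(), u):
        kind = dim[0]
        if kind == "categorical":
            choices = dim[1]
            params[name] = choices[min(int(x * len(choices)), len(choices) - 1)]
        elif kind == "loguniform":
            lo, hi = np.log(dim[1]), np.log(dim[2])
            params[name] = float(np.exp(lo + x * (hi - lo)))
        elif kind == "int":
            lo, hi = dim[1], dim[2]
            params[name] = int(round(lo + x * (hi - lo)))
        else:
            lo, hi = dim[1], dim[2]
            params[name] = float(lo + x * (hi - lo))
    return params


def tune_bayesian(
    spec: ModelSpec,
    matrix: FeatureMatrix,
    config: TuningConfig | None = None,
) -> TuningResult:
    """Tune one architecture's hyperparameters on a subject-grouped matrix.

    ``config.n_validation_subjects`` whole subjects are drawn (seeded) as
    the validation set; the remaining subjects train each candidate.  The
    audit log records every iteration's candidate and validation RMSE.
    """
    config = config if config is not None else TuningConfig()
    subjects = matrix.subjects()
    if len(subjects) < config.n_validation_subjects + 2:
        raise ValueError(
            f"need >= {config.n_validation_subjects + 2} subjects "
            f"(got {len(subjects)}): at least 2 must remain for training"
        )
    space = (
        config.search_space
        if config.search_space is not None
        else SEARCH_SPACES[spec.architecture]
    )
    rng = np.random.default_rng(config.seed)
    val_subjects = set(
        rng.choice(subjects, size=config.n_validation_subjects, replace=False)
    )
    train_m, val_m = split_by_subjects(matrix, val_subjects)
    y_val = val_m.y()

    def evaluate(params: dict) -> float:
        cand = ModelSpec(spec.architecture, dict(params), seed=spec.seed)
        model = fit(cand, train_m)
        resid = predict(model, val_m) - y_val
        return float(np.sqrt(np.mean(resid**2)))

    observed_u: list[np.ndarray] = []
    eval_params: list[dict] = []
    observed_rmse: list[float] = []
    records = []
    gp = GaussianProcessRegressor(
        kernel=Matern(nu=2.5), normalize_y=True, alpha=1e-6, random_state=config.seed
    )
    for it in range(config.n_iterations):
        if it == 0:
            # the architecture's default configuration is always candidate 0;
            # its surrogate position is the library-default values clipped
            # into the declared space
            params = dict(default_spec(spec.architecture).hyperparameters)
            u = _encode(space, {**_LIBRARY_DEFAULT_VALUES[spec.architecture], **params})
        elif it <= _N_RANDOM_PROBES:
            u = rng.uniform(size=len(space))
            params = _decode(space, u)
        else:
            u = _propose_ei(gp, space, observed_u, observed_rmse, rng)
            params = _decode(space, u)
        rmse = evaluate(params)
        observed_u.append(np.asarray(u))
        eval_params.append(params)
        observed_rmse.append(rmse)
        records.append(
            {
                "iteration": it,
                "hyperparameters": json.dumps(params, sort_keys=True, default=str),
                "validation_rmse": rmse,
            }
        )
    best_i = int(np.argmin(observed_rmse))
    best_spec = ModelSpec(spec.architecture, dict(eval_params[best_i]), seed=spec.seed)
    return TuningResult(
        best_spec=best_spec,
        best_rmse=float(observed_rmse[best_i]),
        audit_log=pd.DataFrame.from_records(records),
        validation_subjects=tuple(sorted(val_subjects)),
        training_subjects=tuple(s for s in subjects if s not in val_subjects),
    )


# library-default hyperparameter values, used only to place the default
# candidate on the surrogate's unit cube (clipped into the declared bounds)
_LIBRARY_DEFAULT_VALUES: dict[str, dict] = {
    "xgb": {
        "n_estimators": 100, "learning_rate": 0.3, "max_depth": 6,
        "min_child_weight": 1, "subsample": 1.0, "colsample_bytree": 1.0,
        "gamma": 0.0, "reg_alpha": 1e-3, "reg_lambda": 1.0,
    },
    "rf": {
        "n_estimators": 100, "max_depth": 20, "min_samples_split": 2,
        "min_samples_leaf": 1, "max_features": 1.0, "bootstrap": True,
    },
    "enet": {"alpha": 1.0, "l1_ratio": 0.5},
    "svr": {"C": 1.0, "epsilon": 0.1, "gamma": 0.01, "kernel": "rbf"},
}


def _propose_ei(
    gp: GaussianProcessRegressor,
    space: dict[str, tuple],
    observed_u: list[np.ndarray],
    observed_rmse: list[float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Next candidate (unit-cube point) by expected improvement."""
    X = np.vstack(observed_u)
    y = np.asarray(observed_rmse)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        gp.fit(X, y)
    cand = rng.uniform(size=(_N_EI_CANDIDATES, len(space)))
    mu, sigma = gp.predict(cand, return_std=True)
    y_min = y.min()
    sigma = np.maximum(sigma, 1e-12)
    z = (y_min - mu) / sigma
    ei = (y_min - mu) * norm.cdf(z) + sigma * norm.pdf(z)
    return cand[int(np.argmax(ei))]
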