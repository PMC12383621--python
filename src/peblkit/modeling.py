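"""Regression architectures for PEBL prediction behind one interface.

Four architectures are supported: extreme gradient boosting (XGB), random
forest (RF), elastic net (ENET) and kernel support-vector regression
(SVR).  A :class:`ModelSpec` names the architecture, its hyperparameters
and a seed; :func:`fit` / :func:`predict` run any of the four on a
:class:`~peblkit.features.FeatureMatrix` without code changes.  Declared
hyperparameter search spaces (used by the Bayesian tuner) live in
``SEARCH_SPACES`` and are deliberately explicit so they can be audited and
overridden.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet
from sklearn.svm import SVR
from xgboost import XGBRegressor

from .features import FeatureMatrix
from .manifest import FEATURE_NAMES, MANIFEST_VERSION

ARCHITECTURES = ("xgb", "rf", "enet", "svr")

__all__ = [
    "ARCHITECTURES",
    "ModelSpec",
    "TrainedModel",
    "SEARCH_SPACES",
    "DEFAULT_HYPERPARAMETERS",
    "default_spec",
    "fit",
    "predict",
]


@dataclass(frozen=True)
class ModelSpec:
    architecture: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        allowed = set(SEARCH_SPACES[self.architecture])
        extra = set(self.hyperparameters) - allowed
        if extra:
            raise ValueError(
                f"hyperparameters {sorted(extra)} are not tunable for "
                f"{self.architecture}"
            )


@dataclass
class TrainedModel:
    spec: ModelSpec
    estimator: object
    manifest_version: str
    training_subjects: tuple[str, ...]

    def predict(self, features: FeatureMatrix) -> np.ndarray:
        return predict(self, features)


# Declared search space per architecture: each dimension is
# (kind, ...) with kind in {uniform, loguniform, int, categorical}.
SEARCH_SPACES: dict[str, dict[str, tuple]] = {
    "xgb": {
        "n_estimators": ("int", 50, 500),
        "learning_rate": ("loguniform", 0.01, 0.3),
        "max_depth": ("int", 2, 10),
        "min_child_weight": ("int", 1, 10),
        "subsample": ("uniform", 0.5, 1.0),
        "colsample_bytree": ("uniform", 0.5, 1.0),
        "gamma": ("uniform", 0.0, 5.0),
        "reg_alpha": ("loguniform", 1e-3, 10.0),
        "reg_lambda": ("loguniform", 1e-3, 10.0),
    },
    "rf": {
        "n_estimators": ("int", 50, 500),
        "max_depth": ("int", 2, 20),
        "min_samples_split": ("int", 2, 20),
        "min_samples_leaf": ("int", 1, 10),
        "max_features": ("uniform", 0.1, 1.0),
        "bootstrap": ("categorical", (True, False)),
    },
    "enet": {
        "alpha": ("loguniform", 1e-3, 1e3),
        "l1_ratio": ("uniform", 0.0, 1.0),
    },
    "svr": {
        "C": ("loguniform", 1e-3, 1e3),
        "epsilon": ("loguniform", 1e-3, 1.0),
        "gamma": ("loguniform", 1e-4, 10.0),
        "kernel": ("categorical", ("rbf", "linear")),
    },
}

# Library-default configurations; always the first tuning candidate.
DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "xgb": {},
    "rf": {},
    "enet": {},
    "svr": {},
}


def default_spec(architecture: str, seed: int = 0) -> ModelSpec:
    """The architecture's default (untuned) configuration."""
    return ModelSpec(
        architecture=architecture,
        hyperparameters=dict(DEFAULT_HYPERPARAMETERS[architecture]),
        seed=seed,
    )


def _build_estimator(spec: ModelSpec):
    hp = dict(spec.hyperparameters)
    if spec.architecture == "xgb":
        return XGBRegressor(
            random_state=spec.seed, n_jobs=1, verbosity=0, tree_method="hist", **hp
        )
    if spec.architecture == "rf":
        return RandomForestRegressor(random_state=spec.seed, n_jobs=1, **hp)
    if spec.architecture == "enet":
        return ElasticNet(max_iter=5000, **hp)
    if spec.architecture == "svr":
        return SVR(**hp)
    raise ValueError(spec.architecture)


def fit(
    spec: ModelSpec,
    features: FeatureMatrix,
    targets: np.ndarray | None = None,
) -> TrainedModel:
    """Fit the specified architecture on a feature matrix.

    Targets default to the matrix's paired ground-truth column.  The fit is
    deterministic given the spec's seed.
    """
    if features.manifest_version != MANIFEST_VERSION:
        raise ValueError("feature manifest version mismatch")
    X = features.X()
    y = features.y() if targets is None else np.asarray(targets, dtype=float)
    if X.shape[0] == 0:
        raise ValueError("empty feature matrix")
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and targets are misaligned")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in features or targets")
    est = _build_estimator(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(X, y)
    return TrainedModel(
        spec=spec,
        estimator=est,
        manifest_version=features.manifest_version,
        training_subjects=tuple(features.subjects()),
    )


def predict(model: TrainedModel, features: FeatureMatrix) -> np.ndarray:
    """Predict the target for every row of a feature matrix."""
    if features.manifest_version != model.manifest_version:
        raise ValueError("feature manifest version mismatch")
    missing = [c for c in FEATURE_NAMES if c not in features.df.columns]
    if missing:
        raise ValueError(f"feature matrix is missing columns: {missing[:3]} ...")
    preds = np.asarray(model.estimator.predict(features.X()), dtype=float)
    if not np.all(np.isfinite(preds)):
        raise ValueError("model produced non-finite predictions")
    return preds
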